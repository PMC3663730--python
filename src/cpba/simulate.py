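"""Synthetic network generators and evaluation metrics.

Every input class the method is evaluated on can be generated here, with the
ground truth returned alongside the data and all randomness driven by an
explicit seed:

* planar Gaussian clusters with distance-based adjacency
  ``A_ij = 1 - (d_ij / max d)^2`` — a geometric testbed where propensities
  track distance-to-center and cluster similarities track center distances;
* 0/1 block-diagonal multigraphs with a few planted off-block edges — the
  testbed for edge-significance comparisons;
* exactly factorizable networks ``A_ij = f_i f_j`` (conformity networks);
* Poisson multigraphs drawn from a known ``(c, p, R)`` triple;
* a modular co-expression emulation: correlated latent eigengene profiles,
  per-node module membership kME, and a soft-thresholded correlation
  adjacency ``|corr|^beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "PlanarSimResult",
    "BlockSimResult",
    "CoexpressionSimSpec",
    "CoexpressionSimResult",
    "DEFAULT_PLANAR_CENTERS",
    "DEFAULT_PLANAR_SIZES",
    "simulate_planar_clusters",
    "simulate_block_multigraph",
    "simulate_factorizable",
    "simulate_poisson_cpba",
    "simulate_coexpression",
    "auc",
    "adjusted_rand_index",
    "rank_correlation",
]

# Cluster centers with all six pairwise distances distinct and separations
# large relative to the unit point scatter, so the generating clusters are
# unambiguous and recoverable.
DEFAULT_PLANAR_CENTERS = ((0.0, 0.0), (8.0, 0.0), (0.0, 12.0), (12.0, 10.0))
DEFAULT_PLANAR_SIZES = (50, 100, 150, 200)


@dataclass
class PlanarSimResult:
    points: np.ndarray
    labels: np.ndarray
    centers: np.ndarray
    sample_centers: np.ndarray
    adjacency: np.ndarray
    max_dist: float
    seed: int | None = None


@dataclass
class BlockSimResult:
    adjacency: np.ndarray
    block_sizes: tuple
    labels: np.ndarray
    planted_pairs: list
    off_block_zero_pairs: list = field(repr=False, default_factory=list)
    seed: int | None = None


@dataclass
class CoexpressionSimSpec:
    """Design of the latent-eigengene co-expression emulation.

    ``module_sizes`` gives the K module sizes; ``kme_range`` the per-node
    module membership sampled uniformly within it; ``eigengene_cor`` a K x K
    positive semidefinite correlation matrix between latent profiles (built
    from random loadings when omitted); ``beta`` the soft-thresholding power;
    ``n_samples`` the number of observations per profile.
    """

    module_sizes: tuple = (60, 50, 40, 35, 30)
    kme_range: tuple = (0.6, 0.98)
    eigengene_cor: np.ndarray | None = None
    beta: float = 6.0
    n_samples: int = 120


@dataclass
class CoexpressionSimResult:
    adjacency: np.ndarray
    labels: np.ndarray
    kme: np.ndarray
    eigengene_cor: np.ndarray
    eigengenes: np.ndarray
    expression: np.ndarray
    spec: CoexpressionSimSpec
    seed: int | None = None


def simulate_planar_clusters(
    centers=DEFAULT_PLANAR_CENTERS,
    sizes=DEFAULT_PLANAR_SIZES,
    rng_seed: int | None = None,
) -> PlanarSimResult:
    """Gaussian clusters in the plane with distance-based adjacency.

    Points are drawn N(center_a, I) per cluster; the adjacency is
    ``A_ij = 1 - (d_ij / max d)^2``, so the farthest pair has adjacency
    exactly 0 and coincident points would have adjacency 1.
    """
    centers = np.asarray(centers, dtype=float)
    sizes = np.asarray(sizes, dtype=int)
    if centers.shape[0] != sizes.shape[0]:
        raise ValueError("centers and sizes must have equal lengths")
    if np.any(sizes < 1):
        raise ValueError("cluster sizes must be >= 1")
    n = int(sizes.sum())
    if n < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(rng_seed)
    points = np.vstack(
        [rng.standard_normal((sz, 2)) + ctr for sz, ctr in zip(sizes, centers)]
    )
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    d = squareform(pdist(points))
    max_d = d.max()
    A = 1.0 - (d / max_d) ** 2
    np.fill_diagonal(A, 1.0)
    sample_centers = np.vstack([points[labels == a].mean(axis=0) for a in range(1, len(sizes) + 1)])
    return PlanarSimResult(
        points=points,
        labels=labels,
        centers=centers,
        sample_centers=sample_centers,
        adjacency=A,
        max_dist=float(max_d),
        seed=rng_seed,
    )


def simulate_block_multigraph(
    block_sizes=(100, 200, 500),
    n_switch_per_pair: int = 20,
    rng_seed: int | None = None,
) -> BlockSimResult:
    """0/1 block-diagonal adjacency with planted off-block edges.

    Diagonal blocks are all-1 (off their own diagonal); for every pair of
    blocks, ``n_switch_per_pair`` distinct off-block entries are switched
    from 0 to 1, symmetrically.
    """
    block_sizes = tuple(int(s) for s in block_sizes)
    n = sum(block_sizes)
    labels = np.repeat(np.arange(1, len(block_sizes) + 1), block_sizes)
    A = (labels[:, None] == labels[None, :]).astype(float)
    rng = np.random.default_rng(rng_seed)
    starts = np.cumsum((0,) + block_sizes)
    planted = []
    for a in range(len(block_sizes)):
        for b in range(a + 1, len(block_sizes)):
            na, nb = block_sizes[a], block_sizes[b]
            if n_switch_per_pair > na * nb:
                raise ValueError("n_switch_per_pair exceeds the off-block pair count")
            flat = rng.choice(na * nb, size=n_switch_per_pair, replace=False)
            for f in flat:
                i = starts[a] + f // nb
                j = starts[b] + f % nb
                A[i, j] = A[j, i] = 1.0
                planted.append((int(i), int(j)))
    return BlockSimResult(
        adjacency=A,
        block_sizes=block_sizes,
        labels=labels,
        planted_pairs=planted,
        seed=rng_seed,
    )


def simulate_factorizable(f) -> np.ndarray:
    """Exactly factorizable network ``A_ij = f_i f_j`` (diagonal set to 0)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("conformities must be nonnegative")
    A = np.outer(f, f)
    np.fill_diagonal(A, 0.0)
    return A


def simulate_poisson_cpba(c, p, R, rng_seed: int | None = None) -> np.ndarray:
    """Multigraph counts ``n_ij ~ Poisson(r[c_i, c_j] p_i p_j)``, drawn
    independently per unordered pair and mirrored symmetrically."""
    from .model import CPBAModel, expected_adjacency_matrix

    model = CPBAModel(c=c, p=p, R=R, objective_kind="poisson")
    mu = expected_adjacency_matrix(model)
    rng = np.random.default_rng(rng_seed)
    n = mu.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    counts = rng.poisson(mu[iu, ju])
    A = np.zeros_like(mu)
    A[iu, ju] = counts
    A[ju, iu] = counts
    return A


def _random_psd_correlation(K: int, rng: np.random.Generator) -> np.ndarray:
    """Correlation matrix from random loadings on two common factors; the
    off-diagonal entries land in a moderate, spread-out range."""
    load = rng.uniform(0.2, 0.6, size=(K, 2)) * rng.choice([1.0, 1.0, -1.0], size=(K, 2))
    cov = load @ load.T + np.diag(rng.uniform(0.6, 1.2, size=K))
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def simulate_coexpression(
    spec: CoexpressionSimSpec | None = None,
    rng_seed: int | None = None,
) -> CoexpressionSimResult:
    """Modular co-expression network from correlated latent eigengenes.

    K latent profiles (eigengenes) with a prescribed correlation matrix are
    drawn over ``n_samples`` observations; node ``i`` in module ``a`` gets
    ``x_i = kme_i * u_a + sqrt(1 - kme_i^2) * noise`` so its correlation with
    its eigengene is approximately ``kme_i``.  The adjacency is
    ``|corr(x_i, x_j)|^beta``.  In the noiseless ``kme = 1, beta = 1`` limit
    each module is exactly factorizable.
    """
    spec = spec or CoexpressionSimSpec()
    rng = np.random.default_rng(rng_seed)
    K = len(spec.module_sizes)
    C = spec.eigengene_cor if spec.eigengene_cor is not None else _random_psd_correlation(K, rng)
    C = np.asarray(C, dtype=float)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(K))
    z = rng.standard_normal((spec.n_samples, K))
    z -= z.mean(axis=0)
    Q, _ = np.linalg.qr(z)  # orthonormal zero-mean columns
    u = np.sqrt(spec.n_samples) * Q @ L.T  # empirical correlations equal C exactly
    u /= u.std(axis=0)
    labels = np.repeat(np.arange(1, K + 1), spec.module_sizes)
    n = labels.shape[0]
    kme = rng.uniform(*spec.kme_range, size=n)
    noise = rng.standard_normal((spec.n_samples, n))
    noise = (noise - noise.mean(axis=0)) / noise.std(axis=0)
    X = kme * u[:, labels - 1] + np.sqrt(1.0 - kme**2) * noise
    A = np.abs(np.corrcoef(X.T)) ** spec.beta
    np.fill_diagonal(A, 1.0)
    return CoexpressionSimResult(
        adjacency=A,
        labels=labels,
        kme=kme,
        eigengene_cor=C,
        eigengenes=u,
        expression=X,
        spec=spec,
        seed=rng_seed,
    )


def auc(scores, labels) -> float:
    """Mann-Whitney area under the ROC curve; ties count one half.

    ``labels`` are binary (positives truthy); both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative examples")
    ranks = rankdata(scores)  # midranks implement the half-tie convention
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (1 = identical up
    to relabeling)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal lengths")
    return float(adjusted_rand_score(labels_a, labels_b))


def rank_correlation(x, y) -> float:
    """Spearman rank correlation; raises on constant input where the
    statistic is undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    return float(spearmanr(x, y).statistic)
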