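"""Cluster search for CPBA: initialization, node reassignment, the full
alternating fit, and likelihood-based selection of the number of clusters.

The full algorithm alternates two monotone phases until the assignment
stabilizes:

1. parameter estimation (exact similarity updates + MM propensity updates)
   with the assignment fixed;
2. greedy node reassignment with all parameters fixed — nodes are visited in
   a seeded random order and each is moved to the proper cluster that most
   improves the objective, repeating passes until none moves.

Label 0 is reserved for improper nodes left out of every proper cluster by
the initial cut.  Such nodes keep propensities and an estimated similarity
row like any pseudo-cluster, and reassignment may pull them into a proper
cluster; nodes never enter label 0.

The public surface is the scikit-learn style estimator :class:`CPBA`; the
module-level functions are thin building blocks it composes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .estimation import (
    FitResult,
    FitSettings,
    fit_parameters,
    init_propensities,
    update_R,
)
from .model import CPBAModel, validate_adjacency

__all__ = [
    "CPBA",
    "PurePropensityPoisson",
    "SelectionResult",
    "init_clusters_hierarchical",
    "reassign_nodes",
    "fit_cpba",
    "fit_ppp",
    "select_n_clusters",
]

_MOVE_EPS = 1e-12  # strict-improvement threshold; guards against float-noise cycling

SELECTION_CAVEAT = (
    "AIC and BIC may be inappropriate for models with latent cluster labels; "
    "treat the selected number of clusters as a guide, not a verdict."
)


def _relabel_with_min_size(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Send clusters smaller than ``min_size`` to label 0 and relabel the
    survivors contiguously as 1..K (ordered by first appearance)."""
    out = np.zeros_like(labels)
    next_label = 1
    for lab in pd.unique(labels):
        idx = labels == lab
        if idx.sum() >= min_size:
            out[idx] = next_label
            next_label += 1
    return out


def init_clusters_hierarchical(
    A: np.ndarray,
    target_K: int | None = None,
    cut_height: float | None = None,
    linkage: str = "average",
    min_size: int = 3,
) -> np.ndarray:
    """Initial assignment from average-linkage hierarchical clustering.

    Dissimilarity is 1 minus the similarity rescaled by its maximum (the
    identity map on matrices already in [0, 1]).  The tree is cut either to a
    requested number of clusters or at a height (default: 99% of the highest
    merge); clusters below ``min_size`` are merged into the improper label 0.
    """
    A = validate_adjacency(A)
    n = A.shape[0]
    if target_K is not None:
        if target_K > n:
            raise ValueError(f"target_K={target_K} exceeds the number of nodes {n}")
        if target_K < 1:
            raise ValueError("target_K must be >= 1")
        if target_K == 1:
            return np.ones(n, dtype=int)
    amax = A.max()
    D = 1.0 - (A / amax if amax > 0 else A)
    np.fill_diagonal(D, 0.0)
    Z = scipy_linkage(squareform(np.clip(D, 0.0, None), checks=False), method=linkage)
    if target_K is not None:
        raw = fcluster(Z, t=target_K, criterion="maxclust")
    else:
        h = cut_height if cut_height is not None else 0.99 * Z[:, 2].max()
        raw = fcluster(Z, t=h, criterion="distance")
    return _relabel_with_min_size(np.asarray(raw, dtype=int), min_size)


def _random_assignment(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random labels 1..K, resampled until every cluster is non-empty."""
    while True:
        c = rng.integers(1, K + 1, size=n)
        if np.unique(c).size == K:
            return c


def _node_scores(A, c, p, R, i, candidates, objective_kind):
    """Objective contribution (ordered-pair scale, up to constants) of node
    ``i``'s row under membership in each candidate cluster."""
    pj = p * R[np.ix_(candidates, c)]  # (B, n): r[b, c_j] * p_j
    mu = p[i] * pj
    a_row = A[i]
    mask = np.ones(A.shape[0], dtype=bool)
    mask[i] = False
    mu = mu[:, mask]
    a_row = a_row[mask]
    if objective_kind == "frobenius":
        d = a_row[None, :] - mu
        return -np.sum(d * d, axis=1)  # higher is better for both branches
    pos = a_row > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        lg = np.where(mu[:, pos] > 0, np.log(np.where(mu[:, pos] > 0, mu[:, pos], 1.0)), -np.inf)
        s = np.sum(a_row[pos] * lg, axis=1) - np.sum(mu, axis=1)
    return s


def reassign_nodes(
    A: np.ndarray,
    model: CPBAModel,
    rng: np.random.Generator,
    max_passes: int = 100,
) -> tuple[np.ndarray, int]:
    """Greedy node reassignment with all parameters fixed.

    Nodes are visited in a seeded random permutation; each is moved to the
    proper cluster whose membership most improves the objective, when the
    improvement is strictly positive (ties keep the current cluster).  Moves
    that would empty a proper cluster are skipped; nodes may leave the
    improper label 0 but never enter it.  Passes repeat until one makes no
    move.  Returns the new assignment and the total number of moves.
    """
    A = np.asarray(A, dtype=float)
    c = model.c.copy()
    p, R = model.p, model.R
    kind = model.objective_kind
    n = c.shape[0]
    total_moves = 0
    for _ in range(max_passes):
        moves = 0
        order = rng.permutation(n)
        sizes = np.bincount(c, minlength=R.shape[0])
        for i in order:
            cur = c[i]
            proper = np.flatnonzero(sizes[1:] > 0) + 1
            candidates = proper if cur == 0 or cur in proper else np.append(proper, cur)
            if candidates.size <= 1 and cur != 0:
                continue
            scores = _node_scores(A, c, p, R, i, candidates, kind)
            cur_pos = np.flatnonzero(candidates == cur)
            cur_score = scores[cur_pos[0]] if cur_pos.size else -np.inf
            best = int(np.argmax(scores))
            if candidates[best] == cur or scores[best] <= cur_score + _MOVE_EPS:
                continue
            if cur > 0 and sizes[cur] == 1:
                continue  # never empty a proper cluster
            sizes[cur] -= 1
            c[i] = candidates[best]
            sizes[c[i]] += 1
            moves += 1
        total_moves += moves
        if moves == 0:
            break
    return c, total_moves


@dataclass
class SelectionResult:
    """AIC/BIC table over candidate cluster numbers, plus per-criterion picks."""

    table: pd.DataFrame
    best_aic_K: int
    best_bic_K: int
    caveat: str = SELECTION_CAVEAT
    fits: dict | None = None


class CPBA(ClusterMixin, BaseEstimator):
    """Cluster and propensity based approximation of a symmetric network.

    Approximates a symmetric nonnegative adjacency matrix as
    ``A_ij ~ r[c_i, c_j] * p_i * p_j``, jointly estimating a hard cluster
    assignment ``c``, per-node propensities ``p`` and a unit-diagonal cluster
    similarity matrix ``R`` by alternating monotone parameter updates (exact
    ``R``, MM steps for ``p`` with optional quasi-Newton acceleration) with
    greedy node reassignment.

    Parameters
    ----------
    n_clusters : int or None
        Number of proper clusters to cut the initial tree to.  ``None`` cuts
        at a height instead and lets small clusters fall into label 0.
    objective : {"poisson", "frobenius"}
        ``"poisson"`` maximizes the multigraph Poisson log-likelihood of
        integer edge counts; ``"frobenius"`` minimizes the squared error for
        weighted similarities in [0, 1].
    init : {"hierarchical", "random"} or array-like of int
        Initial assignment: average-linkage hierarchical clustering of
        ``1 - A/max(A)``, random labels, or an explicit label vector
        (labels in ``{0, 1, ..}``, 0 improper).
    tol : float
        Objective-change threshold declaring parameter-fit convergence.
    accelerate : bool
        Apply safeguarded quasi-Newton extrapolation to the propensity
        iterations.
    q : int
        Secant pairs retained by the accelerator.
    max_cycles : int
        Maximum alternations of parameter estimation and reassignment.
    random_state : int, Generator or None
        Seeds the reassignment visit order (and random initialization).

    Attributes
    ----------
    labels_ : ndarray of int
        Final cluster labels (0 = improper).
    propensities_ : ndarray
        Estimated node propensities.
    cluster_similarity_ : ndarray, shape (K, K)
        Similarity between proper clusters 1..K (unit diagonal).
    objective_value_ : float
        Final objective (log-likelihood or squared error).
    converged_ : bool
    n_iter_ : int
        Number of estimation/reassignment cycles run.
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        objective: str = "poisson",
        init="hierarchical",
        linkage: str = "average",
        cut_height: float | None = None,
        min_cluster_size: int = 3,
        tol: float = 1e-5,
        inner_tol: float | None = None,
        max_outer_iter: int = 200,
        max_inner_iter: int = 500,
        max_cycles: int = 50,
        accelerate: bool = True,
        q: int = 6,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.objective = objective
        self.init = init
        self.linkage = linkage
        self.cut_height = cut_height
        self.min_cluster_size = min_cluster_size
        self.tol = tol
        self.inner_tol = inner_tol
        self.max_outer_iter = max_outer_iter
        self.max_inner_iter = max_inner_iter
        self.max_cycles = max_cycles
        self.accelerate = accelerate
        self.q = q
        self.random_state = random_state

    def _settings(self) -> FitSettings:
        return FitSettings(
            objective_kind=self.objective,
            tol=self.tol,
            inner_tol=self.inner_tol,
            max_outer_iter=self.max_outer_iter,
            max_inner_iter=self.max_inner_iter,
            accelerate=self.accelerate,
            q=self.q,
        )

    def _initial_assignment(self, A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.init, str):
            if self.init == "hierarchical":
                return init_clusters_hierarchical(
                    A,
                    target_K=self.n_clusters,
                    cut_height=self.cut_height,
                    linkage=self.linkage,
                    min_size=self.min_cluster_size,
                )
            if self.init == "random":
                if self.n_clusters is None:
                    raise ValueError("init='random' requires n_clusters")
                return _random_assignment(A.shape[0], self.n_clusters, rng)
            raise ValueError(f"unknown init {self.init!r}")
        c0 = np.asarray(self.init, dtype=int)
        if c0.shape != (A.shape[0],):
            raise ValueError("explicit initial assignment has wrong length")
        if c0.min() < 0:
            raise ValueError("labels must be nonnegative")
        return c0

    def fit(self, X, y=None):
        """Fit the decomposition to a square symmetric adjacency matrix ``X``."""
        A = validate_adjacency(X)
        rng = np.random.default_rng(self.random_state)
        settings = self._settings()
        c = self._initial_assignment(A, rng)
        trace: list[float] = []
        moves_per_cycle: list[int] = []
        p_prev = None
        converged = False
        rejections = 0
        result = None
        for _cycle in range(self.max_cycles):
            result = fit_parameters(A, c, settings, p0=p_prev)
            trace.extend(result.objective_trace)
            rejections += result.acceleration_rejections
            p_prev = result.model.p
            c_new, moves = reassign_nodes(A, result.model, rng)
            moves_per_cycle.append(moves)
            if moves == 0:
                converged = converged or result.converged
                break
            c = c_new
        model = result.model
        self.model_ = model
        self.fit_result_ = FitResult(
            model=model,
            objective_trace=trace,
            n_outer_iter=len(moves_per_cycle),
            converged=converged,
            acceleration_rejections=rejections,
            n_moves_per_cycle=moves_per_cycle,
        )
        self.labels_ = model.c
        self.propensities_ = model.p
        self.cluster_similarity_ = model.proper_similarity
        self.cluster_similarity_full_ = model.R
        self.objective_value_ = model.objective_value
        self.objective_trace_ = trace
        self.converged_ = converged
        self.n_iter_ = len(moves_per_cycle)
        self.n_clusters_ = model.n_clusters
        return self

    def score(self, X, y=None) -> float:
        """Objective of the fitted model on ``X`` (higher is better: the
        log-likelihood for Poisson, minus the squared error for Frobenius)."""
        from .model import frobenius_objective, poisson_loglik

        A = validate_adjacency(X)
        if self.objective == "frobenius":
            return -frobenius_objective(A, self.model_)
        return poisson_loglik(A, self.model_)


class PurePropensityPoisson(CPBA):
    """Pure propensity Poisson (PPP) model: CPBA with a single cluster.

    Edge counts are Poisson with mean ``p_i * p_j``; no cluster structure is
    modeled (``r`` is identically 1).  Kept as a named estimator because
    edge-significance comparisons against the clustered model require it.
    """

    def __init__(
        self,
        tol: float = 1e-5,
        inner_tol: float | None = None,
        max_outer_iter: int = 200,
        max_inner_iter: int = 500,
        accelerate: bool = True,
        q: int = 6,
        random_state=None,
    ):
        super().__init__(
            n_clusters=1,
            objective="poisson",
            init="hierarchical",
            tol=tol,
            inner_tol=inner_tol,
            max_outer_iter=max_outer_iter,
            max_inner_iter=max_inner_iter,
            max_cycles=1,
            accelerate=accelerate,
            q=q,
            random_state=random_state,
        )


def fit_cpba(A, n_clusters=None, objective="poisson", random_state=None, **kwargs) -> FitResult:
    """Functional wrapper over :class:`CPBA`; returns the fit result."""
    est = CPBA(n_clusters=n_clusters, objective=objective, random_state=random_state, **kwargs)
    est.fit(A)
    return est.fit_result_


def fit_ppp(A, random_state=None, **kwargs) -> FitResult:
    """Functional wrapper over :class:`PurePropensityPoisson`."""
    est = PurePropensityPoisson(random_state=random_state, **kwargs)
    est.fit(A)
    return est.fit_result_


def select_n_clusters(
    A,
    K_range,
    objective: str = "poisson",
    random_state=None,
    **kwargs,
) -> SelectionResult:
    """Fit each candidate K and score it by AIC and BIC.

    The parameter count is ``n + K(K-1)/2`` (propensities plus free
    similarities; hard labels are treated as a model choice, not counted) and
    the sample size is the ``n(n-1)`` ordered pair terms of the objective.
    Only the Poisson branch defines a likelihood.
    """
    if objective != "poisson":
        raise ValueError("criterion requires a likelihood: use objective='poisson'")
    A = validate_adjacency(A)
    n = A.shape[0]
    sample_size = n * (n - 1)
    rows = []
    fits = {}
    for K in K_range:
        res = fit_cpba(A, n_clusters=int(K), objective="poisson", random_state=random_state, **kwargs)
        lnL = res.model.objective_value
        c_params = n + K * (K - 1) // 2
        rows.append(
            {
                "K": int(K),
                "log_likelihood": lnL,
                "n_params": c_params,
                "AIC": -2.0 * lnL + 2.0 * c_params,
                "BIC": -2.0 * lnL + c_params * np.log(sample_size),
            }
        )
        fits[int(K)] = res
    table = pd.DataFrame(rows)
    warnings.warn(SELECTION_CAVEAT)
    return SelectionResult(
        table=table,
        best_aic_K=int(table.loc[table["AIC"].idxmin(), "K"]),
        best_bic_K=int(table.loc[table["BIC"].idxmin(), "K"]),
        fits=fits,
    )
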