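"""Core CPBA data model and objective functions.

The cluster and propensity based approximation (CPBA) represents a symmetric
nonnegative adjacency matrix ``A`` through three ingredients: a cluster
assignment ``c`` (labels ``1..K`` for proper clusters, ``0`` reserved for
improper singleton nodes), a per-node propensity vector ``p``, and a
symmetric cluster similarity matrix ``R`` with unit diagonal.  The model
approximates ``A_ij ~ r[c_i, c_j] * p_i * p_j`` for ``i != j``; the diagonal
of ``A`` carries no meaning and is never read.

Two objectives measure the quality of the approximation, both summed over
ordered pairs ``(i, j)`` with ``i != j`` (so every unordered pair contributes
twice):

* the squared Frobenius criterion ``sum (A_ij - mu_ij)^2``, minimized for
  weighted similarity networks with entries in [0, 1];
* the Poisson log-likelihood ``sum A_ij*ln(mu_ij) - mu_ij - ln(A_ij!)``,
  maximized when ``A_ij = n_ij`` are multigraph edge counts.

``ln(A_ij!)`` is always evaluated as ``ln Gamma(A_ij + 1)``, so non-integer
"counts" share the integer code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CPBAModel",
    "validate_adjacency",
    "expected_adjacency",
    "expected_adjacency_matrix",
    "frobenius_objective",
    "poisson_loglik",
    "network_connectivity",
    "cpba_connectivity",
]


def validate_adjacency(A, *, atol: float = 1e-8) -> np.ndarray:
    """Validate and return a symmetric nonnegative adjacency matrix.

    The diagonal is accepted but carries no meaning.  Asymmetries up to
    ``atol`` are symmetrized by averaging; larger ones raise ``ValueError``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {A.shape}")
    if A.shape[0] < 2:
        raise ValueError("adjacency matrix needs at least 2 nodes")
    if not np.all(np.isfinite(A)):
        raise ValueError("adjacency matrix contains non-finite entries")
    if np.any(A < 0):
        raise ValueError("adjacency matrix contains negative entries")
    asym = np.max(np.abs(A - A.T)) if A.size else 0.0
    if asym > atol:
        raise ValueError(f"adjacency matrix is asymmetric (max deviation {asym:.3g})")
    if asym > 0:
        A = 0.5 * (A + A.T)
    return A


@dataclass
class CPBAModel:
    """Fitted or hypothesized CPBA parameter triple ``(c, p, R)``.

    Parameters
    ----------
    c : ndarray of int, shape (n,)
        Cluster labels in ``{0, 1, .., K}``; ``0`` marks improper nodes.
    p : ndarray, shape (n,)
        Nonnegative propensities.
    R : ndarray, shape (K+1, K+1)
        Cluster similarity matrix indexed directly by label (row/column 0
        belongs to the improper pseudo-cluster and is only meaningful when
        label 0 is occupied).  Symmetric, unit diagonal.
    objective_kind : {"poisson", "frobenius"}
    objective_value : float or None
        Value of the declared objective at ``(c, p, R)``; filled by fits.
    node_labels : list of str, optional
        External node identifiers, parallel to ``c`` and ``p``.
    """

    c: np.ndarray
    p: np.ndarray
    R: np.ndarray
    objective_kind: str = "poisson"
    objective_value: float | None = None
    node_labels: list[str] | None = None

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=int)
        self.p = np.asarray(self.p, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.objective_kind not in ("poisson", "frobenius"):
            raise ValueError(f"unknown objective kind {self.objective_kind!r}")
        n = self.c.shape[0]
        if self.p.shape != (n,):
            raise ValueError("c and p have mismatched lengths")
        if np.any(self.p < 0) or not np.all(np.isfinite(self.p)):
            raise ValueError("propensities must be finite and nonnegative")
        if self.c.min(initial=0) < 0:
            raise ValueError("cluster labels must be nonnegative")
        L = self.R.shape[0]
        if self.R.shape != (L, L) or self.c.max(initial=0) >= L:
            raise ValueError("R is too small for the labels present in c")
        if not np.allclose(self.R, self.R.T):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("R must have a unit diagonal")
        if np.any(self.R < 0):
            raise ValueError("R must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.c.shape[0]

    @property
    def n_clusters(self) -> int:
        """Number of proper clusters K (labels >= 1 present in c)."""
        proper = self.c[self.c > 0]
        return int(np.unique(proper).size)

    @property
    def proper_similarity(self) -> np.ndarray:
        """The K x K similarity block over proper labels 1..max(c)."""
        return self.R[1:, 1:]

    def with_assignment(self, c: np.ndarray) -> "CPBAModel":
        return replace(self, c=np.asarray(c, dtype=int), objective_value=None)


def _mu_matrix(model: CPBAModel) -> np.ndarray:
    """Expected adjacency ``mu_ij = r[c_i,c_j] p_i p_j`` (diagonal included,
    callers must mask it out)."""
    rc = model.R[np.ix_(model.c, model.c)]
    return rc * np.outer(model.p, model.p)


def expected_adjacency_matrix(model: CPBAModel) -> np.ndarray:
    """Full matrix of expected adjacencies with a zeroed (meaningless) diagonal."""
    mu = _mu_matrix(model)
    np.fill_diagonal(mu, 0.0)
    return mu


def expected_adjacency(model: CPBAModel, i: int, j: int) -> float:
    """Model-expected adjacency ``mu_ij = r[c_i, c_j] p_i p_j`` for ``i != j``."""
    if i == j:
        raise ValueError("diagonal undefined: expected adjacency needs i != j")
    return float(model.R[model.c[i], model.c[j]] * model.p[i] * model.p[j])


def frobenius_objective(A: np.ndarray, model: CPBAModel) -> float:
    """Squared Frobenius criterion over ordered off-diagonal pairs.

    Each unordered pair contributes twice; this doubled scale is used
    consistently by the updates, the stationarity checks and AIC/BIC.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (model.n_nodes, model.n_nodes):
        raise ValueError("adjacency and model dimensions differ")
    D = A - _mu_matrix(model)
    np.fill_diagonal(D, 0.0)
    return float(np.sum(D * D))


def poisson_loglik(A: np.ndarray, model: CPBAModel) -> float:
    """Poisson log-likelihood over ordered off-diagonal pairs.

    Uses the convention ``0 * ln 0 = 0``; an observed positive count with a
    zero model mean yields ``-inf`` (an impossible observation, flagged by the
    return value rather than an exception).
    """
    A = np.asarray(A, dtype=float)
    n = model.n_nodes
    if A.shape != (n, n):
        raise ValueError("adjacency and model dimensions differ")
    mu = _mu_matrix(model)
    off = ~np.eye(n, dtype=bool)
    a = A[off]
    m = mu[off]
    pos = a > 0
    if np.any(m[pos] == 0):
        return float("-inf")
    terms = -m - gammaln(a + 1.0)
    terms[pos] += a[pos] * np.log(m[pos])
    return float(np.sum(terms))


def objective_value(A: np.ndarray, model: CPBAModel) -> float:
    """Evaluate the model's declared objective (Frobenius or Poisson)."""
    if model.objective_kind == "frobenius":
        return frobenius_objective(A, model)
    return poisson_loglik(A, model)


def network_connectivity(A: np.ndarray) -> np.ndarray:
    """Node connectivity ``k_i = sum_{j != i} A_ij`` (row sums, diagonal excluded)."""
    A = np.asarray(A, dtype=float)
    return A.sum(axis=1) - np.diag(A)


def cpba_connectivity(model: CPBAModel) -> np.ndarray:
    """Model-based connectivity ``p_i * sum_{j != i} r[c_i, c_j] p_j``."""
    mu = _mu_matrix(model)
    return mu.sum(axis=1) - np.diag(mu)
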