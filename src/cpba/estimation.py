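"""Parameter estimation for CPBA: closed-form similarity updates, MM
propensity updates, block-coordinate optimization and quasi-Newton
acceleration.

For a fixed cluster assignment the two parameter blocks alternate:

* the cluster similarity ``r_ab`` has an exact closed-form update (the
  stationary point of either objective in ``r_ab``);
* the propensities are updated by a minorize-maximize (Poisson) or
  majorize-minimize (Frobenius) step derived from the arithmetic-geometric
  mean inequality, which moves the objective monotonically in the right
  direction.  The Poisson step carries a square root, the Frobenius step a
  fourth root.

MM iterations converge linearly and can be slow near the optimum, so the
inner propensity loop optionally applies a secant-based quasi-Newton
extrapolation: ``q`` recent secant pairs define a low-rank approximation of
the algorithm map's differential, and the extrapolated iterate costs only a
small ``q x q`` solve.  Proposals that leave the feasible region or fail to
beat the plain MM step are discarded, so the recorded objective trace stays
monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import CPBAModel, frobenius_objective, poisson_loglik

__all__ = [
    "FitSettings",
    "FitResult",
    "SecantBuffer",
    "init_propensities",
    "update_R_poisson",
    "update_p_poisson",
    "update_R_frobenius",
    "update_p_frobenius",
    "update_R",
    "qn_accelerate",
    "fit_parameters",
]


@dataclass
class FitSettings:
    """Knobs controlling parameter estimation.

    ``tol`` is the absolute objective-change threshold declaring outer
    convergence; the inner propensity loop stops on a relative parameter
    change below ``inner_tol`` (default ``max(tol, 1e-7)``).
    """

    objective_kind: str = "poisson"
    tol: float = 1e-5
    inner_tol: float | None = None
    max_outer_iter: int = 200
    max_inner_iter: int = 500
    accelerate: bool = True
    q: int = 6

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.q < 1:
            raise ValueError("secant count q must be >= 1")
        if self.objective_kind not in ("poisson", "frobenius"):
            raise ValueError(f"unknown objective kind {self.objective_kind!r}")

    @property
    def effective_inner_tol(self) -> float:
        return self.inner_tol if self.inner_tol is not None else max(self.tol, 1e-7)


@dataclass
class FitResult:
    """Outcome of a parameter fit (or a full clustering fit).

    ``objective_trace`` is monotone: non-decreasing for the Poisson
    log-likelihood, non-increasing for the Frobenius criterion.
    """

    model: CPBAModel
    objective_trace: list[float] = field(default_factory=list)
    n_outer_iter: int = 0
    converged: bool = False
    acceleration_rejections: int = 0
    n_moves_per_cycle: list[int] = field(default_factory=list)

    @property
    def objective_value(self) -> float:
        return self.model.objective_value


def _membership(c: np.ndarray, L: int | None = None) -> np.ndarray:
    """Indicator matrix M of shape (L, n), M[a, i] = 1 iff c_i == a."""
    c = np.asarray(c, dtype=int)
    if L is None:
        L = int(c.max()) + 1
    M = np.zeros((L, c.shape[0]))
    M[c, np.arange(c.shape[0])] = 1.0
    return M


def init_propensities(A: np.ndarray, objective_kind: str = "poisson") -> np.ndarray:
    """Initial propensities: node connectivity over the square root of the
    total connectivity, ``p_i = k_i / sqrt(sum_k k_k)``.

    The same formula serves both branches (applied to weights or to counts);
    it is exact for a single cluster with ``sum p >> sum p^2`` and works well
    as a starting point in general.  An all-zero matrix yields all-zero
    propensities with a warning.
    """
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=1) - np.diag(A)
    total = k.sum()
    if total <= 0:
        warnings.warn("adjacency has no connections; initial propensities are all zero")
        return np.zeros_like(k)
    return k / np.sqrt(total)


def _cluster_pair_sums(A: np.ndarray, c: np.ndarray, weights: np.ndarray | None = None):
    A0 = np.asarray(A, dtype=float).copy()
    np.fill_diagonal(A0, 0.0)
    if weights is not None:
        A0 = A0 * weights
    M = _membership(c)
    return M @ A0 @ M.T, M


def update_R_poisson(A: np.ndarray, c: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Exact Poisson-likelihood update of the cluster similarity matrix.

    ``r_ab = (total count between a and b) / (P_a * P_b)`` with
    ``P_a = sum of propensities in a``; the diagonal stays 1.  A pair with no
    edges gets ``r_ab = 0``; a pair with edges but zero total propensity is
    unidentifiable and raises.
    """
    p = np.asarray(p, dtype=float)
    S, M = _cluster_pair_sums(A, c)
    P = M @ p
    denom = np.outer(P, P)
    bad = (S > 0) & (denom == 0)
    np.fill_diagonal(bad, False)
    if np.any(bad):
        raise ValueError("unidentifiable similarity: edges between clusters with zero total propensity")
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R


def update_R_frobenius(A: np.ndarray, c: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Exact Frobenius update: ``r_ab = sum A_kl p_k p_l / (P2_a * P2_b)``
    with ``P2_a = sum of squared propensities in a``.  Zero denominators give
    ``r_ab = 0`` with a warning."""
    p = np.asarray(p, dtype=float)
    S, M = _cluster_pair_sums(A, c, weights=np.outer(p, p))
    P2 = M @ (p * p)
    denom = np.outer(P2, P2)
    zero = denom == 0
    np.fill_diagonal(zero, False)
    if np.any(zero & (M.sum(axis=1)[:, None] > 0) & (M.sum(axis=1)[None, :] > 0)):
        warnings.warn("cluster with zero squared propensity: similarity set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R


def update_R(A, c, p, objective_kind: str) -> np.ndarray:
    if objective_kind == "frobenius":
        return update_R_frobenius(A, c, p)
    return update_R_poisson(A, c, p)


def _warn_if_above_unit(R: np.ndarray):
    off = R - np.diag(np.diag(R))
    if np.any(off > 1.0 + 1e-9):
        warnings.warn(
            "estimated cluster similarity exceeds 1; expected within [0, 1] "
            "for networks whose edge formation is enhanced within clusters"
        )


def update_p_poisson(A: np.ndarray, c: np.ndarray, p: np.ndarray, R: np.ndarray) -> np.ndarray:
    """One MM ascent step for the propensities under the Poisson objective:
    ``p+_i = sqrt(p_i * k_i / sum_{j != i} r[c_i, c_j] p_j)``.

    A node with no incident edges maps to 0; a zero denominator with a
    positive numerator is a degenerate configuration and raises.
    """
    A = np.asarray(A, dtype=float)
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=int)
    k = A.sum(axis=1) - np.diag(A)
    P = _membership(c, R.shape[0]) @ p
    denom = (R @ P)[c] - p  # subtract own j = i term (r_aa = 1)
    if np.any((denom <= 0) & (k > 0)):
        raise ValueError("degenerate configuration: positive counts with zero expected connectivity")
    out = np.zeros_like(p)
    pos = k > 0
    out[pos] = np.sqrt(p[pos] * k[pos] / denom[pos])
    return out


def update_p_frobenius(A: np.ndarray, c: np.ndarray, p: np.ndarray, R: np.ndarray) -> np.ndarray:
    """One MM descent step for the propensities under the Frobenius objective:
    ``p+_i = [p_i^3 * sum_j r A_ij p_j / sum_j r^2 p_j^2]^(1/4)`` (sums over
    ``j != i``).  A zero numerator maps to 0."""
    A = np.asarray(A, dtype=float)
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=int)
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    Rc = R[np.ix_(c, c)]
    num = (Rc * A0) @ p
    P2 = _membership(c, R.shape[0]) @ (p * p)
    den = (R * R @ P2)[c] - p * p  # own j = i term has r = 1
    if np.any((den <= 0) & (num > 0)):
        raise ValueError("degenerate configuration: zero denominator with positive numerator")
    out = np.zeros_like(p)
    pos = num > 0
    out[pos] = (p[pos] ** 3 * num[pos] / den[pos]) ** 0.25
    return out


class SecantBuffer:
    """FIFO store of up to ``q`` secant pairs ``(u, v)`` with
    ``u = F(x) - x`` and ``v = F(F(x)) - F(x)``."""

    def __init__(self, q: int = 6):
        if q < 1:
            raise ValueError("capacity q must be >= 1")
        self.q = q
        self._u: list[np.ndarray] = []
        self._v: list[np.ndarray] = []

    def push(self, u: np.ndarray, v: np.ndarray):
        if u.shape != v.shape:
            raise ValueError("secant input and output must have equal shapes")
        self._u.append(np.asarray(u, dtype=float))
        self._v.append(np.asarray(v, dtype=float))
        if len(self._u) > self.q:
            self._u.pop(0)
            self._v.pop(0)

    def drop_oldest(self):
        if self._u:
            self._u.pop(0)
            self._v.pop(0)

    def clear(self):
        self._u.clear()
        self._v.clear()

    def __len__(self) -> int:
        return len(self._u)

    @property
    def U(self) -> np.ndarray:
        return np.column_stack(self._u)

    @property
    def V(self) -> np.ndarray:
        return np.column_stack(self._v)


def qn_accelerate(buffer: SecantBuffer, x: np.ndarray, Fx: np.ndarray) -> np.ndarray | None:
    """Quasi-Newton extrapolation of a fixed-point iteration.

    With secants ``M u_i = v_i`` approximating the map differential, the
    Newton step for ``x = F(x)`` reduces (via an explicit low-rank inverse)
    to ``F(x) - V (U'U - U'V)^{-1} U' (x - F(x))``, which only requires
    solving a ``q x q`` system.  Returns ``None`` when no secants are held or
    the small system is singular (caller falls back to the plain MM step);
    the caller is also responsible for rejecting proposals that worsen the
    objective or leave the feasible region.
    """
    if len(buffer) == 0:
        return None
    U, V = buffer.U, buffer.V
    small = U.T @ U - U.T @ V
    rhs = U.T @ (x - Fx)
    try:
        coef = np.linalg.solve(small, rhs)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(coef)):
        return None
    return Fx - V @ coef


def _evaluate(A, c, p, R, objective_kind) -> float:
    model = CPBAModel(c=c, p=p, R=R, objective_kind=objective_kind)
    if objective_kind == "frobenius":
        return frobenius_objective(A, model)
    return poisson_loglik(A, model)


def _improved(new: float, old: float, objective_kind: str, slack: float = 0.0) -> bool:
    if objective_kind == "frobenius":
        return new <= old + slack
    return new >= old - slack


def _inner_p_loop(A, c, p, R, settings: FitSettings, buffer: SecantBuffer | None):
    """Iterate the propensity MM map to (approximate) convergence, with the
    optional safeguarded quasi-Newton extrapolation.  Returns the new
    propensities and the number of rejected acceleration proposals."""
    kind = settings.objective_kind
    step = update_p_frobenius if kind == "frobenius" else update_p_poisson
    tol = settings.effective_inner_tol
    rejections = 0
    it = 0
    while it < settings.max_inner_iter:
        Fp = step(A, c, p, R)
        delta = np.max(np.abs(Fp - p) / np.maximum(np.abs(p), 1.0))
        if delta < tol:
            p = Fp
            break
        if settings.accelerate and buffer is not None:
            FFp = step(A, c, Fp, R)
            buffer.push(Fp - p, FFp - Fp)
            it += 2
            proposal = qn_accelerate(buffer, p, Fp)
            if proposal is not None and np.all(proposal >= 0):
                with np.errstate(divide="ignore", invalid="ignore"):
                    obj_prop = _evaluate(A, c, proposal, R, kind)
                    obj_mm = _evaluate(A, c, FFp, R, kind)
                if np.isfinite(obj_prop) and _improved(obj_prop, obj_mm, kind):
                    p = proposal
                    continue
                buffer.drop_oldest()
                rejections += 1
            elif proposal is not None:
                buffer.drop_oldest()
                rejections += 1
            p = FFp
        else:
            p = Fp
            it += 1
    return p, rejections


def fit_parameters(
    A: np.ndarray,
    c: np.ndarray,
    settings: FitSettings | None = None,
    p0: np.ndarray | None = None,
) -> FitResult:
    """Block-coordinate estimation of ``(p, R)`` for a fixed assignment.

    Alternates the exact similarity update with the inner-iterated (and
    optionally accelerated) propensity updates until the objective changes by
    less than ``settings.tol``.  The returned trace records the objective
    after every outer cycle and is monotone by construction.
    """
    settings = settings or FitSettings()
    kind = settings.objective_kind
    A = np.asarray(A, dtype=float)
    c = np.asarray(c, dtype=int)
    p = init_propensities(A, kind) if p0 is None else np.asarray(p0, dtype=float).copy()
    R = update_R(A, c, p, kind)
    buffer = SecantBuffer(settings.q) if settings.accelerate else None
    obj = _evaluate(A, c, p, R, kind)
    trace = [obj]
    converged = False
    rejections = 0
    n_outer = 0
    for n_outer in range(1, settings.max_outer_iter + 1):
        p, rej = _inner_p_loop(A, c, p, R, settings, buffer)
        rejections += rej
        R = update_R(A, c, p, kind)
        new_obj = _evaluate(A, c, p, R, kind)
        trace.append(new_obj)
        if abs(new_obj - obj) < settings.tol:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    _warn_if_above_unit(R)
    model = CPBAModel(c=c, p=p, R=R, objective_kind=kind, objective_value=obj)
    return FitResult(
        model=model,
        objective_trace=trace,
        n_outer_iter=n_outer,
        converged=converged,
        acceleration_rejections=rejections,
    )
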