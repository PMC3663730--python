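"""Poisson significance tests for edge counts under a fitted CPBA/PPP model.

Conditioned on the fitted parameters, the count between nodes ``i`` and
``j`` is Poisson with mean ``mu_ij = r[c_i, c_j] p_i p_j``; a pair with more
observed connections than the model expects is flagged by the upper-tail
probability ``P(X >= n_obs)`` (inclusive of the observed count).  Parameters
are not re-fit excluding the tested pair — the test conditions on the global
fit.  No multiple-testing correction is applied by default, matching the raw
thresholds the method is usually reported with; Benjamini-Hochberg is
available as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import poisson as poisson_dist

from .model import CPBAModel, expected_adjacency_matrix, validate_adjacency

__all__ = [
    "edge_pvalue",
    "test_all_edges",
    "cluster_connectivity",
    "NEG_LOG10_CAP",
]

NEG_LOG10_CAP = 300.0  # caps -log10(P) in output tables to avoid infinities


def edge_pvalue(observed, expected):
    """Upper-tail Poisson probability ``P(X >= observed)`` for mean ``expected``.

    ``observed = 0`` gives 1 (the whole distribution); a positive count with
    zero mean is impossible under the model and gives 0.  Vectorized.
    """
    obs = np.asarray(observed, dtype=float)
    mu = np.asarray(expected, dtype=float)
    if np.any(obs < 0) or np.any(mu < 0):
        raise ValueError("observed counts and expected means must be nonnegative")
    # sf(k-1) = P(X >= k); sf(-1) = 1 covers observed = 0, and mu = 0 gives 0
    p = poisson_dist.sf(np.ceil(obs) - 1.0, mu)
    return p if p.shape else float(p)


def _neg_log10(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.minimum(-np.log10(p), NEG_LOG10_CAP)


def test_all_edges(
    A,
    model: CPBAModel,
    alpha: float = 0.01,
    min_observed: float = 1,
    lower_tail: bool = False,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Test every unordered pair with ``observed >= min_observed``.

    Returns a table ranked by descending ``-log10(P)`` with columns
    ``rank, node1, node2, cluster1, cluster2, observed, expected, p_value,
    neg_log10_p, intra_cluster`` (plus ``p_adjusted`` when ``bh_correction``).
    The attached ``.attrs['n_significant']`` maps alpha levels 0.01 and 0.001
    (and the requested ``alpha``) to pair counts below them.

    ``lower_tail=True`` instead tests for a deficit of edges,
    ``P(X <= observed)``; the default is the excess (upper) tail.
    """
    if model.objective_kind != "poisson":
        raise ValueError("edge significance requires a Poisson-branch model")
    A = validate_adjacency(A)
    n = A.shape[0]
    mu = expected_adjacency_matrix(model)
    iu, ju = np.triu_indices(n, k=1)
    obs = A[iu, ju]
    keep = obs >= min_observed
    iu, ju, obs = iu[keep], ju[keep], obs[keep]
    expv = mu[iu, ju]
    if lower_tail:
        pvals = poisson_dist.cdf(np.floor(obs), expv)
    else:
        pvals = np.atleast_1d(edge_pvalue(obs, expv))
    labels = model.node_labels or [str(i) for i in range(n)]
    table = pd.DataFrame(
        {
            "node1": [labels[i] for i in iu],
            "node2": [labels[j] for j in ju],
            "cluster1": model.c[iu],
            "cluster2": model.c[ju],
            "observed": obs,
            "expected": expv,
            "p_value": pvals,
            "neg_log10_p": _neg_log10(pvals),
            "intra_cluster": model.c[iu] == model.c[ju],
        }
    )
    if bh_correction and len(table):
        from statsmodels.stats.multitest import multipletests

        table["p_adjusted"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values("neg_log10_p", ascending=False, kind="mergesort").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    levels = sorted({0.01, 0.001, float(alpha)})
    table.attrs["n_significant"] = {a: int((table["p_value"] < a).sum()) for a in levels}
    table.attrs["alpha"] = float(alpha)
    return table


def cluster_connectivity(R) -> np.ndarray:
    """Row sums of the cluster similarity matrix (unit diagonal included).

    The cluster with the largest row sum is the network's hub cluster.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    return R.sum(axis=1)
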