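"""Reading and writing adjacency matrices and fit outputs.

Canonical table dialect: tab-separated, '.' decimal, UTF-8, Unix newlines;
comma-separated input is accepted on read.  Node identity is carried by
label strings, never by position, across all outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult
from .model import cpba_connectivity, network_connectivity

__all__ = [
    "LabeledAdjacency",
    "read_adjacency",
    "write_adjacency",
    "write_model",
]

_SYMMETRY_TOL = 1e-8


@dataclass
class LabeledAdjacency:
    """Adjacency values plus their ordered node labels."""

    values: np.ndarray
    labels: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _read_matrix(path, sep) -> LabeledAdjacency:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: matrix is not square ({df.shape[0]} rows x {df.shape[1]} columns)"
        )
    labels = [str(x) for x in df.index]
    if labels != [str(x) for x in df.columns]:
        raise ValueError(f"{path}: row and column labels disagree")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate node labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable matrix value ({exc})") from exc
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(f"{path}: negative entry at row {labels[i]!r}, column {labels[j]!r}")
    asym = float(np.max(np.abs(values - values.T))) if values.size else 0.0
    if asym > _SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix is asymmetric (max deviation {asym:.3g})")
    if asym > 0:
        warnings.warn(f"{path}: tiny asymmetry {asym:.3g} symmetrized by averaging")
        values = 0.5 * (values + values.T)
    return LabeledAdjacency(values=values, labels=labels)


def _read_edge_list(path, sep) -> LabeledAdjacency:
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[1] != 3:
        raise ValueError(f"{path}: edge list must have 3 columns, found {df.shape[1]}")
    df.columns = ["i", "j", "value"]
    try:
        vals = df["value"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable edge value ({exc})") from exc
    if (vals < 0).any():
        line = int(vals.lt(0).idxmax()) + 1
        raise ValueError(f"{path}: negative edge value on line {line}")
    labels: list[str] = []
    index: dict[str, int] = {}
    for node in pd.concat([df["i"].astype(str), df["j"].astype(str)]):
        if node not in index:
            index[node] = len(labels)
            labels.append(node)
    n = len(labels)
    A = np.zeros((n, n))
    n_loops = 0
    for a, b, v in zip(df["i"].astype(str), df["j"].astype(str), vals):
        if a == b:
            n_loops += 1
            continue
        ia, ib = index[a], index[b]
        A[ia, ib] += v
        A[ib, ia] += v
    if n_loops:
        warnings.warn(f"{path}: dropped {n_loops} self-loop(s)")
    return LabeledAdjacency(values=A, labels=labels)


def read_adjacency(path, format: str = "matrix_tsv", sep: str | None = None) -> LabeledAdjacency:
    """Read an adjacency matrix from a labeled square table or an undirected
    3-column edge list (duplicate pairs summed, missing pairs 0, self-loops
    dropped with a warning)."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    if format == "matrix_tsv":
        return _read_matrix(path, sep)
    if format == "edge_list":
        return _read_edge_list(path, sep)
    raise ValueError(f"unknown format {format!r} (expected 'matrix_tsv' or 'edge_list')")


def write_adjacency(path, values: np.ndarray, labels=None):
    """Write a labeled square adjacency table (TSV)."""
    values = np.asarray(values, dtype=float)
    labels = [str(x) for x in (labels if labels is not None else range(values.shape[0]))]
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t", lineterminator="\n")


def write_model(
    fit_result: FitResult,
    A: np.ndarray,
    outdir,
    config: dict | None = None,
    edges: pd.DataFrame | None = None,
) -> dict:
    """Write fitted-model outputs under ``outdir``.

    ``nodes.tsv`` (node, cluster, propensity, connectivity, model
    connectivity), ``cluster_similarity.tsv`` (labeled R over occupied
    cluster labels), ``summary.json`` (objective, K, cluster sizes, resolved
    config), and ``edges.tsv`` when a significance table is supplied.
    Returns the summary dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = fit_result.model
    n = model.n_nodes
    labels = model.node_labels or [str(i) for i in range(n)]
    A = np.asarray(A, dtype=float)
    nodes = pd.DataFrame(
        {
            "node": labels,
            "cluster": model.c,
            "propensity": model.p,
            "connectivity": network_connectivity(A),
            "cpba_connectivity": cpba_connectivity(model),
        }
    )
    nodes.to_csv(outdir / "nodes.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.12g")
    occupied = np.unique(model.c)
    r_labels = [str(a) for a in occupied]
    pd.DataFrame(model.R[np.ix_(occupied, occupied)], index=r_labels, columns=r_labels).to_csv(
        outdir / "cluster_similarity.tsv", sep="\t", lineterminator="\n", float_format="%.17g"
    )
    cluster_sizes = {int(a): int((model.c == a).sum()) for a in occupied}
    summary = {
        "objective_kind": model.objective_kind,
        "objective_value": model.objective_value,
        "trace_length": len(fit_result.objective_trace),
        "n_nodes": n,
        "n_clusters": model.n_clusters,
        "cluster_sizes": cluster_sizes,
        "converged": fit_result.converged,
        "n_cycles": fit_result.n_outer_iter,
        "moves_per_cycle": fit_result.n_moves_per_cycle,
        "config": config or {},
    }
    if edges is not None:
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.12g")
        summary["n_significant_edges"] = {
            str(a): v for a, v in edges.attrs.get("n_significant", {}).items()
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
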