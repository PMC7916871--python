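"""Explained variance of a chain graph.

How well does the detected network explain the data?  Each node is
regressed (OLS, with intercept) on its graph neighbors; the unadjusted
coefficient of determination R^2 is recorded per node and averaged over
*all* nodes — isolated nodes contribute 0 — giving the global "model
variance" of the graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .chains import ChainGraph, find_chains, merge_chains
from .correlate import correlation_matrix
from .dataio import DataMatrix

__all__ = ["VarianceReport", "SweepEntry", "model_variance", "alpha_sweep", "sweep_summary"]


@dataclass(frozen=True)
class VarianceReport:
    node_r2: Mapping[str, float]
    global_r2: float

    def to_frame(self, graph: ChainGraph | None = None) -> pd.DataFrame:
        rows = [
            {
                "node": v,
                "degree": graph.degree(v) if graph is not None else None,
                "r2": r2,
            }
            for v, r2 in sorted(self.node_r2.items())
        ]
        return pd.DataFrame(rows, columns=["node", "degree", "r2"])


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("collinear neighbors; R^2 from minimum-norm fit",
                      RuntimeWarning, stacklevel=2)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    r2 = 1.0 - float(resid @ resid) / tss
    return min(max(r2, 0.0), 1.0)


def model_variance(d: DataMatrix, g: ChainGraph) -> VarianceReport:
    """Per-node and global average R^2 of a graph against raw data."""
    missing = set(g.nodes) - set(d.var_names)
    if missing:
        raise KeyError(f"graph nodes absent from data: {sorted(missing)}")
    max_degree = max((g.degree(v) for v in g.nodes), default=0)
    if d.n_obs <= max_degree + 1:
        raise ValueError(
            f"n_obs = {d.n_obs} too small for max node degree {max_degree}"
        )
    node_r2 = {}
    for v in g.nodes:
        nbrs = g.neighbors(v)
        if not nbrs:
            node_r2[v] = 0.0
            continue
        y = d.column(v)
        X = np.column_stack([d.column(u) for u in nbrs])
        node_r2[v] = _ols_r2(y, X)
    global_r2 = float(np.mean(list(node_r2.values()))) if node_r2 else 0.0
    return VarianceReport(node_r2=node_r2, global_r2=global_r2)


class SweepEntry(NamedTuple):
    graph: ChainGraph
    variance: VarianceReport


def alpha_sweep(
    d: DataMatrix,
    alphas: Sequence[float],
    method: str = "spearman",
    abs_threshold: float = 0.1,
    consistency_filter: bool = True,
) -> dict[float, SweepEntry]:
    """Full chain analysis of the same data at several alpha thresholds.

    The correlation matrix is computed once; chain detection, merging and
    the variance report are repeated per alpha.  Use
    :func:`sweep_summary` for the edge-count / global-R^2 table.
    """
    if not alphas:
        raise ValueError("need at least one alpha")
    if any(not 0.0 < a < 1.0 for a in alphas):
        raise ValueError("alphas must lie in (0, 1)")
    c = correlation_matrix(d, method=method)
    out: dict[float, SweepEntry] = {}
    for a in alphas:
        chains = find_chains(c, alpha=a, abs_threshold=abs_threshold,
                             consistency_filter=consistency_filter)
        g = merge_chains(chains, c)
        out[float(a)] = SweepEntry(graph=g, variance=model_variance(d, g))
    return out


def sweep_summary(results: Mapping[float, SweepEntry]) -> pd.DataFrame:
    rows = [
        {"alpha": a, "n_edges": entry.graph.edge_count,
         "global_r2": entry.variance.global_r2}
        for a, entry in sorted(results.items())
    ]
    return pd.DataFrame(rows, columns=["alpha", "n_edges", "global_r2"])
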