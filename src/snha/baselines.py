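"""Baseline network builders and the null-data falseness experiment.

Two conventional ways of turning a data table into a network serve as
comparison points for the chain method: (a) keeping every pair whose
absolute correlation exceeds a threshold, and (b) per-variable forward
stepwise linear regression, connecting each target to its selected
predictors.  On null data (scrambled or iid normal) every edge is
spurious, so the per-replicate edge count is an indicator of falseness;
methods are compared by two-sided rank-sum tests on those counts with
Holm adjustment across all method pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .chains import ChainGraph, GraphEdge, snha
from .correlate import CorrMatrix, correlation_matrix
from .dataio import DataMatrix

__all__ = [
    "PairTest",
    "NetworkComparison",
    "threshold_network",
    "forward_lm_network",
    "count_spurious_edges",
    "standard_builders",
]


def threshold_network(c: CorrMatrix, r_min: float, alpha: float | None = None) -> ChainGraph:
    """Edge for every pair with |r| strictly above ``r_min``.

    When ``alpha`` is given the pair must additionally be significant at
    that level.  No chains are stored.
    """
    if not 0.0 <= r_min < 1.0:
        raise ValueError("r_min must lie in [0, 1)")
    edges: dict[tuple[str, str], GraphEdge] = {}
    for i in range(c.n_var):
        for j in range(i + 1, c.n_var):
            r = c.r[i, j]
            if abs(r) <= r_min:
                continue
            if alpha is not None and c.p[i, j] > alpha:
                continue
            a, b = sorted((c.var_names[i], c.var_names[j]))
            edges[(a, b)] = GraphEdge(sign=1 if r >= 0 else -1,
                                      weight=float(r), chains=())
    return ChainGraph(nodes=c.var_names, edges=edges, chains=())


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0
    return 1.0 - float(resid @ resid) / tss


def forward_lm_network(d: DataMatrix, r2_min: float, alpha: float = 0.05) -> ChainGraph:
    """Forward-selection linear-model network.

    For each target variable, predictors are added greedily: the candidate
    with the largest R^2 increase is accepted while the increase is at
    least ``r2_min`` *and* its partial F-test is significant at ``alpha``.
    Target-predictor pairs become undirected edges; the graph is the union
    over all targets.  Edge signs/weights come from the pairwise Pearson
    correlation of the two endpoints.
    """
    if not 0.0 < r2_min <= 1.0:
        raise ValueError("r2_min must lie in (0, 1]")
    n, vals, names = d.n_obs, d.values, d.var_names
    pairs: set[tuple[int, int]] = set()
    for ti in range(d.n_var):
        y = vals[:, ti]
        selected: list[int] = []
        remaining = [j for j in range(d.n_var) if j != ti]
        r2_cur = 0.0
        while remaining:
            best_j, best_r2 = -1, -np.inf
            for j in remaining:  # first-name wins exact ties
                r2_j = _r2(y, vals[:, selected + [j]])
                if r2_j > best_r2:
                    best_j, best_r2 = j, r2_j
            inc = best_r2 - r2_cur
            df_resid = n - (len(selected) + 1) - 1
            if inc < r2_min or df_resid <= 0:
                break
            if best_r2 >= 1.0 - 1e-12:  # perfect fit: F unbounded
                p_f = 0.0
            else:
                p_f = float(stats.f.sf(inc * df_resid / (1.0 - best_r2), 1, df_resid))
            if p_f > alpha:
                break
            selected.append(best_j)
            remaining.remove(best_j)
            r2_cur = best_r2
        for j in selected:
            pairs.add((min(ti, j), max(ti, j)))
    edges: dict[tuple[str, str], GraphEdge] = {}
    for i, j in pairs:
        r = float(np.corrcoef(vals[:, i], vals[:, j])[0, 1])
        a, b = sorted((names[i], names[j]))
        edges[(a, b)] = GraphEdge(sign=1 if r >= 0 else -1, weight=r, chains=())
    return ChainGraph(nodes=names, edges=edges, chains=())


def standard_builders(alpha: float = 0.05, r_threshold: float = 0.1,
                      abs_threshold: float = 0.1) -> dict[str, Callable[[DataMatrix], ChainGraph]]:
    """The five builders of the falseness comparison: chain analysis with
    Pearson and Spearman correlation, the |r| > 0.1 threshold network, and
    forward-selection models at R^2 thresholds 0.01 and 0.10."""
    return {
        "snha.p": lambda d: snha(d, method="pearson", alpha=alpha,
                                 abs_threshold=abs_threshold, lr_tests=False)[0],
        "snha.s": lambda d: snha(d, method="spearman", alpha=alpha,
                                 abs_threshold=abs_threshold, lr_tests=False)[0],
        "cor": lambda d: threshold_network(correlation_matrix(d, "pearson"), r_threshold),
        "lm.0.01": lambda d: forward_lm_network(d, 0.01, alpha),
        "lm.0.1": lambda d: forward_lm_network(d, 0.10, alpha),
    }


@dataclass(frozen=True)
class PairTest:
    statistic: float
    p_value: float
    p_adjusted: float


@dataclass(frozen=True)
class NetworkComparison:
    methods: tuple[str, ...]
    edge_counts: Mapping[str, tuple[int, ...]]
    pairwise: Mapping[tuple[str, str], PairTest]

    def median(self, method: str) -> float:
        return float(np.median(self.edge_counts[method]))


def _ranksum_p(x: Sequence[int], y: Sequence[int]) -> tuple[float, float]:
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:  # all observations tied: no evidence either way
        return float(len(x) * len(y) / 2.0), 1.0
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 use_continuity=True, method="asymptotic")
    return float(stat), float(p)


def count_spurious_edges(
    builders: Mapping[str, Callable[[DataMatrix], ChainGraph]],
    null_replicates: Sequence[DataMatrix],
) -> NetworkComparison:
    """Edge counts per builder per null replicate, with pairwise tests.

    Every builder is applied to every replicate; the count distributions
    are compared for all builder pairs by two-sided continuity-corrected
    rank-sum tests, Holm-adjusted across the pairs.
    """
    if len(null_replicates) < 2:
        raise ValueError("need at least 2 null replicates")
    methods = tuple(sorted(builders))
    counts = {
        m: tuple(builders[m](d).edge_count for d in null_replicates) for m in methods
    }
    pairs = list(combinations(methods, 2))
    raw = [_ranksum_p(counts[a], counts[b]) for a, b in pairs]
    if pairs:
        _, adj, _, _ = multipletests([p for _, p in raw], method="holm")
    else:
        adj = []
    pairwise = {
        pair: PairTest(statistic=stat, p_value=p, p_adjusted=float(pa))
        for pair, (stat, p), pa in zip(pairs, raw, adj)
    }
    return NetworkComparison(methods=methods, edge_counts=counts, pairwise=pairwise)
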