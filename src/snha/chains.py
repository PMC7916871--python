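"""The St. Nicolas House Analysis (SNHA) chain algorithm.

SNHA detects *association chains* in a correlation matrix: ordered
variable sequences obtained by repeatedly stepping from the current
variable to the not-yet-visited variable with the largest absolute
correlation to it, as long as that correlation clears an absolute
threshold (default 0.1) and is significant at the chosen alpha.  A
sequence qualifies as an association chain only if it is *reversible*:
growing a sequence from its last element must reproduce exactly the
reversed sequence.  Reversibility is what separates genuine serial
dependence from the arbitrary orderings any greedy walk would produce.

All accepted chains (length >= 3, deduplicated up to reversal) are merged
into an undirected signed graph — the St. Nicolas House graph — whose
edges are the consecutive pairs of the chains, signed by the correlation
coefficient, with per-edge provenance recording which chains contributed
it.

Only the correlation matrix and the sample size are needed, never the raw
data, which makes the method applicable to published aggregate results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .correlate import CorrMatrix, correlation_matrix
from .dataio import DataMatrix, GraphExport

__all__ = [
    "Chain",
    "GraphEdge",
    "ChainGraph",
    "grow_sequence",
    "is_reversible",
    "find_chains",
    "merge_chains",
    "snha",
]


@dataclass(frozen=True)
class Chain:
    """An ordered variable sequence that passed the reversibility check.

    A chain and its reversal denote the same object; :meth:`canonical`
    orients the lexicographically smaller endpoint first.
    """

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(str(v) for v in self.members)
        object.__setattr__(self, "members", members)
        if len(members) < 2:
            raise ValueError("a chain needs at least two members")
        if len(set(members)) != len(members):
            raise ValueError("chain members must be distinct")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def canonical(self) -> "Chain":
        if self.members[-1] < self.members[0]:
            return Chain(self.members[::-1])
        return self

    def pairs(self) -> list[tuple[str, str]]:
        """Consecutive (adjacent) member pairs, in chain order."""
        return list(zip(self.members[:-1], self.members[1:]))

    def label(self) -> str:
        return "-".join(self.members)


@dataclass(frozen=True)
class GraphEdge:
    sign: int
    weight: float
    chains: tuple[int, ...]  # indices of contributing chains


@dataclass(frozen=True)
class ChainGraph:
    """Undirected signed graph formed by merging association chains.

    ``edges`` maps unordered name pairs (smaller name first) to
    :class:`GraphEdge`; isolated variables stay in ``nodes``.  Baseline
    network builders reuse this container with an empty chain list.
    """

    nodes: tuple[str, ...]
    edges: Mapping[tuple[str, str], GraphEdge]
    chains: tuple[Chain, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(str(v) for v in self.nodes))
        object.__setattr__(self, "edges", dict(self.edges))
        object.__setattr__(self, "chains", tuple(self.chains))
        nodeset = set(self.nodes)
        for (a, b) in self.edges:
            if a >= b:
                raise ValueError(f"edge key not canonically ordered: {(a, b)}")
            if a not in nodeset or b not in nodeset:
                raise ValueError(f"edge endpoint not a node: {(a, b)}")

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.edges

    def neighbors(self, v: str) -> list[str]:
        out = [b if a == v else a for (a, b) in self.edges if v in (a, b)]
        return sorted(out)

    def degree(self, v: str) -> int:
        return len(self.neighbors(v))

    def edge_pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def to_export(self, node_r2: Mapping[str, float] | None = None) -> GraphExport:
        edges = tuple(
            (a, b, e.sign, e.weight) for (a, b), e in sorted(self.edges.items())
        )
        return GraphExport(self.nodes, edges, node_r2)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), e in self.edges.items():
            g.add_edge(a, b, sign=e.sign, weight=e.weight)
        return g


def _admissible(c: CorrMatrix, i: int, j: int, alpha: float, abs_threshold: float) -> bool:
    return abs(c.r[i, j]) >= abs_threshold and c.p[i, j] <= alpha


def grow_sequence(
    c: CorrMatrix,
    start: str,
    alpha: float = 0.05,
    abs_threshold: float = 0.1,
) -> list[str]:
    """Greedy descending-|r| walk from ``start``.

    From the current variable the walk moves to the unvisited variable
    with the largest |r| to it.  It stops when that best candidate falls
    below ``abs_threshold``, is insignificant at ``alpha``, or no
    unvisited variable remains.  Ties in |r| are broken toward the
    variable earliest in ``var_names`` order, which makes the walk
    deterministic (ties have measure zero on real-valued data).
    """
    try:
        cur = c.index(start)
    except ValueError:
        raise KeyError(f"unknown start variable: {start!r}") from None
    rho = c.rho
    unvisited = np.ones(c.n_var, dtype=bool)
    unvisited[cur] = False
    seq = [cur]
    while unvisited.any():
        row = np.where(unvisited, rho[cur], -np.inf)
        nxt = int(np.argmax(row))  # first max = earliest name on ties
        if not _admissible(c, cur, nxt, alpha, abs_threshold):
            break
        seq.append(nxt)
        unvisited[nxt] = False
        cur = nxt
    return [c.var_names[i] for i in seq]


def is_reversible(
    c: CorrMatrix,
    seq: Sequence[str],
    alpha: float = 0.05,
    abs_threshold: float = 0.1,
) -> bool:
    """True iff the walk from the last element reproduces exactly the
    reversed sequence (neither diverging nor extending past the start)."""
    if len(seq) < 2:
        raise ValueError("reversibility needs a sequence of length >= 2")
    back = grow_sequence(c, seq[-1], alpha=alpha, abs_threshold=abs_threshold)
    return back == list(seq)[::-1]


def _orderings_consistent(a: Chain, b: Chain) -> bool:
    """Whether two chains order their shared variables compatibly.

    Chains are orientation-free (a chain equals its reversal), so the
    induced order of the shared variables in one chain must match the
    induced order in the other either forwards or backwards.
    """
    shared = set(a.members) & set(b.members)
    if len(shared) < 2:
        return True
    in_a = [v for v in a.members if v in shared]
    in_b = [v for v in b.members if v in shared]
    return in_b == in_a or in_b == in_a[::-1]


def _filter_consistent(chains: list[Chain]) -> list[Chain]:
    # longer chains win conflicts; equal lengths keep the lexicographically
    # smaller canonical form
    ordered = sorted(chains, key=lambda ch: (-len(ch), ch.members))
    kept: list[Chain] = []
    for ch in ordered:
        if all(_orderings_consistent(ch, other) for other in kept):
            kept.append(ch)
    return kept


def find_chains(
    c: CorrMatrix,
    alpha: float = 0.05,
    abs_threshold: float = 0.1,
    consistency_filter: bool = True,
) -> list[Chain]:
    """Detect all association chains of a correlation matrix.

    Every variable is tried as a start; the greedy walk is kept when it
    has at least 3 members and passes the reversibility check.  Chains are
    deduplicated up to reversal (canonical orientation: lexicographically
    smaller endpoint first).  With ``consistency_filter`` on (default),
    chains that order a shared variable pair incompatibly are resolved by
    dropping the shorter chain — an ordering established by one chain
    predetermines the ordering of those variables in every other chain.
    The result is sorted by member tuple, so output order is deterministic.
    """
    seen: set[tuple[str, ...]] = set()
    accepted: list[Chain] = []
    for start in c.var_names:
        seq = grow_sequence(c, start, alpha=alpha, abs_threshold=abs_threshold)
        if len(seq) < 3:
            continue
        if not is_reversible(c, seq, alpha=alpha, abs_threshold=abs_threshold):
            continue
        chain = Chain(tuple(seq)).canonical()
        if chain.members not in seen:
            seen.add(chain.members)
            accepted.append(chain)
    if consistency_filter:
        accepted = _filter_consistent(accepted)
    return sorted(accepted, key=lambda ch: ch.members)


def merge_chains(chains: Iterable[Chain], c: CorrMatrix) -> ChainGraph:
    """Union the consecutive pairs of all chains into the final graph.

    Each edge keeps the sign and value of the correlation coefficient plus
    the indices of every chain containing it; variables in no chain remain
    as isolated nodes.
    """
    chains = tuple(chains)
    names = set(c.var_names)
    provenance: dict[tuple[str, str], list[int]] = {}
    for ci, ch in enumerate(chains):
        for u, v in ch.pairs():
            if u not in names or v not in names:
                missing = u if u not in names else v
                raise KeyError(f"chain references unknown variable: {missing!r}")
            key = (u, v) if u < v else (v, u)
            provenance.setdefault(key, []).append(ci)
    edges = {}
    for (a, b), ids in provenance.items():
        r = c.r[c.index(a), c.index(b)]
        edges[(a, b)] = GraphEdge(sign=1 if r >= 0 else -1, weight=float(r),
                                  chains=tuple(ids))
    return ChainGraph(nodes=c.var_names, edges=edges, chains=chains)


def snha(
    data: DataMatrix | CorrMatrix,
    method: str = "spearman",
    alpha: float = 0.05,
    abs_threshold: float = 0.1,
    consistency_filter: bool = True,
    lr_tests: bool = True,
):
    """One-call facade: correlation -> chains -> merged graph -> LR tests.

    Accepts either raw data or a precomputed :class:`CorrMatrix` (the
    aggregate-only pathway; likelihood-ratio tests then use the stored
    sample size).  Returns ``(graph, results)`` where ``results`` is a
    list of per-chain likelihood-ratio test results (empty when
    ``lr_tests`` is off).
    """
    from .likelihood import chain_lr_test

    c = data if isinstance(data, CorrMatrix) else correlation_matrix(data, method=method)
    chains = find_chains(c, alpha=alpha, abs_threshold=abs_threshold,
                         consistency_filter=consistency_filter)
    graph = merge_chains(chains, c)
    results = [chain_lr_test(ch, c) for ch in chains] if lr_tests else []
    return graph, results
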