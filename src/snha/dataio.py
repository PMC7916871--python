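"""Reading and writing the tabular, matrix and graph artifacts.

The analysis consumes either a rectangular observations-by-variables table
(CSV/TSV with a header row) or a precomputed symmetric correlation matrix
with a known sample size.  Result graphs are written as plain-text edge
lists, Graphviz DOT, GraphML or signed adjacency matrices; every writer
sorts nodes and edges lexicographically so repeated runs produce
byte-identical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "GraphExport",
    "read_data",
    "read_corr",
    "write_graph",
    "read_graph",
]

_GRAPH_FORMATS = ("edgelist", "dot", "graphml", "adjacency")


def _sniff_sep(path: str | Path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


@dataclass(frozen=True)
class DataMatrix:
    """An observations x variables numeric table with column names.

    Invariants: variable names are unique, there are at least two
    variables, and every entry is finite (missing data are handled by the
    reader before construction).
    """

    values: np.ndarray
    var_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "var_names", tuple(str(v) for v in self.var_names))
        if values.ndim != 2:
            raise ValueError("data matrix must be two-dimensional")
        if len(self.var_names) != values.shape[1]:
            raise ValueError("number of variable names does not match columns")
        if len(set(self.var_names)) != len(self.var_names):
            raise ValueError("duplicate variable names")
        if values.shape[1] < 2:
            raise ValueError("need at least two variables")
        if not np.all(np.isfinite(values)):
            raise ValueError("data matrix contains non-finite entries")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_var(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.var_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.var_names))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DataMatrix":
        return cls(frame.to_numpy(dtype=float), tuple(str(c) for c in frame.columns))


def read_data(
    path: str | Path,
    missing_policy: str = "drop_rows",
    sep: str | None = None,
    index_col: int | None = None,
) -> DataMatrix:
    """Read a delimited numeric table into a :class:`DataMatrix`.

    ``missing_policy`` is ``"drop_rows"`` (complete-case: any row with a
    missing or non-numeric cell is removed) or ``"error"``.  The delimiter
    is sniffed from the file extension (``.tsv``/``.tab``/``.txt`` are
    tab-separated, everything else comma) unless ``sep`` is given.
    ``index_col`` marks a row-label column that is not a variable.
    """
    if missing_policy not in {"drop_rows", "error"}:
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    frame = pd.read_csv(path, sep=sep or _sniff_sep(path), index_col=index_col)
    coerced = frame.apply(pd.to_numeric, errors="coerce")
    if missing_policy == "error":
        if coerced.isna().any().any():
            bad = [str(c) for c in coerced.columns[coerced.isna().any()]]
            raise ValueError(f"missing or non-numeric cells in columns: {', '.join(bad)}")
    else:
        coerced = coerced.dropna(axis=0)
    if len(coerced) < 3:
        raise ValueError(
            f"only {len(coerced)} complete rows retained; "
            "correlation needs at least 3"
        )
    return DataMatrix.from_frame(coerced)


def read_corr(
    path: str | Path,
    n: int,
    method: str = "pearson",
    sep: str | None = None,
):
    """Read a symmetric correlation matrix with row/column names.

    The file must carry variable names in both the header row and the
    first column, and those must match.  ``n`` is the sample size the
    correlations were computed from; it is required because significance
    levels and likelihood-ratio tests are derived from ``r`` and ``n``.
    """
    from .correlate import CorrMatrix  # local import avoids a cycle

    if n < 4:
        raise ValueError("sample size n must be at least 4")
    frame = pd.read_csv(path, sep=sep or _sniff_sep(path), index_col=0)
    cols = [str(c) for c in frame.columns]
    rows = [str(r) for r in frame.index]
    if cols != rows:
        raise ValueError("header and first-column variable names do not match")
    m = frame.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("correlation matrix is not square")
    if np.max(np.abs(m - m.T)) > 1e-8:
        raise ValueError("correlation matrix is asymmetric beyond tolerance 1e-8")
    if np.max(np.abs(np.diag(m) - 1.0)) > 1e-8:
        raise ValueError("correlation matrix diagonal is not 1")
    if np.max(np.abs(m)) > 1.0 + 1e-8:
        raise ValueError("correlation entries must lie in [-1, 1]")
    r = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrMatrix.from_r(r, n=int(n), var_names=tuple(cols), method=method)


@dataclass(frozen=True)
class GraphExport:
    """A plain, serializable undirected signed graph.

    Edges are unordered pairs stored with the lexicographically smaller
    endpoint first; ``sign`` is +1/-1 and must agree with the sign of the
    (correlation) weight.  ``node_r2`` optionally carries per-node
    explained variance for renderers.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int, float], ...]
    node_r2: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        nodes = tuple(sorted(str(v) for v in self.nodes))
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate nodes")
        norm = []
        for a, b, sign, weight in self.edges:
            a, b = str(a), str(b)
            if a > b:
                a, b = b, a
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge endpoint not declared as node: {a!r}-{b!r}")
            sign = int(sign)
            if sign not in (-1, 1):
                raise ValueError("edge sign must be +1 or -1")
            weight = float(weight)
            if weight != 0.0 and int(np.sign(weight)) != sign:
                raise ValueError(f"sign/weight mismatch on edge {a!r}-{b!r}")
            norm.append((a, b, sign, weight))
        norm.sort()
        if len({(a, b) for a, b, _, _ in norm}) != len(norm):
            raise ValueError("duplicate edges")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", tuple(norm))
        if self.node_r2 is not None:
            object.__setattr__(
                self, "node_r2", {str(k): float(v) for k, v in self.node_r2.items()}
            )


def _fmt(x: float) -> str:
    return format(x, ".17g")


def _write_edgelist(g: GraphExport, path: Path) -> None:
    lines = ["# nodes: " + "\t".join(g.nodes), "node_a\tnode_b\tsign\tweight"]
    for a, b, sign, weight in g.edges:
        lines.append(f"{a}\t{b}\t{sign}\t{_fmt(weight)}")
    path.write_text("\n".join(lines) + "\n")


def _read_edgelist(path: Path) -> GraphExport:
    lines = path.read_text().splitlines()
    nodes: tuple[str, ...] = ()
    edges = []
    for line in lines:
        if line.startswith("# nodes:"):
            rest = line[len("# nodes:") :].strip()
            nodes = tuple(rest.split("\t")) if rest else ()
        elif line and not line.startswith("#") and not line.startswith("node_a\t"):
            a, b, sign, weight = line.split("\t")
            edges.append((a, b, int(sign), float(weight)))
    return GraphExport(nodes, tuple(edges))


def _write_dot(g: GraphExport, path: Path) -> None:
    # red edges mark negative correlations, matching the convention the
    # result figures use; r2 node shading is carried as an attribute
    lines = ["graph snha {"]
    for v in g.nodes:
        if g.node_r2 is not None and v in g.node_r2:
            lines.append(f'  "{v}" [r2="{_fmt(g.node_r2[v])}"];')
        else:
            lines.append(f'  "{v}";')
    for a, b, sign, weight in g.edges:
        color = "red" if sign < 0 else "black"
        lines.append(f'  "{a}" -- "{b}" [color={color}, weight="{_fmt(weight)}"];')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


_DOT_EDGE = re.compile(r'^\s*"(.*)" -- "(.*)" \[color=(\w+), weight="([^"]+)"\];$')
_DOT_NODE = re.compile(r'^\s*"(.*?)"(?: \[r2="([^"]+)"\])?;$')


def _read_dot(path: Path) -> GraphExport:
    nodes, edges, node_r2 = [], [], {}
    for line in path.read_text().splitlines():
        m = _DOT_EDGE.match(line)
        if m:
            a, b, color, weight = m.groups()
            edges.append((a, b, -1 if color == "red" else 1, float(weight)))
            continue
        m = _DOT_NODE.match(line)
        if m:
            nodes.append(m.group(1))
            if m.group(2) is not None:
                node_r2[m.group(1)] = float(m.group(2))
    return GraphExport(tuple(nodes), tuple(edges), node_r2 or None)


def _write_graphml(g: GraphExport, path: Path) -> None:
    gr = nx.Graph()
    for v in g.nodes:
        if g.node_r2 is not None and v in g.node_r2:
            gr.add_node(v, r2=float(g.node_r2[v]))
        else:
            gr.add_node(v)
    for a, b, sign, weight in g.edges:
        gr.add_edge(a, b, sign=int(sign), weight=float(weight))
    nx.write_graphml(gr, path)


def _read_graphml(path: Path) -> GraphExport:
    gr = nx.read_graphml(path)
    node_r2 = {
        str(v): float(d["r2"]) for v, d in gr.nodes(data=True) if "r2" in d
    }
    edges = tuple(
        (str(a), str(b), int(d["sign"]), float(d["weight"]))
        for a, b, d in gr.edges(data=True)
    )
    return GraphExport(tuple(str(v) for v in gr.nodes), edges, node_r2 or None)


def _write_adjacency(g: GraphExport, path: Path) -> None:
    idx = {v: i for i, v in enumerate(g.nodes)}
    m = np.zeros((len(g.nodes), len(g.nodes)))
    for a, b, _sign, weight in g.edges:
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = weight
    pd.DataFrame(m, index=list(g.nodes), columns=list(g.nodes)).to_csv(path)


def _read_adjacency(path: Path) -> GraphExport:
    frame = pd.read_csv(path, index_col=0)
    nodes = tuple(str(c) for c in frame.columns)
    m = frame.to_numpy(dtype=float)
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if m[i, j] != 0.0:
                edges.append((nodes[i], nodes[j], int(np.sign(m[i, j])), m[i, j]))
    return GraphExport(nodes, tuple(edges))


def write_graph(g, path: str | Path, format: str = "edgelist") -> Path:
    """Write a graph to ``path`` in one of the supported text formats.

    ``g`` may be a :class:`GraphExport` or any object with a
    ``to_export()`` method (such as a chain graph).  Formats: ``edgelist``
    (TSV), ``dot`` (Graphviz, negative edges colored red), ``graphml``,
    ``adjacency`` (signed CSV matrix).
    """
    if not isinstance(g, GraphExport):
        g = g.to_export()
    if format not in _GRAPH_FORMATS:
        raise ValueError(f"unknown graph format: {format!r}")
    path = Path(path)
    {"edgelist": _write_edgelist, "dot": _write_dot,
     "graphml": _write_graphml, "adjacency": _write_adjacency}[format](g, path)
    return path


def read_graph(path: str | Path, format: str = "edgelist") -> GraphExport:
    """Read a graph previously written by :func:`write_graph`."""
    if format not in _GRAPH_FORMATS:
        raise ValueError(f"unknown graph format: {format!r}")
    path = Path(path)
    return {"edgelist": _read_edgelist, "dot": _read_dot,
            "graphml": _read_graphml, "adjacency": _read_adjacency}[format](path)
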