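import numpy as np
import pytest

from snha import GraphExport, read_corr, read_data, read_graph, write_graph

# first six rows of the 1988 Olympic decathlon results (speeds in km/h,
# distances in m) — exercises a row-label column and numeric parsing
DECATHLON6 = """\
Athlete,100,long,shot,high,400,110,disq,pole,jave,1500
1,32.00,7.43,15.48,2.27,29.45,26.17,49.28,4.7,61.32,20.08
2,33.12,7.45,14.97,1.97,30.18,27.39,44.36,5.1,61.76,19.78
3,32.20,7.44,14.20,1.97,29.82,26.74,43.66,5.2,64.16,20.52
4,33.90,7.38,15.02,2.03,29.35,26.90,44.80,4.9,64.04,18.94
5,32.67,7.43,12.92,1.97,30.35,27.50,41.20,5.2,57.46,21.04
6,33.24,7.72,13.58,2.12,29.79,27.93,43.06,4.9,52.18,19.70
"""


def test_read_data_decathlon_excerpt(tmp_path):
    f = tmp_path / "dec.csv"
    f.write_text(DECATHLON6)
    d = read_data(f, index_col=0)
    assert d.n_obs == 6 and d.n_var == 10
    assert d.var_names == ("100", "long", "shot", "high", "400", "110",
                           "disq", "pole", "jave", "1500")
    assert d.column("shot")[0] == pytest.approx(15.48)


def test_read_data_missing_policies(tmp_path):
    f = tmp_path / "m.csv"
    f.write_text("a,b\n1,2\n3,\n4,5\n6,7\n")
    d = read_data(f, missing_policy="drop_rows")
    assert d.n_obs == 3  # row with the empty cell dropped
    with pytest.raises(ValueError, match="missing or non-numeric"):
        read_data(f, missing_policy="error")
    with pytest.raises(ValueError):
        read_data(f, missing_policy="bogus")


def test_read_data_too_few_rows(tmp_path):
    f = tmp_path / "short.csv"
    f.write_text("a,b\n1,2\n3,4\n")
    with pytest.raises(ValueError, match="complete rows"):
        read_data(f)


def test_read_data_accepts_constant_columns(tmp_path):
    # the reader accepts constants; only correlation rejects them
    f = tmp_path / "const.csv"
    f.write_text("a,b\n1,1\n1,2\n1,3\n1,4\n")
    d = read_data(f)
    assert d.n_obs == 4
    from snha import correlation_matrix

    with pytest.raises(ValueError, match="zero-variance"):
        correlation_matrix(d)


def _write_corr_csv(path, m, names):
    lines = ["," + ",".join(names)]
    for name, row in zip(names, m):
        lines.append(name + "," + ",".join(repr(float(x)) for x in row))
    path.write_text("\n".join(lines) + "\n")


def test_read_corr_valid_and_identity(tmp_path):
    m = np.array([[1.0, 0.9, 0.6, 0.3], [0.9, 1.0, 0.7, 0.4],
                  [0.6, 0.7, 1.0, 0.5], [0.3, 0.4, 0.5, 1.0]])
    f = tmp_path / "c.csv"
    _write_corr_csv(f, m, list("ABCD"))
    c = read_corr(f, n=100)
    assert c.n == 100 and c.var_names == ("A", "B", "C", "D")
    np.testing.assert_allclose(c.r, m)

    f2 = tmp_path / "eye.csv"
    _write_corr_csv(f2, np.eye(5), list("ABCDE"))
    c2 = read_corr(f2, n=50)
    off = ~np.eye(5, dtype=bool)
    assert np.all(c2.p[off] == 1.0)  # r = 0 gives t = 0, p = 1


@pytest.mark.parametrize(
    "mutate, msg",
    [
        (lambda m: m.__setitem__((0, 1), 1.2) or m.__setitem__((1, 0), 1.2), "\\[-1, 1\\]"),
        (lambda m: m.__setitem__((0, 1), 0.5), "asymmetric"),
        (lambda m: m.__setitem__((0, 0), 0.9), "diagonal"),
    ],
)
def test_read_corr_rejects_invalid(tmp_path, mutate, msg):
    m = np.array([[1.0, 0.2, 0.1], [0.2, 1.0, 0.3], [0.1, 0.3, 1.0]])
    mutate(m)
    f = tmp_path / "bad.csv"
    _write_corr_csv(f, m, list("ABC"))
    with pytest.raises(ValueError, match=msg):
        read_corr(f, n=30)


def test_read_corr_name_mismatch(tmp_path):
    f = tmp_path / "names.csv"
    f.write_text(",A,B\nA,1.0,0.5\nC,0.5,1.0\n")
    with pytest.raises(ValueError, match="do not match"):
        read_corr(f, n=30)


@pytest.fixture
def export():
    return GraphExport(
        nodes=("A", "B", "C", "D", "E"),  # E isolated
        edges=(("A", "B", 1, 0.9), ("B", "C", -1, -0.7), ("C", "D", 1, 0.5)),
        node_r2={"A": 0.25, "B": 0.5},
    )


@pytest.mark.parametrize("fmt", ["edgelist", "dot", "graphml", "adjacency"])
def test_graph_round_trip(tmp_path, export, fmt):
    path = write_graph(export, tmp_path / f"g.{fmt}", fmt)
    back = read_graph(path, fmt)
    assert back.nodes == export.nodes
    assert [(a, b, s) for a, b, s, _ in back.edges] == [
        (a, b, s) for a, b, s, _ in export.edges
    ]
    np.testing.assert_allclose(
        [w for *_, w in back.edges], [w for *_, w in export.edges], atol=1e-12
    )
    if fmt in {"graphml", "dot"}:
        assert back.node_r2 == export.node_r2


@pytest.mark.parametrize("fmt", ["edgelist", "dot", "graphml", "adjacency"])
def test_graph_write_deterministic(tmp_path, export, fmt):
    a = write_graph(export, tmp_path / "a", fmt).read_bytes()
    b = write_graph(export, tmp_path / "b", fmt).read_bytes()
    assert a == b


def test_dot_marks_negative_edges_red(tmp_path, export):
    text = write_graph(export, tmp_path / "g.dot", "dot").read_text()
    assert '"B" -- "C" [color=red' in text
    assert text.count("color=red") == 1


def test_empty_graph_and_unknown_format(tmp_path):
    g = GraphExport(nodes=("A", "B"), edges=())
    path = write_graph(g, tmp_path / "empty.tsv", "edgelist")
    assert read_graph(path, "edgelist") == g
    with pytest.raises(ValueError, match="unknown graph format"):
        write_graph(g, tmp_path / "x", "yaml")


def test_graph_export_validation():
    with pytest.raises(ValueError, match="not declared"):
        GraphExport(nodes=("A",), edges=(("A", "B", 1, 0.5),))
    with pytest.raises(ValueError, match="sign/weight"):
        GraphExport(nodes=("A", "B"), edges=(("A", "B", 1, -0.5),))
    # unordered input is canonicalized
    g = GraphExport(nodes=("B", "A"), edges=(("B", "A", 1, 0.5),))
    assert g.nodes == ("A", "B") and g.edges[0][:2] == ("A", "B")
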