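import numpy as np
import pytest

from snha import (
    Chain,
    correlation_matrix,
    DataMatrix,
    find_chains,
    generate_planted,
    grow_sequence,
    is_reversible,
    merge_chains,
    planted_path,
    snha,
)
from snha.chains import _filter_consistent, _orderings_consistent

from conftest import make_corr, random_corrmatrix
from oracles import enumerate_chains


def test_grow_sequence_hand_trace(corr4):
    # |r|: AB=.9 > AC=.6 > AD=.3; from B the best unvisited is C (.7),
    # then D (.5): the greedy walk visits in descending-|r| order
    assert grow_sequence(corr4, "A") == ["A", "B", "C", "D"]
    assert grow_sequence(corr4, "D") == ["D", "C", "B", "A"]


def test_grow_sequence_stops_on_identity(identity_corr):
    assert grow_sequence(identity_corr, "C") == ["C"]


def test_grow_sequence_threshold_and_alpha_stop(corr4):
    # a high |r| floor truncates the walk; AD=.3 and BD=.4 never qualify
    assert grow_sequence(corr4, "A", abs_threshold=0.65) == ["A", "B", "C"]
    # tiny alpha disqualifies D's best pair (CD=.5, p ~ 1e-7 at n=100)
    assert grow_sequence(corr4, "D", alpha=1e-12) == ["D"]


def test_grow_sequence_unknown_start(corr4):
    with pytest.raises(KeyError):
        grow_sequence(corr4, "Z")


def test_reversible_chain(corr4):
    # reverse walk from D: DC=.5 > DB=.4 > DA=.3 retraces the sequence
    assert is_reversible(corr4, ["A", "B", "C", "D"])


def test_isolated_pair_is_reversible():
    # a pair with no other admissible partner retraces itself trivially
    r = np.eye(4)
    r[2, 3] = r[3, 2] = 0.5
    c = make_corr(r, n=100)
    assert is_reversible(c, ["C", "D"])
    assert find_chains(c) == []  # but it is too short to be a chain


def test_reverse_walk_divergence_breaks_chain():
    # same forward walk A,B,C,D but now DB=.6 > DC=.5: the reverse walk
    # jumps D -> B first, so the sequence is not an association chain
    r = np.array(
        [
            [1.0, 0.9, 0.2, 0.1],
            [0.9, 1.0, 0.7, 0.6],
            [0.2, 0.7, 1.0, 0.5],
            [0.1, 0.6, 0.5, 1.0],
        ]
    )
    c = make_corr(r, n=100)
    assert grow_sequence(c, "A") == ["A", "B", "C", "D"]
    assert not is_reversible(c, ["A", "B", "C", "D"])
    assert find_chains(c) == []


def test_find_chains_identity_empty(identity_corr):
    assert find_chains(identity_corr) == []


def test_find_chains_hand_example(corr4):
    chains = find_chains(corr4)
    assert [ch.members for ch in chains] == [("A", "B", "C", "D")]


def test_find_chains_recovers_planted_path():
    d = generate_planted(planted_path(seed=11))
    g, _ = snha(d)
    expected = {("X1", "X2"), ("X2", "X3"), ("X3", "X4"), ("X4", "X5")}
    assert set(g.edges) == expected
    assert all(len(ch) >= 3 for ch in g.chains)


@pytest.mark.parametrize("seed", range(5))
def test_outputs_pass_reversibility_and_thresholds(seed):
    rng = np.random.default_rng(seed)
    c = random_corrmatrix(rng, n_var=int(rng.integers(4, 8)))
    alpha, thr = 0.05, 0.1
    chains = find_chains(c, alpha=alpha, abs_threshold=thr)
    for ch in chains:
        assert is_reversible(c, ch.members, alpha=alpha, abs_threshold=thr)
    g = merge_chains(chains, c)
    for (a, b), e in g.edges.items():
        i, j = c.index(a), c.index(b)
        assert abs(c.r[i, j]) >= thr and c.p[i, j] <= alpha
        assert e.sign == (1 if c.r[i, j] >= 0 else -1)


@pytest.mark.parametrize("seed", range(40))
def test_brute_force_oracle_agreement(seed):
    rng = np.random.default_rng(1000 + seed)
    c = random_corrmatrix(rng, n_var=int(rng.integers(3, 7)))
    got = {ch.members for ch in find_chains(c, consistency_filter=False)}
    assert got == enumerate_chains(c)


def test_permutation_equivariance():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((40, 6)) + rng.standard_normal((40, 1))
    names = [f"v{i}" for i in range(6)]
    d = DataMatrix(X, names)
    perm = rng.permutation(6)
    d2 = DataMatrix(X[:, perm], [names[i] for i in perm])
    c1 = correlation_matrix(d, "pearson")
    c2 = correlation_matrix(d2, "pearson")
    assert {ch.members for ch in find_chains(c1)} == {
        ch.members for ch in find_chains(c2)
    }


def test_orderings_consistency_rules():
    a = Chain(("A", "B", "C", "D"))
    assert _orderings_consistent(a, Chain(("B", "C", "E")))
    assert _orderings_consistent(a, Chain(("E", "C", "B")))  # reversed view
    # two shared variables can always be reconciled by flipping one chain
    assert _orderings_consistent(a, Chain(("C", "E", "A")))
    assert _orderings_consistent(a, Chain(("E", "F", "B")))  # one shared var
    # three shared variables in an incompatible interleaving cannot
    assert not _orderings_consistent(a, Chain(("A", "C", "B", "E")))
    assert not _orderings_consistent(a, Chain(("E", "B", "C", "A")))


def test_consistency_filter_drops_shorter():
    long = Chain(("A", "B", "C", "D"))
    clash = Chain(("A", "C", "B"))  # interleaves B and C against the long chain
    ok = Chain(("B", "C", "E"))
    kept = _filter_consistent([long, clash, ok])
    assert long in kept and ok in kept and clash not in kept
    # equal lengths: the lexicographically smaller canonical form survives
    x, y = Chain(("A", "B", "C")), Chain(("B", "A", "C"))
    assert not _orderings_consistent(x, y)
    assert _filter_consistent([y, x]) == [x]


def test_merge_chains_union_and_provenance(corr4):
    chains = [Chain(("A", "B", "C")), Chain(("B", "C", "D"))]
    g = merge_chains(chains, corr4)
    assert set(g.edges) == {("A", "B"), ("B", "C"), ("C", "D")}
    assert g.edges[("B", "C")].chains == (0, 1)
    assert g.edges[("A", "B")].chains == (0,)
    assert g.edges[("A", "B")].weight == pytest.approx(0.9)


def test_merge_chains_empty_and_unknown(corr4, identity_corr):
    g = merge_chains([], identity_corr)
    assert g.edge_count == 0 and len(g.nodes) == 5
    with pytest.raises(KeyError, match="unknown variable"):
        merge_chains([Chain(("A", "Z", "B"))], corr4)


def test_snha_on_corrmatrix_aggregate_only(corr4):
    # the aggregate-only pathway: no raw data, LR tests from r and n
    g, results = snha(corr4)
    assert set(g.edges) == {("A", "B"), ("B", "C"), ("C", "D")}
    assert len(results) == 1 and results[0].df == 3


def test_snha_null_data_mostly_empty():
    rng = np.random.default_rng(5)
    d = DataMatrix(rng.standard_normal((33, 5)), [f"v{i}" for i in range(5)])
    g, _ = snha(d)
    assert g.edge_count <= 2  # iid noise: chains are rare
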