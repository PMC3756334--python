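import itertools

import numpy as np
import pytest

from stemward.matrix import CharacterMatrix, StemwardError
from stemward.parsimony import (
    SearchSettings,
    acctran_edge_lengths,
    exhaustive_search,
    fitch_length,
    heuristic_search,
    mean_root_distance,
    strict_consensus,
)
from stemward.trees import PhyloTree, TreeSet, adjacency, canonical_key, root_clades

from conftest import build_matrix, random_binary_matrix


def brute_force_length(edges, matrix):
    """Minimum changes by enumerating all internal-node state assignments.

    Valid for binary-state matrices (optimal internal states then lie in
    {0, 1}); MISSING leaves are compatible with either neighbor state.
    """
    L = matrix.n_taxa
    internals = list(range(L, 2 * L - 2))
    states = matrix.fitch_codes()
    best_total = 0
    for c in range(matrix.n_char):
        leaf_opts = [{s for s in (0, 1) if states[i, c] >> s & 1} for i in range(L)]
        best = None
        for assign in itertools.product((0, 1), repeat=len(internals)):
            st = dict(zip(internals, assign))
            cost = 0
            for a, b in edges:
                if a < L:
                    cost += 0 if st[b] in leaf_opts[a] else 1
                elif b < L:
                    cost += 0 if st[a] in leaf_opts[b] else 1
                else:
                    cost += st[a] != st[b]
            best = cost if best is None else min(best, cost)
        best_total += best
    return best_total


@pytest.mark.parametrize("seed", range(8))
def test_fitch_length_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    m = random_binary_matrix(rng, 5, 6, missing=0.15)
    ts = exhaustive_search(m)
    for edges in ts.trees[:2]:
        assert fitch_length(edges, m) == brute_force_length(edges, m)


def test_fitch_length_examples_ab_cd():
    # two binary characters splitting AB|CD: matching tree costs 2, the
    # conflicting tree costs 4
    m = build_matrix(["00", "00", "11", "11"], "HH", outgroup="t0")
    match = np.array([[0, 4], [1, 4], [2, 5], [3, 5], [4, 5]], dtype=np.int64)
    clash = np.array([[0, 4], [2, 4], [1, 5], [3, 5], [4, 5]], dtype=np.int64)
    assert fitch_length(match, m) == 2
    assert fitch_length(clash, m) == 4


def test_constant_matrix_has_zero_length():
    m = build_matrix(["00", "00", "00", "00"], "HH", outgroup="t0")
    for edges in exhaustive_search(m).trees:
        assert fitch_length(edges, m) == 0


def test_missing_data_never_lengthens():
    rng = np.random.default_rng(5)
    m = random_binary_matrix(rng, 6, 8, missing=0.0)
    edges = exhaustive_search(m).trees[0]
    base = fitch_length(edges, m)
    codes = m.codes.copy()
    codes[2, 3] = 0  # blank one cell
    m2 = m.with_codes(codes)
    assert fitch_length(edges, m2) <= base


def test_sankoff_agrees_with_kernel_and_is_rooting_invariant():
    rng = np.random.default_rng(7)
    for _ in range(5):
        m = random_binary_matrix(rng, 6, 10, missing=0.1)
        edges = exhaustive_search(m).trees[0]
        kernel = fitch_length(edges, m)
        tree = PhyloTree.from_unrooted(edges, m.taxa, m.outgroup)
        assert fitch_length(tree, m) == kernel
        # re-root on a different taxon: length unchanged
        tree2 = PhyloTree.from_unrooted(edges, m.taxa, m.taxa[3])
        assert fitch_length(tree2, m) == kernel


def test_ordered_characters_use_wagner_counting():
    # states 0 and 2 in one ordered character: two steps apart
    m = CharacterMatrix(
        taxa=("a", "b", "c", "d"),
        codes=np.array([[1], [1], [4], [4]], dtype=np.int64),  # 0,0,2,2
        partition=np.zeros(1, dtype=np.int8),
        outgroup="a",
        ordered=np.array([True]),
    )
    edges = np.array([[0, 4], [1, 4], [2, 5], [3, 5], [4, 5]], dtype=np.int64)
    assert fitch_length(edges, m) == 2  # one 0->2 transition = 2 steps
    m_unord = CharacterMatrix(
        taxa=m.taxa, codes=m.codes, partition=m.partition, outgroup="a",
    )
    assert fitch_length(edges, m_unord) == 1


@pytest.mark.parametrize("n_taxa, expected", [(4, 3), (6, 105)])
def test_exhaustive_enumerates_all_topologies(n_taxa, expected):
    rng = np.random.default_rng(0)
    m = random_binary_matrix(rng, n_taxa, 4)
    ts = exhaustive_search(m)
    assert ts.n_topologies_examined == expected
    assert len({canonical_key(e, n_taxa) for e in ts.trees}) == len(ts.trees)


def test_exhaustive_refuses_large_trees(rng):
    m = random_binary_matrix(rng, 10, 4)
    with pytest.raises(StemwardError, match="9 taxa"):
        exhaustive_search(m)


def test_heuristic_score_matches_exhaustive(rng):
    settings = SearchSettings(n_addition_replicates=3, hold_per_replicate=100,
                              max_trees=300, rng_seed=1)
    for seed in range(20):
        sub = np.random.default_rng(seed)
        m = random_binary_matrix(sub, int(sub.integers(5, 8)), int(sub.integers(6, 14)))
        ex = exhaustive_search(m)
        he = heuristic_search(m, settings)
        assert he.score == ex.score
        hk = {canonical_key(e, m.n_taxa) for e in he.trees}
        ek = {canonical_key(e, m.n_taxa) for e in ex.trees}
        assert hk <= ek  # every heuristic tree is a true MPT


def test_heuristic_search_is_deterministic(rng):
    m = random_binary_matrix(rng, 10, 20)
    s = SearchSettings(n_addition_replicates=3, hold_per_replicate=50,
                       max_trees=50, rng_seed=42)
    a = heuristic_search(m, s)
    b = heuristic_search(m, s)
    assert a.score == b.score
    assert [canonical_key(e, 10) for e in a.trees] == [canonical_key(e, 10) for e in b.trees]


def test_heuristic_requires_four_taxa():
    m = build_matrix(["01", "10", "11"], "HH", outgroup="t0")
    with pytest.raises(StemwardError, match="4 taxa"):
        heuristic_search(m)


def test_strict_consensus_identity_and_star():
    rng = np.random.default_rng(3)
    m = random_binary_matrix(rng, 6, 10)
    ts = exhaustive_search(m)
    single = TreeSet(labels=ts.labels, trees=[ts.trees[0]], score=ts.score,
                     outgroup=ts.outgroup)
    cons = strict_consensus(single)
    assert cons.clades == PhyloTree.from_unrooted(ts.trees[0], ts.labels,
                                                  ts.outgroup).clades
    # two trees sharing no non-trivial clade -> empty consensus (star)
    a = np.array([[0, 6], [1, 6], [2, 7], [3, 7], [4, 8], [5, 8],
                  [6, 9], [7, 9], [8, 9]], dtype=np.int64)
    b = np.array([[0, 6], [3, 6], [1, 7], [4, 7], [2, 8], [5, 8],
                  [6, 9], [7, 9], [8, 9]], dtype=np.int64)
    pair = TreeSet(labels=ts.labels, trees=[a, b], score=0, outgroup="t0")
    assert strict_consensus(pair).clades == frozenset()


def test_strict_consensus_equals_dendropy_clade_intersection():
    import dendropy

    rng = np.random.default_rng(11)
    for seed in range(5):
        sub = np.random.default_rng(seed)
        m = random_binary_matrix(sub, 7, 8)
        ts = heuristic_search(m, SearchSettings(n_addition_replicates=2,
                                                hold_per_replicate=60,
                                                max_trees=60, rng_seed=seed))
        ours = strict_consensus(ts).clade_set()
        og = ts.labels.index(ts.outgroup)
        common = None
        from stemward.trees import newick_from_edges

        for edges in ts:
            nwk = newick_from_edges(edges, ts.labels, og)
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            clades = set()
            for node in tree.preorder_node_iter():
                if node.parent_node is None or node.is_leaf():
                    continue
                leaves = frozenset(l.taxon.label for l in node.leaf_iter())
                if 2 <= len(leaves) <= len(ts.labels) - 2:
                    clades.add(leaves)
            common = clades if common is None else common & clades
        assert ours == common


def test_adding_trees_shrinks_consensus(rng):
    m = random_binary_matrix(rng, 7, 10)
    ts = exhaustive_search(m)
    if len(ts) < 2:
        pytest.skip("unique MPT for this draw")
    one = TreeSet(labels=ts.labels, trees=ts.trees[:1], score=ts.score,
                  outgroup=ts.outgroup)
    assert strict_consensus(ts).clades <= strict_consensus(one).clades


def test_mean_root_distance_node_metric_examples():
    # caterpillar over 5 leaves rooted at t0's attachment node:
    # t1 sits at the root (0), the deepest cherry leaves at 2
    edges = np.array([[0, 5], [1, 5], [5, 6], [2, 6], [6, 7], [3, 7], [4, 7]],
                     dtype=np.int64)
    labels = ("t0", "t1", "t2", "t3", "t4")
    ts = TreeSet(labels=labels, trees=[edges], score=0, outgroup="t0")
    assert mean_root_distance(ts, "t1") == 0.0
    assert mean_root_distance(ts, "t3") == 2.0
    # mean over a set: a second tree where t3 attaches at the root (0)
    edges2 = np.array([[0, 5], [3, 5], [5, 6], [1, 6], [6, 7], [2, 7], [4, 7]],
                      dtype=np.int64)
    both = TreeSet(labels=labels, trees=[edges, edges2], score=0, outgroup="t0")
    assert mean_root_distance(both, "t3") == pytest.approx(1.0)


def test_mean_root_distance_bounds(rng):
    m = random_binary_matrix(rng, 8, 12)
    ts = heuristic_search(m, SearchSettings(n_addition_replicates=2,
                                            hold_per_replicate=40, max_trees=40,
                                            rng_seed=0))
    for taxon in m.taxa:
        d = mean_root_distance(ts, taxon)
        assert 0 <= d <= m.n_taxa - 2


def test_acctran_edge_lengths_sum_to_tree_length():
    rng = np.random.default_rng(9)
    for seed in range(10):
        sub = np.random.default_rng(seed)
        m = random_binary_matrix(sub, int(sub.integers(5, 8)),
                                 int(sub.integers(5, 15)), missing=0.15,
                                 n_states=3)
        ts = exhaustive_search(m)
        lengths = acctran_edge_lengths(ts.trees[0], m)
        assert sum(lengths.values()) == ts.score


def test_patristic_distance_simple_case():
    # 0=outgroup; one character separates {t2,t3} from the rest
    m = build_matrix(["0", "0", "1", "1"], "H", outgroup="t0")
    edges = np.array([[0, 4], [1, 4], [2, 5], [3, 5], [4, 5]], dtype=np.int64)
    ts = TreeSet(labels=m.taxa, trees=[edges], score=1, outgroup="t0")
    # path t2 -> root crosses the single changing branch
    assert mean_root_distance(ts, "t2", metric="patristic", matrix=m) == 1.0
    assert mean_root_distance(ts, "t1", metric="patristic", matrix=m) == 0.0


def test_mean_root_distance_unknown_taxon_errors(rng):
    m = random_binary_matrix(rng, 6, 6)
    ts = exhaustive_search(m)
    with pytest.raises(StemwardError):
        mean_root_distance(ts, "nope")
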