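import numpy as np
import pytest

from stemward.matrix import CharacterMatrix, StemwardError
from stemward.node_recovery import (
    NodeRecoveryResult,
    aggregate_node_recovery,
    node_recovery_index,
    run_node_recovery,
)
from stemward.parsimony import SearchSettings, exhaustive_search, strict_consensus
from stemward.stats import rank_p
from stemward.trees import PhyloTree

from conftest import random_binary_matrix


def random_rooted_tree(rng, labels, outgroup):
    from stemward.simulate import SyntheticSpec, generate_tree

    truth = generate_tree(SyntheticSpec(n_taxa=len(labels) - 1), rng)
    return PhyloTree.from_unrooted(truth["edges"], labels, outgroup)


def test_index_identity_and_star(rng):
    labels = tuple(f"t{i}" for i in range(7))
    tree = random_rooted_tree(rng, labels, labels[-1])
    assert node_recovery_index(tree, tree) == 1.0
    star = PhyloTree(labels=labels, clades=frozenset(), outgroup=labels[-1])
    assert node_recovery_index(tree, star) == 0.0


def test_index_matches_set_intersection_oracle(rng):
    labels = tuple(f"t{i}" for i in range(8))
    for _ in range(10):
        a = random_rooted_tree(rng, labels, labels[-1])
        b = random_rooted_tree(rng, labels, labels[-1])
        expected = len(a.clade_set() & b.clade_set()) / len(a.clade_set())
        assert node_recovery_index(a, b) == pytest.approx(expected)


def test_index_requires_same_leaves(rng):
    a = random_rooted_tree(rng, tuple(f"t{i}" for i in range(7)), "t6")
    b = random_rooted_tree(rng, tuple(f"x{i}" for i in range(7)), "x6")
    with pytest.raises(StemwardError):
        node_recovery_index(a, b)


def test_rank_p_formula_in_run():
    from stemward.simulate import SyntheticSpec, generate_dataset

    ds = generate_dataset(SyntheticSpec(n_taxa=8, n_hard=8, n_soft=8, rng_seed=3))
    m = ds.matrix
    settings = SearchSettings(n_addition_replicates=2, hold_per_replicate=32,
                              max_trees=32)
    res = run_node_recovery(m, n_reps=19, settings=settings, rng_seed=5)
    assert not res.undefined
    r = int((res.null_indices <= res.recovery_index + 1e-12).sum())
    assert res.p_value == pytest.approx(rank_p(r, 19))
    assert 0 < res.p_value <= 1


def test_exchangeable_duplicate_partitions_not_significant(rng):
    # SOFT block is an exact copy of the HARD block: deleting either
    # partition leaves a full copy of the signal
    base = random_binary_matrix(rng, 8, 10, missing=0.0)
    codes = np.hstack([base.codes, base.codes])
    part = np.array([0] * 10 + [1] * 10, dtype=np.int8)
    m = CharacterMatrix(taxa=base.taxa, codes=codes, partition=part,
                        outgroup=base.outgroup)
    settings = SearchSettings(n_addition_replicates=2, hold_per_replicate=32,
                              max_trees=32)
    res = run_node_recovery(m, n_reps=19, settings=settings, rng_seed=3)
    assert res.recovery_index == 1.0
    assert res.p_value > 0.05


def make_result(mid, bench, recovered, nulls, mode="fossilization"):
    nulls = np.asarray(nulls, dtype=np.int64)
    idx = nulls / bench
    sysi = recovered / bench
    return NodeRecoveryResult(
        matrix_id=mid, mode=mode, benchmark_nodes=bench, recovered=recovered,
        recovery_index=sysi, k_deleted=5, null_recovered=nulls,
        null_indices=idx, p_value=rank_p(int((idx <= sysi + 1e-12).sum()), len(nulls)),
    )


def test_aggregate_pools_counts_not_fractions():
    a = make_result("a", 20, 10, [12, 14, 16])
    b = make_result("b", 30, 30, [20, 25, 30])
    agg = aggregate_node_recovery([a, b])
    assert agg.pooled_recovery == pytest.approx(40 / 50)  # not mean(0.5, 1.0)
    # i-th pooled null pairs the i-th replicates
    assert agg.pooled_null == pytest.approx([(12 + 20) / 50, (14 + 25) / 50,
                                             (16 + 30) / 50])


def test_aggregate_single_matrix_is_identity():
    a = make_result("a", 20, 10, [12, 14, 16])
    agg = aggregate_node_recovery([a])
    assert agg.pooled_recovery == a.recovery_index
    assert agg.p_value == a.p_value


def test_aggregate_null_mean_is_benchmark_weighted():
    a = make_result("a", 20, 10, [12, 14, 16])
    b = make_result("b", 30, 30, [20, 25, 30])
    agg = aggregate_node_recovery([a, b])
    weighted = (20 * a.null_indices + 30 * b.null_indices) / 50
    assert agg.pooled_null_mean == pytest.approx(float(weighted.mean()))


def test_aggregate_rejects_mismatched_replicates():
    a = make_result("a", 20, 10, [12, 14, 16])
    b = make_result("b", 30, 30, [20, 25])
    with pytest.raises(StemwardError):
        aggregate_node_recovery([a, b])


def test_undefined_benchmark_excluded():
    a = make_result("a", 20, 10, [12, 14, 16])
    z = NodeRecoveryResult(
        matrix_id="z", mode="fossilization", benchmark_nodes=0, recovered=0,
        recovery_index=float("nan"), k_deleted=3,
        null_recovered=np.zeros(3, dtype=np.int64),
        null_indices=np.full(3, np.nan), p_value=float("nan"),
    )
    agg = aggregate_node_recovery([a, z])
    assert agg.n_matrices == 1
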