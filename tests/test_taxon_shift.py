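import numpy as np
import pytest

from stemward.matrix import StemwardError
from stemward.parsimony import SearchSettings, exhaustive_search, mean_root_distance
from stemward.taxon_shift import (
    TaxonShiftResult,
    classify_shift,
    run_all_taxon_shifts,
    run_taxon_shift,
    summarize_shifts,
)
from stemward.perturb import fossilize_taxon

from conftest import build_matrix


def make_result(delta, p, nulls=(), taxon="x"):
    return TaxonShiftResult(
        matrix_id="m", taxon=taxon, metric="nodes", k_deleted=3,
        d_orig=2.0, d_foss=2.0 + delta, delta=delta,
        null_deltas=np.asarray(nulls, dtype=float), p_magnitude=p,
    )


@pytest.mark.parametrize(
    "delta, p, expected",
    [
        (-0.4, 0.002, ("down", True)),
        (0.1, 0.40, ("up", False)),
        (0.0, 0.001, ("none", False)),  # no move is never significant
    ],
)
def test_classify_shift(delta, p, expected):
    assert classify_shift(make_result(delta, p)) == expected


def crown_soft_matrix():
    """Taxon X's nested crown membership rests on soft characters only.

    Hard characters place X merely inside the large clade {B,C,D,X};
    soft characters supply the {D,X} and {C,D,X} synapomorphies.
    """
    #         h1  h2  h3  s1  s2  s3  s4
    rows = {
        "OUT": "0000000",
        "A":   "0000000",
        "B":   "1110000",
        "C":   "1110011",
        "D":   "1111111",
        "X":   "1111111",
    }
    return build_matrix(list(rows.values()), "HHHSSSS", outgroup="OUT",
                        taxa=tuple(rows))


def test_fossilized_crown_taxon_slips_stemward():
    m = crown_soft_matrix()
    settings = SearchSettings(n_addition_replicates=3, hold_per_replicate=64,
                              max_trees=64, rng_seed=0)
    res = run_taxon_shift(m, "X", n_reps=19, settings=settings, rng_seed=2)
    assert res.delta < 0
    assert res.direction == "down"
    # exhaustive oracle: the displaced optimum includes basal placements of X
    foss = fossilize_taxon(m, "X")
    ts = exhaustive_search(foss)
    assert mean_root_distance(ts, "X") < mean_root_distance(exhaustive_search(m), "X")


def test_unperturbable_taxon_flagged():
    m = crown_soft_matrix()
    codes = m.codes.copy()
    codes[1, 3:] = 0  # A loses its (already ancestral) soft scores
    m2 = m.with_codes(codes)
    settings = SearchSettings(n_addition_replicates=2, hold_per_replicate=32,
                              max_trees=32)
    res = run_taxon_shift(m2, "A", n_reps=5, settings=settings, rng_seed=1)
    assert res.unperturbable
    assert res.delta == 0.0
    assert res.direction == "none"


def test_outgroup_is_never_fossilized():
    m = crown_soft_matrix()
    with pytest.raises(StemwardError, match="outgroup"):
        run_taxon_shift(m, "OUT", n_reps=5)


def test_matched_null_row_missingness():
    m = crown_soft_matrix()
    settings = SearchSettings(n_addition_replicates=2, hold_per_replicate=16,
                              max_trees=16)
    res = run_taxon_shift(m, "D", n_reps=7, settings=settings, rng_seed=4)
    assert res.k_deleted == 4  # D's scored soft cells
    assert len(res.null_deltas) == 7


def test_summary_counting_and_pooling():
    results = [
        make_result(-0.5, 0.01), make_result(-0.2, 0.2), make_result(-0.1, 0.9),
        make_result(0.3, 0.01), make_result(0.4, 0.5),
        make_result(0.0, 0.1),
    ]
    s = summarize_shifts(results, "fossilization")
    assert (s.moved, s.moved_down, s.moved_up) == (5, 3, 2)
    assert s.significant == 2 and s.significant_down == 1 and s.significant_up == 1
    assert s.down_fraction == pytest.approx(3 / 5)


def test_random_summary_per_replicate_and_per_taxon_mean():
    r1 = make_result(-0.5, 0.01, nulls=[-1.0, -0.5, 0.2, 0.0])
    r2 = make_result(0.2, 0.5, nulls=[0.4, 0.3, -0.1, 0.0])
    per_rep = summarize_shifts([r1, r2], "random")
    assert per_rep.moved == 6  # two exact zeros do not move
    assert per_rep.moved_down == 3 and per_rep.moved_up == 3
    per_taxon = summarize_shifts([r1, r2], "random", accounting="per_taxon_mean")
    assert per_taxon.moved == 2
    assert per_taxon.moved_down == 1 and per_taxon.moved_up == 1


def test_metrics_agree_on_planted_stemward_shift():
    """The node-count and patristic root-distance metrics classify the
    planted crown taxon's slippage identically."""
    m = crown_soft_matrix()
    settings = SearchSettings(n_addition_replicates=3, hold_per_replicate=64,
                              max_trees=64)
    by_metric = {}
    for metric in ("nodes", "patristic"):
        res = run_taxon_shift(m, "X", n_reps=11, metric=metric,
                              settings=settings, rng_seed=8)
        by_metric[metric] = res.direction
    assert by_metric["nodes"] == by_metric["patristic"] == "down"


def test_run_all_shares_original_search():
    m = crown_soft_matrix()
    settings = SearchSettings(n_addition_replicates=2, hold_per_replicate=16,
                              max_trees=16)
    results = run_all_taxon_shifts(m, n_reps=3, settings=settings, rng_seed=6)
    assert [r.taxon for r in results] == ["A", "B", "C", "D", "X"]
    d_orig = {r.d_orig for r in results if r.taxon in ("D", "X")}
    # D and X are placed identically in the original tree set
    assert len(d_orig) == 1
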