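import numpy as np
import pytest

from stemward.curation import (
    Thresholds,
    apply_inclusion_thresholds,
    balance_missing,
    curate,
    is_informative,
    remove_taxonomic_equivalents,
    remove_uninformative,
)
from stemward.matrix import CharacterMatrix, Partition

from conftest import build_matrix


def codes_of(row):
    return np.array([1 << int(c) if c not in "?-" else 0 for c in row], dtype=np.int64)


@pytest.mark.parametrize(
    "column, informative",
    [
        ("00000", False),        # constant
        ("00001", False),        # autapomorphy
        ("0011?", True),         # two states twice each
        ("00112", True),
        ("00012", False),        # second state only once
    ],
)
def test_informativeness_definition(column, informative):
    assert is_informative(codes_of(column)) == informative


def test_remove_uninformative_keeps_partition_alignment():
    m = build_matrix(["000011", "000110", "100101", "100000", "010011"],
                     "HSHSHS", outgroup="t0")
    out, rep = remove_uninformative(m)
    assert rep.original_chars == 6
    assert out.n_hard + out.n_soft == out.n_char
    assert all(is_informative(out.codes[:, j]) for j in range(out.n_char))
    # retained cell values untouched
    kept = [j - 1 for j in range(1, 7) if j not in rep.removed_chars]
    assert np.array_equal(out.codes, m.codes[:, kept])


def test_identical_rows_keep_first_listed():
    m = build_matrix(["0011", "0101", "0101", "1100"], "HHSS", outgroup="t0")
    out, rep = remove_taxonomic_equivalents(m)
    assert rep.removed_taxa == ["t2"]
    assert out.taxa == ("t0", "t1", "t3")


def test_missing_subsumed_row_removed_either_direction():
    # B equals A with two cells MISSING -> B goes, regardless of order
    a, b = "010110", "01?1?0"
    for rows, removed in ([(a, b), "t1"], [(b, a), "t0"]):
        m = build_matrix(list(rows) + ["111000", "000111"], "HHHSSS", outgroup="t2")
        out, rep = remove_taxonomic_equivalents(m)
        assert rep.removed_taxa == [removed]


def test_all_distinct_rows_unchanged():
    m = build_matrix(["0011", "0101", "0110", "1100"], "HHSS", outgroup="t0")
    out, rep = remove_taxonomic_equivalents(m)
    assert out is m
    assert rep.removed_taxa == []


def test_outgroup_never_removed():
    m = build_matrix(["0101", "0101", "1100"], "HHSS", outgroup="t1")
    out, _ = remove_taxonomic_equivalents(m)
    assert "t1" in out.taxa


def test_balance_untouched_below_gap():
    # both partitions fully scored: gap 0
    m = build_matrix(["0011", "0101", "0110", "1100"], "HHSS", outgroup="t0")
    out, rep = balance_missing(m)
    assert out is m


def test_balance_removes_pathological_taxon_then_stops():
    # one taxon missing most soft cells drives the partition gap
    rows = [
        "11110000",
        "00001111",
        "0101????",   # 50% missing, all in SOFT -> gap driver, >30% row missing
        "01010101",
        "10101010",
    ]
    m = build_matrix(rows, "HHHHSSSS", outgroup="t0")
    gap_before = abs(m.missing_fraction(Partition.HARD) - m.missing_fraction(Partition.SOFT))
    assert gap_before >= 0.10
    out, rep = balance_missing(m)
    assert "t2" in rep.removed_taxa
    gap_after = abs(out.missing_fraction(Partition.HARD) - out.missing_fraction(Partition.SOFT))
    assert gap_after < 0.10


@pytest.mark.parametrize(
    "n_char, n_taxa, n_hard, include, reason",
    [
        (29, 15, 10, False, "characters"),
        (40, 10, 8, True, None),       # hard fraction exactly 0.20 is allowed
        (40, 10, 7, False, "hard fraction"),
        (60, 30, 30, True, None),
        (40, 9, 20, False, "taxa"),
    ],
)
def test_inclusion_thresholds(n_char, n_taxa, n_hard, include, reason):
    rng = np.random.default_rng(1)
    codes = (1 << rng.integers(0, 2, size=(n_taxa, n_char))).astype(np.int64)
    part = np.array([0] * n_hard + [1] * (n_char - n_hard), dtype=np.int8)
    m = CharacterMatrix(taxa=tuple(f"t{i}" for i in range(n_taxa)),
                        codes=codes, partition=part, outgroup="t0")
    decision = apply_inclusion_thresholds(m)
    assert decision.include == include
    if reason:
        assert any(reason in v for v in decision.violated)


def test_curation_pipeline_idempotent():
    from stemward.simulate import SyntheticSpec, generate_dataset

    for seed in range(3):
        ds = generate_dataset(SyntheticSpec(n_taxa=12, n_hard=20, n_soft=20,
                                            rng_seed=seed))
        once, _, d1 = curate(ds.matrix)
        twice, _, d2 = curate(once)
        assert twice == once
        assert d1.include == d2.include


def test_curation_never_alters_retained_cells():
    m = build_matrix(["0011?", "01010", "01100", "11001", "1010?"],
                     "HHHSS", outgroup="t0")
    out, _, _ = curate(m)
    for t in out.taxa:
        for j in range(out.n_char):
            orig_col = list(m.taxa).index(t)
            # every retained cell appears with its original value
            assert out.codes[out.taxon_index(t), j] in m.codes[orig_col, :]
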