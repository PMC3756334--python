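"""Matrix editing and inclusion protocol.

Published matrices are edited before analysis: parsimony-uninformative
characters go, taxonomic equivalents (rows identical up to MISSING
subsumption) go, flagged extinct taxa go, and missing data are balanced
between the hard and soft partitions.  A curated matrix is then accepted
into a study compilation only if it keeps >= 30 characters, >= 10 taxa
and a hard fraction between 0.20 and 0.80 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import CharacterMatrix, Partition

__all__ = [
    "CurationReport",
    "InclusionDecision",
    "Thresholds",
    "remove_uninformative",
    "remove_taxonomic_equivalents",
    "remove_extinct",
    "balance_missing",
    "apply_inclusion_thresholds",
    "curate",
    "is_informative",
]


@dataclass
class Thresholds:
    """Inclusion thresholds for the compiled study."""

    min_characters: int = 30
    min_taxa: int = 10
    min_hard_fraction: float = 0.20
    max_hard_fraction: float = 0.80
    max_taxon_missing: float = 0.30   # taxa above this are dropped while balancing
    max_char_missing: float = 0.50    # characters above this are dropped while balancing
    partition_gap: float = 0.10       # balance only if |%miss(hard) - %miss(soft)| >= gap


@dataclass
class CurationReport:
    """Counts and reasons for everything a curation step removed."""

    step: str
    removed_taxa: list[str] = field(default_factory=list)
    removed_chars: list[int] = field(default_factory=list)  # 1-based indices
    original_taxa: int = 0
    original_chars: int = 0
    retained_taxa: int = 0
    retained_chars: int = 0
    missing_before: tuple[float, float] = (0.0, 0.0)  # (hard, soft)
    missing_after: tuple[float, float] = (0.0, 0.0)
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "step": self.step,
            "removed_taxa": list(self.removed_taxa),
            "removed_chars": list(self.removed_chars),
            "original_taxa": self.original_taxa,
            "original_chars": self.original_chars,
            "retained_taxa": self.retained_taxa,
            "retained_chars": self.retained_chars,
            "missing_before": list(self.missing_before),
            "missing_after": list(self.missing_after),
            "notes": list(self.notes),
        }


@dataclass
class InclusionDecision:
    include: bool
    violated: list[str] = field(default_factory=list)
    n_taxa: int = 0
    n_char: int = 0
    hard_fraction: float = 0.0

    def as_dict(self) -> dict:
        return {
            "include": self.include,
            "violated": list(self.violated),
            "n_taxa": self.n_taxa,
            "n_char": self.n_char,
            "hard_fraction": self.hard_fraction,
        }


def _report(step: str, matrix: CharacterMatrix, kept_rows, kept_cols) -> CurationReport:
    rep = CurationReport(step=step)
    rep.original_taxa = matrix.n_taxa
    rep.original_chars = matrix.n_char
    rep.removed_taxa = [matrix.taxa[i] for i in range(matrix.n_taxa) if i not in set(kept_rows)]
    rep.removed_chars = [j + 1 for j in range(matrix.n_char) if j not in set(kept_cols)]
    rep.retained_taxa = len(kept_rows)
    rep.retained_chars = len(kept_cols)
    rep.missing_before = (
        matrix.missing_fraction(Partition.HARD),
        matrix.missing_fraction(Partition.SOFT),
    )
    return rep


def is_informative(column: np.ndarray) -> bool:
    """Parsimony informativeness of one character column (bitmask codes).

    A character is informative when at least two states are each observed
    unambiguously (single-state cells) in at least two taxa, so that
    alternative groupings can differ in length.
    """
    counts: dict[int, int] = {}
    for mask in column:
        m = int(mask)
        if m and (m & (m - 1)) == 0:  # single observed state
            counts[m] = counts.get(m, 0) + 1
    return sum(1 for c in counts.values() if c >= 2) >= 2


def remove_uninformative(matrix: CharacterMatrix) -> tuple[CharacterMatrix, CurationReport]:
    """Drop parsimony-uninformative characters (constant, autapomorphic...)."""
    keep = [j for j in range(matrix.n_char) if is_informative(matrix.codes[:, j])]
    rep = _report("remove_uninformative", matrix, range(matrix.n_taxa), keep)
    if not keep:
        rep.notes.append("all characters uninformative; matrix flagged for exclusion")
        out = matrix  # cannot build an empty matrix; caller sees retained_chars == 0
    else:
        out = matrix.with_chars(keep)
    rep.missing_after = (
        out.missing_fraction(Partition.HARD),
        out.missing_fraction(Partition.SOFT),
    )
    return out, rep


def _subsumes(a: np.ndarray, b: np.ndarray) -> bool:
    """True if row ``b`` is a taxonomic equivalent of row ``a``.

    Every scored cell of b must be scored identically in a (b adds no
    conflicting and no extra information beyond a).
    """
    for ma, mb in zip(a, b):
        if int(mb) != 0 and int(mb) != int(ma):
            return False
    return True


def remove_taxonomic_equivalents(matrix: CharacterMatrix) -> tuple[CharacterMatrix, CurationReport]:
    """Collapse groups of identical / MISSING-subsumed rows to their first member.

    The outgroup is never removed: if it is subsumed by another row, the
    other row is kept too only when not itself redundant.
    """
    n = matrix.n_taxa
    og = matrix.outgroup_index
    removed: set[int] = set()
    for i in range(n):
        if i in removed:
            continue
        for j in range(i + 1, n):
            if j in removed:
                continue
            i_covers_j = _subsumes(matrix.codes[i], matrix.codes[j])
            j_covers_i = _subsumes(matrix.codes[j], matrix.codes[i])
            if i_covers_j and j_covers_i:  # identical rows: keep the first-listed
                if j != og:
                    removed.add(j)
                elif i != og:
                    removed.add(i)
            elif i_covers_j and j != og:  # j adds nothing beyond i
                removed.add(j)
            elif j_covers_i and i != og:  # i adds nothing beyond j
                removed.add(i)
            if i in removed:
                break
    keep = [i for i in range(n) if i not in removed]
    rep = _report("remove_taxonomic_equivalents", matrix, keep, range(matrix.n_char))
    out = matrix.with_rows(keep) if removed else matrix
    rep.missing_after = rep.missing_before if not removed else (
        out.missing_fraction(Partition.HARD),
        out.missing_fraction(Partition.SOFT),
    )
    return out, rep


def remove_extinct(
    matrix: CharacterMatrix, extinct: Sequence[str]
) -> tuple[CharacterMatrix, CurationReport]:
    """Drop taxa flagged extinct by the input annotation (never the outgroup)."""
    flagged = {t for t in extinct if t != matrix.outgroup}
    keep = [i for i, t in enumerate(matrix.taxa) if t not in flagged]
    rep = _report("remove_extinct", matrix, keep, range(matrix.n_char))
    out = matrix.with_rows(keep) if len(keep) < matrix.n_taxa else matrix
    rep.missing_after = (
        out.missing_fraction(Partition.HARD),
        out.missing_fraction(Partition.SOFT),
    )
    return out, rep


def _partition_gap(matrix: CharacterMatrix) -> float:
    return abs(
        matrix.missing_fraction(Partition.HARD) - matrix.missing_fraction(Partition.SOFT)
    )


def balance_missing(
    matrix: CharacterMatrix,
    thresholds: Thresholds | None = None,
    *,
    iterate: bool = True,
) -> tuple[CharacterMatrix, CurationReport]:
    """Balance missing data between partitions.

    If the partitions differ by >= ``partition_gap`` (10 points) in percent
    missing, remove taxa with > 30% MISSING cells, then characters with
    > 50% MISSING cells, repeating (taxa first) until the gap falls below
    the threshold or nothing removable remains.  ``iterate=False`` applies
    a single taxa-then-characters pass.
    """
    th = thresholds or Thresholds()
    out = matrix
    removed_taxa: list[str] = []
    removed_chars: list[int] = []  # 1-based indices into the ORIGINAL matrix
    # map retained columns back to original indices for reporting
    col_ids = list(range(1, matrix.n_char + 1))
    rep = _report("balance_missing", matrix, range(matrix.n_taxa), range(matrix.n_char))
    while _partition_gap(out) >= th.partition_gap - 1e-12:
        changed = False
        row_missing = (out.codes == 0).mean(axis=1)
        keep_rows = [
            i for i in range(out.n_taxa)
            if row_missing[i] <= th.max_taxon_missing + 1e-12 or i == out.outgroup_index
        ]
        if len(keep_rows) < out.n_taxa:
            removed_taxa.extend(out.taxa[i] for i in range(out.n_taxa) if i not in set(keep_rows))
            out = out.with_rows(keep_rows)
            changed = True
        if _partition_gap(out) < th.partition_gap - 1e-12:
            break
        col_missing = (out.codes == 0).mean(axis=0)
        keep_cols = [j for j in range(out.n_char) if col_missing[j] <= th.max_char_missing + 1e-12]
        if keep_cols and len(keep_cols) < out.n_char:
            removed_chars.extend(col_ids[j] for j in range(out.n_char) if j not in set(keep_cols))
            col_ids = [col_ids[j] for j in keep_cols]
            out = out.with_chars(keep_cols)
            changed = True
        if not changed or not iterate:
            break
    rep.removed_taxa = removed_taxa
    rep.removed_chars = removed_chars
    rep.retained_taxa = out.n_taxa
    rep.retained_chars = out.n_char
    rep.missing_after = (
        out.missing_fraction(Partition.HARD),
        out.missing_fraction(Partition.SOFT),
    )
    rep.notes.append(f"final partition gap {_partition_gap(out):.4f}")
    return out, rep


def apply_inclusion_thresholds(
    matrix: CharacterMatrix, thresholds: Thresholds | None = None
) -> InclusionDecision:
    """Include/exclude decision for the compiled study (boundaries inclusive)."""
    th = thresholds or Thresholds()
    hard_fraction = matrix.n_hard / matrix.n_char
    violated = []
    if matrix.n_char < th.min_characters:
        violated.append(f"characters {matrix.n_char} < {th.min_characters}")
    if matrix.n_taxa < th.min_taxa:
        violated.append(f"taxa {matrix.n_taxa} < {th.min_taxa}")
    if not (th.min_hard_fraction - 1e-12 <= hard_fraction <= th.max_hard_fraction + 1e-12):
        violated.append(
            f"hard fraction {hard_fraction:.3f} outside "
            f"[{th.min_hard_fraction}, {th.max_hard_fraction}]"
        )
    return InclusionDecision(
        include=not violated,
        violated=violated,
        n_taxa=matrix.n_taxa,
        n_char=matrix.n_char,
        hard_fraction=hard_fraction,
    )


def curate(
    matrix: CharacterMatrix,
    thresholds: Thresholds | None = None,
    extinct: Sequence[str] = (),
) -> tuple[CharacterMatrix, list[CurationReport], InclusionDecision]:
    """Full editing pipeline: uninformative, extinct, equivalents, balance.

    Returns the curated matrix, the per-step reports, and the inclusion
    decision.  The pipeline is idempotent: curating a curated matrix is a
    no-op.
    """
    reports: list[CurationReport] = []
    out, rep = remove_uninformative(matrix)
    reports.append(rep)
    if rep.retained_chars == 0:
        return out, reports, InclusionDecision(include=False, violated=["no informative characters"])
    if extinct:
        out, rep = remove_extinct(out, extinct)
        reports.append(rep)
    out, rep = remove_taxonomic_equivalents(out)
    reports.append(rep)
    out, rep = balance_missing(out, thresholds)
    reports.append(rep)
    # removals can create new uninformative characters; re-check once
    out, rep = remove_uninformative(out)
    reports.append(rep)
    if rep.retained_chars == 0:
        return out, reports, InclusionDecision(include=False, violated=["no informative characters"])
    decision = apply_inclusion_thresholds(out, thresholds)
    return out, reports, decision
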