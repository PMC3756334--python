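"""Deletion operators simulating fossilization and their random nulls.

Whole-matrix operators remove characters (systematically by partition,
or the same number at random); per-taxon operators blank cells in one
row only (all scored soft cells = pseudoextinction, or the same number
of scored cells at random).  No operator ever changes a scored state
into a different state -- only into MISSING or removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix, Partition, StemwardError

__all__ = [
    "Perturbation",
    "delete_partition_characters",
    "delete_random_characters",
    "fossilize_taxon",
    "randomize_taxon",
    "scored_cells",
    "scored_soft_cells",
]


@dataclass(frozen=True)
class Perturbation:
    """Record sufficient to reproduce one perturbed matrix."""

    kind: str
    taxon: str | None = None
    indices: tuple[int, ...] = field(default_factory=tuple)  # characters (0-based) or cells
    seed: int | None = None


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def delete_partition_characters(
    matrix: CharacterMatrix, which: Partition
) -> CharacterMatrix:
    """Remove every character labelled ``which``; taxa unchanged.

    Deleting the only populated partition would leave an empty matrix
    and raises a validation error.
    """
    keep = np.nonzero(matrix.partition != int(which))[0]
    return matrix.with_chars(keep)


def delete_random_characters(
    matrix: CharacterMatrix, k: int, rng
) -> CharacterMatrix:
    """Remove ``k`` whole characters chosen uniformly, ignoring partition."""
    if not 0 <= k < matrix.n_char:
        raise StemwardError(f"k={k} outside [0, {matrix.n_char})")
    if k == 0:
        return matrix
    gen = _as_rng(rng)
    drop = set(gen.choice(matrix.n_char, size=k, replace=False).tolist())
    keep = [j for j in range(matrix.n_char) if j not in drop]
    return matrix.with_chars(keep)


def scored_cells(matrix: CharacterMatrix, taxon: str) -> np.ndarray:
    """0-based character indices scored (non-MISSING) for one taxon."""
    row = matrix.codes[matrix.taxon_index(taxon)]
    return np.nonzero(row != 0)[0]


def scored_soft_cells(matrix: CharacterMatrix, taxon: str) -> np.ndarray:
    """Scored soft-character indices for one taxon.

    This is the matched deletion count ``k`` for the per-taxon random
    null: already-MISSING soft cells add nothing to fossilization, so
    matching on scored cells keeps row missingness exactly equal.
    """
    row = matrix.codes[matrix.taxon_index(taxon)]
    soft = matrix.partition == int(Partition.SOFT)
    return np.nonzero((row != 0) & soft)[0]


def fossilize_taxon(matrix: CharacterMatrix, taxon: str) -> CharacterMatrix:
    """Pseudoextinction: blank every soft cell of one taxon's row."""
    i = matrix.taxon_index(taxon)
    codes = matrix.codes.copy()
    codes[i, matrix.partition == int(Partition.SOFT)] = 0
    return matrix.with_codes(codes)


def randomize_taxon(
    matrix: CharacterMatrix, taxon: str, k: int, rng
) -> CharacterMatrix:
    """Blank ``k`` scored cells of one taxon's row, chosen uniformly
    across both partitions."""
    i = matrix.taxon_index(taxon)
    scored = scored_cells(matrix, taxon)
    if k > len(scored):
        raise StemwardError(
            f"k={k} exceeds the {len(scored)} scored cells of {taxon!r}"
        )
    if k == 0:
        return matrix
    gen = _as_rng(rng)
    drop = gen.choice(scored, size=k, replace=False)
    codes = matrix.codes.copy()
    codes[i, drop] = 0
    return matrix.with_codes(codes)
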