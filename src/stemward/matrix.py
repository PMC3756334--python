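"""Partitioned morphological character matrices.

A :class:`CharacterMatrix` is a rectangular grid of taxa x discrete
characters.  Each cell is a non-empty set of observed states (integers
0-9) or MISSING.  Every character carries a partition label -- ``HARD``
for biomineralized (readily fossilizable) anatomy, ``SOFT`` for
non-biomineralized anatomy -- and one taxon is designated the outgroup
used to root all trees inferred from the matrix.

Internally cells are stored as bitmasks (bit *i* set = state *i*
observed); a mask of 0 encodes MISSING.  Inapplicable codings ("-") are
collapsed to MISSING on input.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "MISSING",
    "Partition",
    "CharacterMatrix",
    "StemwardError",
    "MatrixParseError",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "read_partition_csv",
    "write_partition_csv",
]

N_SYMBOLS = 10  # states are the digits 0..9
FULL_MASK = (1 << N_SYMBOLS) - 1


class StemwardError(Exception):
    """Base class for package errors."""


class MatrixParseError(StemwardError):
    """Malformed matrix file (message names the offending line)."""


class MatrixValidationError(StemwardError):
    """Structurally invalid matrix or inconsistent annotations."""


class Partition(enum.IntEnum):
    HARD = 0
    SOFT = 1

    @classmethod
    def from_label(cls, label: str) -> "Partition":
        key = str(label).strip().lower()
        if key in ("hard", "h", "0"):
            return cls.HARD
        if key in ("soft", "s", "1"):
            return cls.SOFT
        raise MatrixValidationError(f"unknown partition label {label!r}")

    @property
    def label(self) -> str:
        return "hard" if self is Partition.HARD else "soft"


class _Missing:
    """Sentinel for an unscored cell; distinct from every state-set."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()


def states_to_mask(states: Iterable[int]) -> int:
    mask = 0
    for s in states:
        if not 0 <= int(s) < N_SYMBOLS:
            raise MatrixValidationError(f"state {s} outside the 0-9 alphabet")
        mask |= 1 << int(s)
    return mask


def mask_to_states(mask: int) -> frozenset[int]:
    return frozenset(i for i in range(N_SYMBOLS) if mask >> i & 1)


_LABEL_RE = re.compile(r"^[A-Za-z0-9_.+-]+$")


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters grid with a hard/soft partition and an outgroup.

    Parameters
    ----------
    taxa:
        Ordered, unique taxon labels.
    codes:
        ``(n_taxa, n_char)`` array of state bitmasks; 0 encodes MISSING.
    partition:
        Per-character :class:`Partition` labels, ``(n_char,)``.
    outgroup:
        Label of the outgroup taxon; must be present in ``taxa``.
    ordered:
        Per-character flag: True = ordered (additive, Wagner counting),
        False = unordered (Fitch).  Default all unordered.
    """

    taxa: tuple[str, ...]
    codes: np.ndarray
    partition: np.ndarray
    outgroup: str
    ordered: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxa)
        object.__setattr__(self, "taxa", taxa)
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.ndim != 2:
            raise MatrixValidationError("codes must be a 2-D taxa x characters grid")
        object.__setattr__(self, "codes", codes)
        part = np.asarray(self.partition, dtype=np.int8)
        object.__setattr__(self, "partition", part)
        if self.ordered is None:
            ordered = np.zeros(codes.shape[1], dtype=bool)
        else:
            ordered = np.asarray(self.ordered, dtype=bool)
        object.__setattr__(self, "ordered", ordered)
        self._validate()

    def _validate(self) -> None:
        n_taxa, n_char = self.codes.shape
        if n_taxa == 0 or n_char == 0:
            raise MatrixValidationError("matrix must have at least one taxon and one character")
        if len(self.taxa) != n_taxa:
            raise MatrixValidationError("taxon label count does not match row count")
        if len(set(self.taxa)) != n_taxa:
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixValidationError(f"duplicate taxon labels: {dupes}")
        for t in self.taxa:
            if not _LABEL_RE.match(t):
                raise MatrixValidationError(f"invalid taxon label {t!r}")
        if self.partition.shape != (n_char,):
            raise MatrixValidationError(
                f"partition labels {self.partition.shape[0] if self.partition.ndim == 1 else '?'} "
                f"do not match character count {n_char}"
            )
        if not np.isin(self.partition, (int(Partition.HARD), int(Partition.SOFT))).all():
            raise MatrixValidationError("partition labels must be HARD or SOFT")
        if self.ordered.shape != (n_char,):
            raise MatrixValidationError("ordering flags do not match character count")
        if self.outgroup not in self.taxa:
            raise MatrixValidationError(f"outgroup {self.outgroup!r} not among taxa")
        if (self.codes < 0).any() or (self.codes > FULL_MASK).any():
            raise MatrixValidationError("cell codes outside the 0-9 state alphabet")
        # ordered characters must have contiguous (interval) state sets
        for j in np.nonzero(self.ordered)[0]:
            for mask in self.codes[:, j]:
                if mask and not _is_interval(int(mask)):
                    raise MatrixValidationError(
                        f"ordered character {j + 1} has a non-contiguous polymorphic cell"
                    )

    # ------------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_char(self) -> int:
        return self.codes.shape[1]

    @property
    def outgroup_index(self) -> int:
        return self.taxa.index(self.outgroup)

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise MatrixValidationError(f"taxon {label!r} not in matrix") from None

    def cell(self, taxon: str, char: int):
        """State set of one cell (``MISSING`` if unscored); ``char`` 0-based."""
        mask = int(self.codes[self.taxon_index(taxon), char])
        return MISSING if mask == 0 else mask_to_states(mask)

    def char_indices(self, which: Partition) -> np.ndarray:
        return np.nonzero(self.partition == int(which))[0]

    @property
    def n_hard(self) -> int:
        return int((self.partition == int(Partition.HARD)).sum())

    @property
    def n_soft(self) -> int:
        return int((self.partition == int(Partition.SOFT)).sum())

    def missing_fraction(self, which: Partition | None = None) -> float:
        """Fraction of MISSING cells, overall or within one partition."""
        cols = self.codes if which is None else self.codes[:, self.char_indices(which)]
        if cols.size == 0:
            return 0.0
        return float((cols == 0).mean())

    # ------------------------------------------------------------------
    def with_rows(self, keep: Sequence[int]) -> "CharacterMatrix":
        keep = list(keep)
        return CharacterMatrix(
            taxa=tuple(self.taxa[i] for i in keep),
            codes=self.codes[keep, :].copy(),
            partition=self.partition.copy(),
            outgroup=self.outgroup,
            ordered=self.ordered.copy(),
        )

    def with_chars(self, keep: Sequence[int]) -> "CharacterMatrix":
        keep = list(keep)
        return CharacterMatrix(
            taxa=self.taxa,
            codes=self.codes[:, keep].copy(),
            partition=self.partition[keep].copy(),
            outgroup=self.outgroup,
            ordered=self.ordered[keep].copy(),
        )

    def with_codes(self, codes: np.ndarray) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=self.taxa,
            codes=codes,
            partition=self.partition.copy(),
            outgroup=self.outgroup,
            ordered=self.ordered.copy(),
        )

    def fitch_codes(self) -> np.ndarray:
        """Codes with MISSING expanded to the full alphabet (for optimization)."""
        codes = self.codes.copy()
        codes[codes == 0] = FULL_MASK
        return codes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.outgroup == other.outgroup
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.partition, other.partition)
            and np.array_equal(self.ordered, other.ordered)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays: identity hash
        return object.__hash__(self)


def _is_interval(mask: int) -> bool:
    if mask == 0:
        return False
    while mask & 1 == 0:
        mask >>= 1
    return (mask & (mask + 1)) == 0


# ----------------------------------------------------------------------
# cell token parsing/formatting shared by both dialects
# ----------------------------------------------------------------------

def _parse_row_tokens(seq: str, path: str, lineno: int) -> list[int]:
    masks: list[int] = []
    i, n = 0, len(seq)
    while i < n:
        ch = seq[i]
        if ch in "?-":
            masks.append(0)
            i += 1
        elif ch.isdigit():
            masks.append(1 << int(ch))
            i += 1
        elif ch in "{([":
            closer = {"{": "}", "(": ")", "[": "]"}[ch]
            j = seq.find(closer, i)
            if j < 0:
                raise MatrixParseError(f"{path}:{lineno}: unclosed {ch!r} in row")
            group = seq[i + 1 : j]
            if not group or not all(c.isdigit() for c in group):
                raise MatrixParseError(f"{path}:{lineno}: bad polymorphism token {seq[i:j+1]!r}")
            masks.append(states_to_mask(int(c) for c in group))
            i = j + 1
        elif ch.isspace():
            i += 1
        else:
            raise MatrixParseError(f"{path}:{lineno}: unexpected symbol {ch!r} in row")
    return masks


def _format_cell(mask: int) -> str:
    if mask == 0:
        return "?"
    states = sorted(mask_to_states(mask))
    if len(states) == 1:
        return str(states[0])
    return "{" + "".join(str(s) for s in states) + "}"


def _format_row(row: np.ndarray) -> str:
    return "".join(_format_cell(int(m)) for m in row)


# ----------------------------------------------------------------------
# TNT xread dialect
# ----------------------------------------------------------------------

def _read_tnt(path: Path) -> tuple[list[str], list[list[int]]]:
    text = path.read_text()
    lines = text.splitlines()
    header_idx = None
    for idx, line in enumerate(lines):
        if line.strip().lower().startswith("xread"):
            header_idx = idx
            break
    if header_idx is None:
        raise MatrixParseError(f"{path}:1: no 'xread' block found")
    # collect tokens after xread; optional quoted title, then nchar ntax
    rest = "\n".join(lines[header_idx:])
    rest = rest[rest.lower().find("xread") + 5 :]
    rest = re.sub(r"'[^']*'", " ", rest, count=1)  # drop optional title
    m = re.match(r"\s*(\d+)\s+(\d+)\s*\n?", rest)
    if not m:
        raise MatrixParseError(f"{path}:{header_idx + 1}: expected 'nchar ntax' after xread")
    n_char, n_taxa = int(m.group(1)), int(m.group(2))
    body = rest[m.end() :]
    if ";" in body:
        body = body[: body.index(";")]
    taxa: list[str] = []
    rows: list[list[int]] = []
    offset = header_idx + 2
    for k, line in enumerate(body.splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixParseError(f"{path}:{offset + k}: expected 'taxon states' on line")
        name, seq = parts
        masks = _parse_row_tokens(seq, str(path), offset + k)
        if name in taxa:  # interleaved continuation
            rows[taxa.index(name)].extend(masks)
        else:
            taxa.append(name)
            rows.append(masks)
    if len(taxa) != n_taxa:
        raise MatrixParseError(
            f"{path}: header declares {n_taxa} taxa but {len(taxa)} rows found"
        )
    for name, row in zip(taxa, rows):
        if len(row) != n_char:
            raise MatrixParseError(
                f"{path}: taxon {name!r} has {len(row)} characters, header declares {n_char}"
            )
    return taxa, rows


def _write_tnt(matrix: CharacterMatrix, path: Path) -> None:
    lines = [f"xread {matrix.n_char} {matrix.n_taxa}"]
    width = max(len(t) for t in matrix.taxa) + 2
    for i, taxon in enumerate(matrix.taxa):
        lines.append(f"{taxon:<{width}}{_format_row(matrix.codes[i])}")
    lines.append(";")
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# NEXUS dialect (DATA/CHARACTERS block; parsing delegated to dendropy)
# ----------------------------------------------------------------------

def _read_nexus(path: Path) -> tuple[list[str], list[list[int]]]:
    import dendropy

    try:
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises schema-specific errors
        raise MatrixParseError(f"{path}: NEXUS parse failed: {exc}") from exc
    taxa: list[str] = []
    rows: list[list[int]] = []
    for tx in dmat.taxon_namespace:
        label = str(tx.label).replace(" ", "_")
        row_masks: list[int] = []
        for cell in dmat[tx]:
            if cell.member_states:
                symbols = {s.symbol for s in cell.member_states}
                if "?" in symbols or "-" in symbols or len(symbols) >= N_SYMBOLS:
                    row_masks.append(0)
                else:
                    row_masks.append(states_to_mask(int(s) for s in symbols))
            else:
                sym = cell.symbol
                if sym in ("?", "-") or sym is None:
                    row_masks.append(0)
                else:
                    if not str(sym).isdigit():
                        raise MatrixParseError(f"{path}: non-numeric state symbol {sym!r}")
                    row_masks.append(1 << int(sym))
        taxa.append(label)
        rows.append(row_masks)
    return taxa, rows


def _write_nexus(matrix: CharacterMatrix, path: Path) -> None:
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};",
        '  FORMAT SYMBOLS="0123456789" MISSING=? GAP=-;',
        "  MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for i, taxon in enumerate(matrix.taxa):
        lines.append(f"    {taxon:<{width}}{_format_row(matrix.codes[i])}")
    lines.extend(["  ;", "END;"])
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# partition sidecar and matrix config
# ----------------------------------------------------------------------

def read_partition_csv(path: str | Path, n_char: int) -> np.ndarray:
    """Read a per-character partition CSV (columns: char_index 1-based, label)."""
    path = Path(path)
    labels: dict[int, Partition] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].strip().lower() in ("char_index", "index", ""):
                continue
            if len(row) < 2:
                raise MatrixParseError(f"{path}:{lineno}: expected 'char_index,label'")
            try:
                idx = int(row[0])
            except ValueError:
                raise MatrixParseError(f"{path}:{lineno}: bad character index {row[0]!r}") from None
            if idx in labels:
                raise MatrixValidationError(f"{path}: duplicate partition entry for character {idx}")
            labels[idx] = Partition.from_label(row[1])
    if set(labels) != set(range(1, n_char + 1)):
        raise MatrixValidationError(
            f"{path}: partition file labels {len(labels)} characters "
            f"but the matrix has {n_char}"
        )
    return np.array([int(labels[i]) for i in range(1, n_char + 1)], dtype=np.int8)


def write_partition_csv(partition: np.ndarray, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["char_index", "label"])
        for i, p in enumerate(partition, start=1):
            writer.writerow([i, Partition(int(p)).label])


def read_matrix_config(path: str | Path) -> dict:
    """Read the small YAML/JSON sidecar giving outgroup and ordered characters."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "outgroup" not in cfg:
        raise MatrixValidationError(f"{path}: config must be a mapping with an 'outgroup' key")
    return cfg


# ----------------------------------------------------------------------
# public readers/writers
# ----------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    if path.suffix.lower() in (".nex", ".nexus", ".nxs"):
        return "nexus"
    if path.suffix.lower() in (".tnt", ".ss"):
        return "tnt"
    head = path.read_text(errors="replace")[:64].lstrip().lower()
    return "nexus" if head.startswith("#nexus") else "tnt"


def read_matrix(
    path: str | Path,
    format: str | None = None,
    partition_path: str | Path | None = None,
    *,
    outgroup: str | None = None,
    config_path: str | Path | None = None,
    ordered: Sequence[int] = (),
) -> CharacterMatrix:
    """Read a morphological matrix plus its partition sidecar.

    ``outgroup`` (and optionally 1-based ``ordered`` character indices) may be
    given directly or through a small YAML config file.  Exactly one source
    for the outgroup is required.
    """
    path = Path(path)
    fmt = (format or _infer_format(path)).lower()
    if fmt == "tnt":
        taxa, rows = _read_tnt(path)
    elif fmt == "nexus":
        taxa, rows = _read_nexus(path)
    else:
        raise StemwardError(f"unknown matrix format {format!r}")
    if len(set(taxa)) != len(taxa):
        raise MatrixValidationError(f"{path}: duplicate taxon labels")
    codes = np.array(rows, dtype=np.int64)
    if config_path is not None:
        cfg = read_matrix_config(config_path)
        outgroup = outgroup or cfg.get("outgroup")
        ordered = tuple(ordered) or tuple(cfg.get("ordered", ()))
    if outgroup is None:
        raise MatrixValidationError("an outgroup taxon must be specified")
    if partition_path is None:
        raise MatrixValidationError("a partition sidecar file is required")
    partition = read_partition_csv(partition_path, codes.shape[1])
    ordered_flags = np.zeros(codes.shape[1], dtype=bool)
    for idx in ordered:
        if not 1 <= int(idx) <= codes.shape[1]:
            raise MatrixValidationError(f"ordered character index {idx} out of range")
        ordered_flags[int(idx) - 1] = True
    return CharacterMatrix(
        taxa=tuple(taxa), codes=codes, partition=partition,
        outgroup=str(outgroup), ordered=ordered_flags,
    )


def write_matrix(
    matrix: CharacterMatrix,
    path: str | Path,
    format: str = "tnt",
    partition_path: str | Path | None = None,
) -> None:
    """Write the matrix (and, if requested, its partition sidecar).

    Output is canonical: re-reading and re-writing is byte-stable.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "tnt":
        _write_tnt(matrix, path)
    elif fmt == "nexus":
        _write_nexus(matrix, path)
    else:
        raise StemwardError(f"unknown matrix format {format!r}")
    if partition_path is not None:
        write_partition_csv(matrix.partition, partition_path)
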