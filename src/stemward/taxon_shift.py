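"""Taxon shift test (stemward slippage).

Each taxon in turn is simulated as a fossil: its soft cells are
blanked, the matrix is re-searched, and the taxon's mean distance to
the root over all MPTs is compared with its original mean distance.
The matched null blanks the same number of that taxon's scored cells at
random.  The shift magnitude is judged against the null by rank:
``p = (#{|null delta| >= |delta|} + 1) / (n_reps + 1)``.

Sign convention: negative delta = toward the root = "down" (stemward);
positive = away from the root = "up" (crownward).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import CharacterMatrix, StemwardError
from .parsimony import SearchSettings, heuristic_search, mean_root_distance
from .perturb import fossilize_taxon, randomize_taxon, scored_soft_cells
from .stats import rank_p
from .trees import TreeSet

__all__ = [
    "MOVE_TOL",
    "TaxonShiftResult",
    "ShiftSummary",
    "run_taxon_shift",
    "run_all_taxon_shifts",
    "classify_shift",
    "summarize_shifts",
]

# a taxon "moved" when |delta| exceeds this float-noise tolerance
MOVE_TOL = 1e-9


@dataclass
class TaxonShiftResult:
    matrix_id: str
    taxon: str
    metric: str
    k_deleted: int
    d_orig: float
    d_foss: float
    delta: float
    null_deltas: np.ndarray
    p_magnitude: float
    unperturbable: bool = False
    alpha: float = 0.05

    @property
    def direction(self) -> str:
        if self.delta < -MOVE_TOL:
            return "down"
        if self.delta > MOVE_TOL:
            return "up"
        return "none"

    @property
    def moved(self) -> bool:
        return self.direction != "none"

    @property
    def significant(self) -> bool:
        return self.moved and self.p_magnitude <= self.alpha

    def as_row(self) -> dict:
        nd = self.null_deltas
        return {
            "matrix_id": self.matrix_id,
            "taxon": self.taxon,
            "metric": self.metric,
            "k_deleted": self.k_deleted,
            "d_orig": self.d_orig,
            "d_foss": self.d_foss,
            "delta": self.delta,
            "null_mean": float(nd.mean()) if len(nd) else float("nan"),
            "null_sd": float(nd.std(ddof=1)) if len(nd) > 1 else float("nan"),
            "p_magnitude": self.p_magnitude,
            "direction": self.direction,
            "significant": self.significant,
            "unperturbable": self.unperturbable,
        }


@dataclass
class ShiftSummary:
    """Pooled direction counts over many taxon-shift results."""

    condition: str                  # {"fossilization", "random"}
    n_taxa: int = 0
    moved: int = 0
    moved_down: int = 0
    moved_up: int = 0
    significant: int = 0
    significant_down: int = 0
    significant_up: int = 0

    @property
    def down_fraction(self) -> float:
        return self.moved_down / self.moved if self.moved else float("nan")

    @property
    def significant_down_fraction(self) -> float:
        return self.significant_down / self.significant if self.significant else float("nan")

    def as_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_taxa": self.n_taxa,
            "moved": self.moved,
            "moved_down": self.moved_down,
            "moved_up": self.moved_up,
            "down_fraction": self.down_fraction,
            "significant": self.significant,
            "significant_down": self.significant_down,
            "significant_up": self.significant_up,
            "significant_down_fraction": self.significant_down_fraction,
        }


def run_taxon_shift(
    matrix: CharacterMatrix,
    taxon: str,
    n_reps: int = 500,
    metric: str = "nodes",
    settings: SearchSettings | None = None,
    rng_seed: int | None = None,
    matrix_id: str = "matrix",
    original: TreeSet | None = None,
    alpha: float = 0.05,
) -> TaxonShiftResult:
    """Pseudofossilize one taxon and measure its root-distance shift.

    ``original`` may carry a pre-computed full-matrix search shared
    across the taxa of one matrix.  The outgroup cannot be fossilized.
    """
    if taxon == matrix.outgroup:
        raise StemwardError("the outgroup anchors the root and is never fossilized")
    if taxon not in matrix.taxa:
        raise StemwardError(f"taxon {taxon!r} not in matrix")
    settings = settings or SearchSettings()
    base_seed = rng_seed if rng_seed is not None else (settings.rng_seed or 0)
    ss = np.random.SeedSequence([int(base_seed) % (2**31), 2, matrix.taxon_index(taxon)])
    seeds = [int(s) % (2**31) for s in ss.generate_state(n_reps + 2)]
    if original is None:
        original = heuristic_search(matrix, replace(settings, rng_seed=seeds[0]))
    d_orig = mean_root_distance(original, taxon, metric, matrix)
    k = len(scored_soft_cells(matrix, taxon))
    if k == 0:
        return TaxonShiftResult(
            matrix_id=matrix_id, taxon=taxon, metric=metric, k_deleted=0,
            d_orig=d_orig, d_foss=d_orig, delta=0.0,
            null_deltas=np.zeros(n_reps), p_magnitude=1.0,
            unperturbable=True, alpha=alpha,
        )
    foss = fossilize_taxon(matrix, taxon)
    ts = heuristic_search(foss, replace(settings, rng_seed=seeds[1]))
    d_foss = mean_root_distance(ts, taxon, metric, foss)
    delta = d_foss - d_orig
    null_deltas = np.zeros(n_reps)
    for i in range(n_reps):
        rep_rng = np.random.default_rng(seeds[2 + i])
        null_matrix = randomize_taxon(matrix, taxon, k, rep_rng)
        nts = heuristic_search(null_matrix, replace(settings, rng_seed=seeds[2 + i]))
        null_deltas[i] = mean_root_distance(nts, taxon, metric, null_matrix) - d_orig
    p = rank_p(int((np.abs(null_deltas) >= abs(delta) - 1e-12).sum()), n_reps)
    return TaxonShiftResult(
        matrix_id=matrix_id, taxon=taxon, metric=metric, k_deleted=k,
        d_orig=d_orig, d_foss=d_foss, delta=delta,
        null_deltas=null_deltas, p_magnitude=p, alpha=alpha,
    )


def run_all_taxon_shifts(
    matrix: CharacterMatrix,
    n_reps: int = 500,
    metric: str = "nodes",
    settings: SearchSettings | None = None,
    rng_seed: int | None = None,
    matrix_id: str = "matrix",
    taxa: list[str] | None = None,
    alpha: float = 0.05,
) -> list[TaxonShiftResult]:
    """Taxon-shift test for every (ingroup) taxon of one matrix.

    The original full-matrix search is performed once and shared.
    """
    settings = settings or SearchSettings()
    base_seed = rng_seed if rng_seed is not None else (settings.rng_seed or 0)
    ss = np.random.SeedSequence([int(base_seed) % (2**31), 3])
    orig_seed = int(ss.generate_state(1)[0]) % (2**31)
    original = heuristic_search(matrix, replace(settings, rng_seed=orig_seed))
    targets = taxa if taxa is not None else [
        t for t in matrix.taxa if t != matrix.outgroup
    ]
    return [
        run_taxon_shift(
            matrix, t, n_reps=n_reps, metric=metric, settings=settings,
            rng_seed=base_seed, matrix_id=matrix_id, original=original,
            alpha=alpha,
        )
        for t in targets
    ]


def classify_shift(result: TaxonShiftResult, alpha: float = 0.05) -> tuple[str, bool]:
    """(direction, significant) for one result; delta == 0 is never significant."""
    direction = result.direction
    significant = direction != "none" and result.p_magnitude <= alpha
    return direction, significant


def summarize_shifts(
    results: list[TaxonShiftResult],
    condition: str = "fossilization",
    accounting: str = "per_replicate",
) -> ShiftSummary:
    """Pool direction counts.

    ``fossilization``: each taxon contributes its systematic shift.
    ``random``: by default each taxon contributes every null
    replicate's direction (``accounting='per_replicate'``), with a
    replicate judged significant if its magnitude is in the top alpha
    fraction of that taxon's own null distribution.  With
    ``accounting='per_taxon_mean'`` each taxon contributes one entry --
    the direction of its mean random shift -- which is the appropriate
    unit for binomial calibration checks, since replicate directions
    within a taxon are strongly correlated.
    """
    s = ShiftSummary(condition=condition)
    if condition == "fossilization":
        for r in results:
            s.n_taxa += 1
            d, sig = classify_shift(r, r.alpha)
            if d == "down":
                s.moved += 1
                s.moved_down += 1
            elif d == "up":
                s.moved += 1
                s.moved_up += 1
            if sig:
                s.significant += 1
                if d == "down":
                    s.significant_down += 1
                else:
                    s.significant_up += 1
        return s
    if condition == "random":
        if accounting == "per_taxon_mean":
            for r in results:
                s.n_taxa += 1
                mean_delta = float(np.mean(r.null_deltas)) if len(r.null_deltas) else 0.0
                if mean_delta < -MOVE_TOL:
                    s.moved += 1
                    s.moved_down += 1
                elif mean_delta > MOVE_TOL:
                    s.moved += 1
                    s.moved_up += 1
            return s
        if accounting != "per_replicate":
            raise StemwardError(f"unknown accounting {accounting!r}")
        for r in results:
            s.n_taxa += 1
            nd = r.null_deltas
            absnd = np.abs(nd)
            n = len(nd)
            for i, delta in enumerate(nd):
                if delta < -MOVE_TOL:
                    s.moved += 1
                    s.moved_down += 1
                elif delta > MOVE_TOL:
                    s.moved += 1
                    s.moved_up += 1
                else:
                    continue
                p_i = rank_p(int((absnd >= abs(delta) - 1e-12).sum()) - 1, n - 1)
                if p_i <= r.alpha:
                    s.significant += 1
                    if delta < 0:
                        s.significant_down += 1
                    else:
                        s.significant_up += 1
        return s
    raise StemwardError(f"unknown condition {condition!r}")
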