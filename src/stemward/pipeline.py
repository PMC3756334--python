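"""Experiment orchestration.

Runs the full protocol over a collection of matrices: curation ->
full-matrix searches -> node-recovery test (fossilization and inverse)
-> per-taxon shift test -> cross-dataset statistics and jackknife.
Every stochastic stage derives its seed deterministically from
``(master_seed, matrix index, stage)`` so a run is reproducible from
its manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .curation import Thresholds, curate
from .matrix import CharacterMatrix, StemwardError, read_matrix
from .node_recovery import (
    AggregateNodeRecovery,
    NodeRecoveryResult,
    aggregate_node_recovery,
    run_node_recovery,
)
from .parsimony import SearchSettings, heuristic_search
from .stats import ContingencyTable2x2, JackknifeReport, binomial_test, dataset_jackknife, g_test
from .taxon_shift import ShiftSummary, TaxonShiftResult, run_all_taxon_shifts, summarize_shifts

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "load_input_dir"]


@dataclass
class ExperimentConfig:
    """Replicates, thresholds and search effort for one full run."""

    n_reps: int = 500
    alpha: float = 0.05
    metric: str = "nodes"
    do_node_recovery: bool = True
    do_inverse: bool = True
    do_taxon_shift: bool = True
    jackknife_resamples: int = 50
    jackknife_inclusion_p: float = 0.5
    addition_replicates: int = 100
    hold_per_replicate: int = 1000
    max_trees: int = 10000

    @classmethod
    def paper(cls) -> "ExperimentConfig":
        return cls()

    @classmethod
    def desk(cls) -> "ExperimentConfig":
        """Reduced effort for simulation-scale runs on one workstation."""
        return cls(n_reps=100, addition_replicates=3,
                   hold_per_replicate=64, max_trees=64)

    def settings(self, seed: int | None = None) -> SearchSettings:
        return SearchSettings(
            n_addition_replicates=self.addition_replicates,
            hold_per_replicate=self.hold_per_replicate,
            max_trees=self.max_trees,
            rng_seed=seed,
        )


def _seed_for(master: int, *path: int) -> int:
    ss = np.random.SeedSequence([int(master) % (2**31), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0]) % (2**31)


@dataclass
class ExperimentReport:
    master_seed: int
    config: ExperimentConfig
    curation: dict = field(default_factory=dict)
    node_recovery: dict = field(default_factory=dict)       # mode -> [NodeRecoveryResult]
    aggregates: dict = field(default_factory=dict)          # mode -> AggregateNodeRecovery
    jackknife: dict = field(default_factory=dict)           # mode -> JackknifeReport
    taxon_shifts: list = field(default_factory=list)        # [TaxonShiftResult]
    shift_summaries: dict = field(default_factory=dict)     # condition -> ShiftSummary
    stats: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def node_recovery_table(self, mode: str = "fossilization") -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.node_recovery.get(mode, [])])

    def taxon_shift_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.taxon_shifts])

    def summary_dict(self) -> dict:
        out = {
            "master_seed": self.master_seed,
            "version": self.manifest.get("version"),
            "n_matrices": self.manifest.get("n_matrices"),
            "curation": self.curation,
            "stats": self.stats,
        }
        for mode, agg in self.aggregates.items():
            out[f"aggregate_{mode}"] = {
                "total_benchmark_nodes": agg.total_benchmark_nodes,
                "total_recovered": agg.total_recovered,
                "pooled_recovery": agg.pooled_recovery,
                "pooled_null_mean": agg.pooled_null_mean,
                "p_value": agg.p_value,
                "n_matrices": agg.n_matrices,
            }
        for cond, summ in self.shift_summaries.items():
            out[f"shift_{cond}"] = summ.as_dict()
        for mode, jk in self.jackknife.items():
            out[f"jackknife_{mode}"] = jk.as_dict()
        return out

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with (out_dir / "summary.json").open("w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, default=_json_default)
        with (out_dir / "manifest.json").open("w") as fh:
            json.dump(self.manifest, fh, indent=2, default=_json_default)
        for mode in self.node_recovery:
            self.node_recovery_table(mode).to_csv(
                out_dir / f"node_recovery_{mode}.tsv", sep="\t", index=False
            )
        if self.taxon_shifts:
            self.taxon_shift_table().to_csv(
                out_dir / "taxon_shift.tsv", sep="\t", index=False
            )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    return str(obj)


def load_input_dir(input_dir: str | Path) -> list[tuple[str, CharacterMatrix]]:
    """Load every matrix in a directory.

    Each matrix ``NAME.tnt`` / ``NAME.nex`` needs a partition sidecar
    ``NAME.partition.csv`` and a config ``NAME.yaml`` naming the
    outgroup (and any ordered characters).
    """
    input_dir = Path(input_dir)
    out = []
    for path in sorted(input_dir.iterdir()):
        if path.suffix.lower() not in (".tnt", ".nex", ".nexus", ".ss"):
            continue
        stem = path.stem
        part = input_dir / f"{stem}.partition.csv"
        cfg = input_dir / f"{stem}.yaml"
        if not part.exists():
            raise StemwardError(f"missing partition sidecar for {path.name}")
        if not cfg.exists():
            raise StemwardError(f"missing config (outgroup) for {path.name}")
        out.append((stem, read_matrix(path, partition_path=part, config_path=cfg)))
    if not out:
        raise StemwardError(f"no matrices found in {input_dir}")
    return out


def run_experiment(
    matrices: list[tuple[str, CharacterMatrix]],
    config: ExperimentConfig | None = None,
    master_seed: int = 0,
    thresholds: Thresholds | None = None,
    skip_curation: bool = False,
) -> ExperimentReport:
    """Run the complete protocol over named matrices.

    Matrices failing curation thresholds are skipped (recorded in the
    report); the remaining stages run on the curated matrices.
    """
    if not matrices:
        raise StemwardError("no input matrices")
    config = config or ExperimentConfig()
    report = ExperimentReport(master_seed=master_seed, config=config)
    t_start = time.time()
    included: list[tuple[str, CharacterMatrix]] = []
    cur_info = {}
    for mid, matrix in matrices:
        if skip_curation:
            included.append((mid, matrix))
            cur_info[mid] = {"include": True, "skipped_curation": True}
            continue
        curated, reports, decision = curate(matrix, thresholds)
        cur_info[mid] = {
            "include": decision.include,
            "violated": decision.violated,
            "n_taxa": decision.n_taxa,
            "n_char": decision.n_char,
            "steps": [r.as_dict() for r in reports],
        }
        if decision.include:
            included.append((mid, curated))
    report.curation = cur_info
    if not included:
        raise StemwardError("every matrix failed curation thresholds")

    modes = []
    if config.do_node_recovery:
        modes.append("fossilization")
        if config.do_inverse:
            modes.append("inverse_fossilization")
    timings = {}
    t0 = time.time()
    for mode in modes:
        results = []
        for i, (mid, matrix) in enumerate(included):
            bench_seed = _seed_for(master_seed, i, 0)
            benchmark = heuristic_search(matrix, config.settings(bench_seed))
            results.append(
                run_node_recovery(
                    matrix, mode=mode, n_reps=config.n_reps,
                    settings=config.settings(),
                    rng_seed=_seed_for(master_seed, i, 1 if mode == "fossilization" else 2),
                    matrix_id=mid, benchmark=benchmark,
                )
            )
        report.node_recovery[mode] = results
        report.aggregates[mode] = aggregate_node_recovery(results)
        report.jackknife[mode] = dataset_jackknife(
            results, n_resamples=config.jackknife_resamples,
            inclusion_p=config.jackknife_inclusion_p,
            rng=np.random.default_rng(_seed_for(master_seed, 0, 9)),
            alpha=config.alpha,
        )
    timings["node_recovery_s"] = time.time() - t0

    t0 = time.time()
    if config.do_taxon_shift:
        all_shifts: list[TaxonShiftResult] = []
        for i, (mid, matrix) in enumerate(included):
            all_shifts.extend(
                run_all_taxon_shifts(
                    matrix, n_reps=config.n_reps, metric=config.metric,
                    settings=config.settings(),
                    rng_seed=_seed_for(master_seed, i, 3),
                    matrix_id=mid, alpha=config.alpha,
                )
            )
        report.taxon_shifts = all_shifts
        foss = summarize_shifts(all_shifts, "fossilization")
        rand = summarize_shifts(all_shifts, "random")
        report.shift_summaries = {"fossilization": foss, "random": rand}
        stats: dict = {}
        if foss.moved and rand.moved:
            table = ContingencyTable2x2(
                ((foss.moved_down, foss.moved_up), (rand.moved_down, rand.moved_up))
            )
            g = g_test(table)
            stats["g_test"] = {"G": g.G, "p_value": g.p_value,
                               "table": [list(r) for r in table.counts]}
        if foss.moved:
            stats["binomial_moved_down"] = {
                "k": foss.moved_down, "n": foss.moved,
                "p_two": binomial_test(foss.moved_down, foss.moved, 0.5, "two"),
                "p_one": binomial_test(foss.moved_down, foss.moved, 0.5, "one"),
            }
        if foss.significant:
            stats["binomial_significant_down"] = {
                "k": foss.significant_down, "n": foss.significant,
                "p_two": binomial_test(foss.significant_down, foss.significant, 0.5, "two"),
                "p_one": binomial_test(foss.significant_down, foss.significant, 0.5, "one"),
            }
        report.stats = stats
    timings["taxon_shift_s"] = time.time() - t0

    report.manifest = {
        "version": _pkg_version,
        "master_seed": master_seed,
        "config": asdict(config),
        "n_matrices": len(included),
        "matrix_ids": [mid for mid, _ in included],
        "per_matrix_seeds": {
            mid: {
                "benchmark": _seed_for(master_seed, i, 0),
                "node_recovery": _seed_for(master_seed, i, 1),
                "inverse": _seed_for(master_seed, i, 2),
                "taxon_shift": _seed_for(master_seed, i, 3),
            }
            for i, (mid, _) in enumerate(included)
        },
        "timings_s": timings,
        "wall_s": time.time() - t_start,
    }
    return report
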