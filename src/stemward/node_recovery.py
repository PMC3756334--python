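"""Node recovery test.

How much of the original strict-consensus topology survives when the
soft partition is deleted wholesale, compared with deleting the same
number of characters at random?  The benchmark is the strict consensus
of the full-matrix search; the systematic condition deletes all soft
characters (fossilization) or all hard characters (inverse
fossilization); the null repeats the search after random deletions of
the same count.  Significance is the rank of the systematic recovery
index in the null distribution, one-tailed low:
``p = (#{null <= systematic} + 1) / (n_reps + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix, MatrixValidationError, Partition, StemwardError
from .parsimony import SearchSettings, heuristic_search, strict_consensus
from .perturb import delete_partition_characters, delete_random_characters
from .stats import rank_p
from .trees import PhyloTree, TreeSet

__all__ = [
    "NodeRecoveryResult",
    "AggregateNodeRecovery",
    "node_recovery_index",
    "run_node_recovery",
    "aggregate_node_recovery",
]


@dataclass
class NodeRecoveryResult:
    matrix_id: str
    mode: str                       # {"fossilization", "inverse_fossilization"}
    benchmark_nodes: int
    recovered: int
    recovery_index: float
    k_deleted: int
    null_recovered: np.ndarray      # per-replicate recovered-node counts
    null_indices: np.ndarray
    p_value: float
    flagged: list[str] = field(default_factory=list)

    @property
    def n_reps(self) -> int:
        return len(self.null_indices)

    @property
    def undefined(self) -> bool:
        return self.benchmark_nodes == 0

    def as_row(self) -> dict:
        return {
            "matrix_id": self.matrix_id,
            "mode": self.mode,
            "benchmark_nodes": self.benchmark_nodes,
            "recovered": self.recovered,
            "recovery_index": self.recovery_index,
            "k_deleted": self.k_deleted,
            "null_mean": float(self.null_indices.mean()) if self.n_reps else float("nan"),
            "null_sd": float(self.null_indices.std(ddof=1)) if self.n_reps > 1 else float("nan"),
            "p_value": self.p_value,
            "flagged": ";".join(self.flagged),
        }


@dataclass
class AggregateNodeRecovery:
    """Pooled comparison across matrices (counts, not mean-of-fractions)."""

    mode: str
    total_benchmark_nodes: int
    total_recovered: int
    pooled_recovery: float
    pooled_null: np.ndarray   # i-th entry pools every matrix's i-th replicate
    p_value: float
    n_matrices: int

    @property
    def pooled_null_mean(self) -> float:
        return float(self.pooled_null.mean())


def node_recovery_index(benchmark: PhyloTree, test: PhyloTree) -> float:
    """Fraction of the benchmark's clades present in the test tree."""
    if set(benchmark.labels) != set(test.labels):
        raise StemwardError("node recovery requires identical leaf sets")
    bench = benchmark.clade_set()
    if not bench:
        raise StemwardError("benchmark consensus has no non-trivial clades")
    return len(bench & test.clade_set()) / len(bench)


def _consensus_recovered(matrix: CharacterMatrix, bench_clades: frozenset,
                         settings: SearchSettings, seed: int) -> int:
    from dataclasses import replace

    ts = heuristic_search(matrix, replace(settings, rng_seed=seed))
    cons = strict_consensus(ts)
    return len(bench_clades & cons.clade_set())


def run_node_recovery(
    matrix: CharacterMatrix,
    mode: str = "fossilization",
    n_reps: int = 500,
    settings: SearchSettings | None = None,
    rng_seed: int | None = None,
    matrix_id: str = "matrix",
    benchmark: TreeSet | None = None,
) -> NodeRecoveryResult:
    """Full node-recovery test for one matrix.

    ``benchmark`` may be passed to reuse an existing full-matrix search
    (e.g. when running both modes).  All searches are seeded
    deterministically from ``rng_seed``.
    """
    if mode not in ("fossilization", "inverse_fossilization"):
        raise StemwardError(f"unknown mode {mode!r}")
    settings = settings or SearchSettings()
    base_seed = rng_seed if rng_seed is not None else (settings.rng_seed or 0)
    ss = np.random.SeedSequence([int(base_seed) % (2**31), 1])
    seeds = [int(s) % (2**31) for s in ss.generate_state(n_reps + 2)]
    flagged: list[str] = []
    if benchmark is None:
        from dataclasses import replace

        benchmark = heuristic_search(matrix, replace(settings, rng_seed=seeds[0]))
    bench_cons = strict_consensus(benchmark)
    bench_clades = bench_cons.clade_set()
    benchmark_nodes = len(bench_clades)
    which = Partition.SOFT if mode == "fossilization" else Partition.HARD
    k = int((matrix.partition == int(which)).sum())
    if benchmark_nodes == 0:
        flagged.append("benchmark consensus unresolved; recovery index undefined")
        return NodeRecoveryResult(
            matrix_id=matrix_id, mode=mode, benchmark_nodes=0, recovered=0,
            recovery_index=float("nan"), k_deleted=k,
            null_recovered=np.zeros(n_reps, dtype=np.int64),
            null_indices=np.full(n_reps, np.nan), p_value=float("nan"),
            flagged=flagged,
        )
    # systematic deletion
    try:
        sys_matrix = delete_partition_characters(matrix, which)
        recovered = _consensus_recovered(sys_matrix, bench_clades, settings, seeds[1])
    except MatrixValidationError:
        flagged.append("systematic deletion left no characters; recovery recorded as 0")
        recovered = 0
    sys_index = recovered / benchmark_nodes
    # random-deletion null, matched k
    null_recovered = np.zeros(n_reps, dtype=np.int64)
    for i in range(n_reps):
        rep_rng = np.random.default_rng(seeds[2 + i])
        try:
            null_matrix = delete_random_characters(matrix, k, rep_rng)
            null_recovered[i] = _consensus_recovered(
                null_matrix, bench_clades, settings, seeds[2 + i]
            )
        except MatrixValidationError:
            flagged.append(f"replicate {i}: deletion left no characters; recovery 0")
            null_recovered[i] = 0
    null_indices = null_recovered / benchmark_nodes
    p = rank_p(int((null_indices <= sys_index + 1e-12).sum()), n_reps)
    return NodeRecoveryResult(
        matrix_id=matrix_id, mode=mode, benchmark_nodes=benchmark_nodes,
        recovered=recovered, recovery_index=sys_index, k_deleted=k,
        null_recovered=null_recovered, null_indices=null_indices,
        p_value=p, flagged=flagged,
    )


def aggregate_node_recovery(results: list[NodeRecoveryResult]) -> AggregateNodeRecovery:
    """Pool raw node counts across matrices.

    The i-th pooled null value combines every matrix's i-th random
    replicate, preserving the pairing of replicates across matrices; the
    pooled p-value applies the same one-tailed rank formula.  Matrices
    with an undefined (zero-node) benchmark are excluded.
    """
    usable = [r for r in results if not r.undefined]
    if not usable:
        raise StemwardError("no usable node-recovery results to aggregate")
    n_reps = {r.n_reps for r in usable}
    if len(n_reps) != 1:
        raise StemwardError("results have differing replicate counts")
    n_reps = n_reps.pop()
    modes = {r.mode for r in usable}
    if len(modes) != 1:
        raise StemwardError("cannot pool across modes")
    total_bench = sum(r.benchmark_nodes for r in usable)
    total_rec = sum(r.recovered for r in usable)
    pooled = total_rec / total_bench
    pooled_null = (
        np.sum([r.null_recovered for r in usable], axis=0) / total_bench
    )
    p = rank_p(int((pooled_null <= pooled + 1e-12).sum()), n_reps)
    return AggregateNodeRecovery(
        mode=modes.pop(), total_benchmark_nodes=total_bench,
        total_recovered=total_rec, pooled_recovery=pooled,
        pooled_null=pooled_null, p_value=p, n_matrices=len(usable),
    )
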