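"""Synthetic partitioned matrices with known generating trees.

The generator emulates the kind of neontological data the experiment
runs on: a Yule topology over 10-40 ingroup taxa plus an outgroup
attached at the root, and >= 30 binary characters split into hard
(biomineralized) and soft (non-biomineralized) partitions.

Two signal modes:

``exchangeable``
    Both partitions place their character changes uniformly over the
    parsimony-informative edges; swapping the HARD/SOFT labels yields a
    statistically indistinguishable experiment.  This is the null
    configuration used to calibrate the permutation tests.

``decay_biased``
    Soft characters preferentially change on crownward (tipward) edges
    and hard characters on rootward edges, emulating the taphonomic
    premise that derived synapomorphies diagnosing crown groups reside
    in soft anatomy.  Because a tree has few deep edges and many shallow
    ones, hard signal is redundant where soft signal is spread thin --
    removing the soft partition then costs many shallow nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .curation import Thresholds, apply_inclusion_thresholds, curate
from .matrix import CharacterMatrix, Partition, StemwardError
from .trees import PhyloTree

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_tree",
    "evolve_matrix",
    "make_benchmark_suite",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    ``crown_bias`` is the proportion of soft-character changes placed on
    the crownward (small-clade) zone of informative edges in
    decay-biased mode; ``deep_bias`` the proportion of hard-character
    changes on the rootward (large-clade) zone.  ``homoplasy_rate`` is
    the expected number of extra convergent changes per character
    (Poisson); the default of 1 extra change per character gives
    consistency indices near 0.5, typical of real morphological
    matrices -- much cleaner data makes random-missingness nulls
    artificially one-sided, because deleting cells from a
    low-homoplasy matrix can only release a taxon rootward.
    """

    n_taxa: int = 15               # ingroup leaves; one outgroup is added
    n_hard: int = 30
    n_soft: int = 30
    n_states: int = 2
    signal_mode: str = "exchangeable"  # {"exchangeable", "decay_biased"}
    homoplasy_rate: float = 1.0
    crown_bias: float = 0.8
    deep_bias: float = 0.6
    missing_rate_hard: float = 0.1
    missing_rate_soft: float = 0.1
    outgroup_label: str = "OUT"
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise StemwardError("need at least 4 ingroup taxa")
        if not 2 <= self.n_states <= 10:
            raise StemwardError("n_states must be between 2 and 10")
        for p in (self.crown_bias, self.deep_bias,
                  self.missing_rate_hard, self.missing_rate_soft):
            if not 0.0 <= p <= 1.0:
                raise StemwardError("probabilities must lie in [0, 1]")
        if self.homoplasy_rate < 0:
            raise StemwardError("homoplasy_rate must be non-negative")
        if self.signal_mode not in ("exchangeable", "decay_biased"):
            raise StemwardError(f"unknown signal mode {self.signal_mode!r}")


@dataclass
class SyntheticDataset:
    """A generated matrix plus the truth that produced it."""

    matrix: CharacterMatrix
    true_edges: np.ndarray          # unrooted edges, leaf ids match matrix taxa
    spec: SyntheticSpec
    seed: int | None
    change_edges: list[list[int]]   # per character: child-node ids of change edges
    eligible_edges: list[int]
    crown_zone: list[int]
    deep_zone: list[int]

    @property
    def true_tree(self) -> PhyloTree:
        return PhyloTree.from_unrooted(
            self.true_edges, self.matrix.taxa, self.matrix.outgroup
        )

    def manifest(self) -> dict:
        from dataclasses import asdict

        return {"spec": asdict(self.spec), "seed": self.seed}


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_tree(spec: SyntheticSpec, rng) -> dict:
    """Yule (uniform-split) ingroup topology with the outgroup at the root.

    Returns a truth record with the unrooted edge array, taxon labels
    (ingroup ``T01..`` then the outgroup), per-node depths and parents.
    Leaf ids 0..n-1 are ingroup, id n is the outgroup; internal ids
    follow.
    """
    gen = _as_rng(rng)
    n = spec.n_taxa
    L = n + 1
    og = n
    # grow a rooted ingroup tree by splitting uniformly chosen leaves
    next_internal = L  # ids L..2L-3
    root = next_internal
    next_internal += 1
    children: dict[int, list[int]] = {root: [0, 1]}
    parent = {0: root, 1: root}
    leaves = [0, 1]
    for new_leaf in range(2, n):
        split = leaves[int(gen.integers(len(leaves)))]
        node = next_internal
        next_internal += 1
        par = parent[split]
        children[par][children[par].index(split)] = node
        children[node] = [split, new_leaf]
        parent[split] = node
        parent[new_leaf] = node
        parent[node] = par
        leaves.append(new_leaf)
    # outgroup attaches at the ingroup root, making it degree 3 (unrooted)
    parent[og] = root
    edges = [(og, root)]
    depth = {root: 0}
    stack = [root]
    order = [root]
    while stack:
        v = stack.pop()
        for w in children.get(v, []):
            edges.append((v, w))
            depth[w] = depth[v] + 1
            order.append(w)
            if w in children:
                stack.append(w)
    # clade sizes (ingroup leaves below each node)
    size = {}
    for v in reversed(order):
        if v < n:
            size[v] = 1
        else:
            size[v] = sum(size[w] for w in children[v])
    eligible = [w for w in order if w != root and 2 <= size.get(w, 1) <= n - 1]
    eligible.sort(key=lambda w: (depth[w], w))
    # Zones by clade size, the cladistic depth proxy: crownward edges
    # subtend small clades (cherries and near-cherries -- numerous, so
    # crown-biased signal is spread thin), rootward edges subtend large
    # clades (few, so root-biased signal is redundant).
    deep_zone = [w for w in eligible if size[w] >= max(4, (n + 1) // 2)]
    if not deep_zone:  # tiny trees: fall back to the largest clade
        biggest = max(size[w] for w in eligible)
        deep_zone = [w for w in eligible if size[w] == biggest]
    crown_zone = [w for w in eligible if size[w] <= 3 and w not in deep_zone]
    if not crown_zone:
        smallest = min(size[w] for w in eligible)
        crown_zone = [w for w in eligible if size[w] == smallest and w not in deep_zone]
    labels = tuple(f"T{i + 1:02d}" for i in range(n)) + (spec.outgroup_label,)
    # homoplasy may hit any ingroup edge, terminal edges included
    # (autapomorphic convergence keeps sister taxa distinguishable)
    homoplasy_pool = [w for w in order if w != root]
    edge_arr = np.array(sorted((min(a, b), max(a, b)) for a, b in edges), dtype=np.int64)
    return {
        "homoplasy_pool": homoplasy_pool,
        "edges": edge_arr,
        "labels": labels,
        "children": children,
        "parent": parent,
        "depth": depth,
        "size": size,
        "eligible": eligible,
        "crown_zone": crown_zone,
        "deep_zone": deep_zone,
        "root": root,
        "n_ingroup": n,
    }


def _pick_edge(spec: SyntheticSpec, part: Partition, truth: dict,
               gen: np.random.Generator) -> int:
    eligible = truth["eligible"]
    if spec.signal_mode == "exchangeable":
        return int(eligible[int(gen.integers(len(eligible)))])
    if part is Partition.SOFT:
        zone, bias = truth["crown_zone"], spec.crown_bias
    else:
        zone, bias = truth["deep_zone"], spec.deep_bias
    rest = [e for e in eligible if e not in zone]
    if gen.random() < bias or not rest:
        return int(zone[int(gen.integers(len(zone)))])
    return int(rest[int(gen.integers(len(rest)))])


def evolve_matrix(truth: dict, spec: SyntheticSpec, rng) -> SyntheticDataset:
    """Drop character changes onto the tree and read off leaf states.

    Each character receives one primary change on an informative edge
    chosen by the signal mode, plus (with probability ``homoplasy_rate``)
    one convergent change on a uniformly random ingroup edge (terminal
    edges included).
    States start at 0 at the root (the outgroup is ancestral) and step
    to the next state at each change edge.  MISSING cells are then
    injected per partition.
    """
    gen = _as_rng(rng)
    n = truth["n_ingroup"]
    L = n + 1
    labels = truth["labels"]
    children = truth["children"]
    root = truth["root"]
    n_char = spec.n_hard + spec.n_soft
    partition = np.array(
        [int(Partition.HARD)] * spec.n_hard + [int(Partition.SOFT)] * spec.n_soft,
        dtype=np.int8,
    )
    codes = np.zeros((L, n_char), dtype=np.int64)
    change_edges: list[list[int]] = []
    eligible = truth["eligible"]
    for j in range(n_char):
        part = Partition(int(partition[j]))
        changes = [_pick_edge(spec, part, truth, gen)]
        pool = truth["homoplasy_pool"]
        for _ in range(int(gen.poisson(spec.homoplasy_rate))):
            changes.append(int(pool[int(gen.integers(len(pool)))]))
        change_edges.append(changes)
        # propagate states from the root (state 0); a change edge is the
        # edge above the recorded child node
        state = {root: 0}
        stack = [root]
        while stack:
            v = stack.pop()
            for w in children.get(v, []):
                s = (state[v] + changes.count(w)) % spec.n_states
                state[w] = s
                if w in children:
                    stack.append(w)
        for i in range(n):
            codes[i, j] = 1 << state.get(i, 0)
        codes[n, j] = 1 << 0  # outgroup keeps the ancestral state
    # inject missing data per partition
    for part, rate in ((Partition.HARD, spec.missing_rate_hard),
                       (Partition.SOFT, spec.missing_rate_soft)):
        cols = np.nonzero(partition == int(part))[0]
        if rate > 0 and len(cols):
            mask = gen.random((L, len(cols))) < rate
            sub = codes[:, cols]
            sub[mask] = 0
            codes[:, cols] = sub
    matrix = CharacterMatrix(
        taxa=labels, codes=codes, partition=partition,
        outgroup=spec.outgroup_label,
    )
    return SyntheticDataset(
        matrix=matrix, true_edges=truth["edges"], spec=spec,
        seed=spec.rng_seed, change_edges=change_edges,
        eligible_edges=list(eligible),
        crown_zone=list(truth["crown_zone"]),
        deep_zone=list(truth["deep_zone"]),
    )


def generate_dataset(spec: SyntheticSpec, rng=None) -> SyntheticDataset:
    """Convenience: tree + matrix in one call."""
    gen = _as_rng(spec.rng_seed if rng is None else rng)
    truth = generate_tree(spec, gen)
    return evolve_matrix(truth, spec, gen)


def make_benchmark_suite(
    n_matrices: int,
    mode: str = "exchangeable",
    rng=None,
    spec: SyntheticSpec | None = None,
    thresholds: Thresholds | None = None,
    max_retries: int = 50,
) -> list[SyntheticDataset]:
    """Generate matrices that all pass the inclusion thresholds.

    With an explicit ``spec`` every matrix uses those sizes; otherwise
    sizes are sampled across the compiled-study ranges (10-40 ingroup
    taxa, hard fractions 0.2-0.8, 40-80 characters).  Matrices whose
    curated form fails a threshold are redrawn with a fresh sub-seed.
    """
    if n_matrices < 1:
        raise StemwardError("n_matrices must be >= 1")
    gen = _as_rng(rng)
    th = thresholds or Thresholds()
    out: list[SyntheticDataset] = []
    for m in range(n_matrices):
        for attempt in range(max_retries):
            sub_seed = int(gen.integers(2**31 - 1))
            sub = np.random.default_rng(sub_seed)
            if spec is None:
                n_taxa = int(sub.integers(10, 41))
                n_char = int(sub.integers(40, 81))
                hard_frac = float(sub.uniform(0.2, 0.8))
                n_hard = int(round(hard_frac * n_char))
                n_hard = min(max(n_hard, int(np.ceil(0.2 * n_char))),
                             int(np.floor(0.8 * n_char)))
                cand = SyntheticSpec(
                    n_taxa=n_taxa, n_hard=n_hard, n_soft=n_char - n_hard,
                    signal_mode=mode, rng_seed=sub_seed,
                )
            else:
                cand = replace(spec, signal_mode=mode, rng_seed=sub_seed)
            ds = generate_dataset(cand, sub)
            curated, _, decision = curate(ds.matrix, th)
            if decision.include:
                out.append(ds)
                break
        else:
            raise StemwardError(
                f"could not generate an includable matrix after {max_retries} tries"
            )
    return out
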