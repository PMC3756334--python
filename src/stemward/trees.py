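"""Tree representations.

The search engine works on *unrooted binary* trees stored as plain edge
arrays: for ``L`` leaves, nodes ``0..L-1`` are leaves (indexing the
matrix's taxa) and ``L..2L-3`` are internal, giving ``2L-3`` edges.
Rooted results are exposed as :class:`PhyloTree`, rooted at the node
where the outgroup attaches, which is how all "distance to the root"
and clade bookkeeping is defined downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .matrix import StemwardError

__all__ = [
    "PhyloTree",
    "TreeSet",
    "adjacency",
    "leaf_bitmasks",
    "edge_bipartitions",
    "canonical_key",
    "root_clades",
    "newick_from_edges",
]


def adjacency(edges: np.ndarray, n_nodes: int) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n_nodes)]
    for a, b in edges:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    return adj


def leaf_bitmasks(edges: np.ndarray, n_leaves: int) -> dict[tuple[int, int], int]:
    """Directed leaf-set bitmasks: ``(u, v) -> leaves on v's side of edge u-v``."""
    n_nodes = 2 * n_leaves - 2 if len(edges) == 2 * n_leaves - 3 else int(edges.max()) + 1
    adj = adjacency(edges, n_nodes)
    masks: dict[tuple[int, int], int] = {}

    def down(u: int, v: int) -> int:
        if (u, v) in masks:
            return masks[(u, v)]
        if v < n_leaves:
            m = 1 << v
        else:
            m = 0
            for w in adj[v]:
                if w != u:
                    m |= down(v, w)
        masks[(u, v)] = m
        return m

    # iterative wrapper to avoid recursion limits on large pectinate trees
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n_nodes + 100))
    try:
        for a, b in edges:
            down(int(a), int(b))
            down(int(b), int(a))
    finally:
        sys.setrecursionlimit(old)
    return masks


def edge_bipartitions(edges: np.ndarray, n_leaves: int, ref: int = 0) -> list[int]:
    """Bitmask of the side NOT containing leaf ``ref``, for every edge."""
    masks = leaf_bitmasks(edges, n_leaves)
    out = []
    for a, b in edges:
        m = masks[(int(a), int(b))]
        if m >> ref & 1:
            m = masks[(int(b), int(a))]
        out.append(m)
    return out


def canonical_key(edges: np.ndarray, n_leaves: int) -> frozenset[int]:
    """Topology-identifying key: the set of non-trivial bipartitions.

    Two unrooted trees over the same leaves are identical iff their keys
    are equal.  Sides are canonicalised to exclude leaf 0.
    """
    sides = edge_bipartitions(edges, n_leaves, ref=0)
    nontrivial = [m for m in sides if bin(m).count("1") >= 2]
    return frozenset(nontrivial)


def root_clades(edges: np.ndarray, n_leaves: int, outgroup: int) -> list[int]:
    """Clades of the tree rooted at the outgroup's attachment node.

    Each internal edge contributes its outgroup-free side; sides of size
    1 and ``n_leaves - 1`` are trivial (terminal edges / the rooting edge)
    and excluded.
    """
    sides = edge_bipartitions(edges, n_leaves, ref=outgroup)
    return [m for m in sides if 2 <= bin(m).count("1") <= n_leaves - 2]


def newick_from_edges(
    edges: np.ndarray,
    labels: Sequence[str],
    outgroup: int | None = None,
    edge_lengths: dict[tuple[int, int], float] | None = None,
) -> str:
    """Newick string, rooted at the outgroup attachment node (or node L)."""
    n_leaves = len(labels)
    n_nodes = 2 * n_leaves - 2
    adj = adjacency(edges, n_nodes)
    if outgroup is None:
        start = n_leaves
    else:
        start = adj[outgroup][0]

    def fmt_len(u: int, v: int) -> str:
        if edge_lengths is None:
            return ""
        val = edge_lengths.get((u, v), edge_lengths.get((v, u), 0.0))
        return f":{val:g}"

    def render(u: int, v: int) -> str:
        if v < n_leaves:
            return labels[v] + fmt_len(u, v)
        parts = [render(v, w) for w in adj[v] if w != u]
        return "(" + ",".join(parts) + ")" + fmt_len(u, v)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n_nodes + 100))
    try:
        parts = [render(start, w) for w in adj[start]]
    finally:
        sys.setrecursionlimit(old)
    return "(" + ",".join(parts) + ");"


def _mask_labels(mask: int, labels: Sequence[str]) -> frozenset[str]:
    return frozenset(labels[i] for i in range(len(labels)) if mask >> i & 1)


@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree over named leaves, summarised by its clade set.

    The clade set (outgroup-free descendant leaf sets of the non-root
    internal nodes) determines the rooted topology completely for the
    uses here: strict consensus, node recovery and root distances.
    """

    labels: tuple[str, ...]
    clades: frozenset[int]  # bitmasks over ``labels``; excludes root and singletons
    outgroup: str | None = None

    @classmethod
    def from_unrooted(
        cls, edges: np.ndarray, labels: Sequence[str], outgroup: str
    ) -> "PhyloTree":
        labels = tuple(labels)
        og = labels.index(outgroup)
        clades = frozenset(root_clades(np.asarray(edges), len(labels), og))
        return cls(labels=labels, clades=clades, outgroup=outgroup)

    @classmethod
    def from_clades(
        cls,
        labels: Sequence[str],
        clades: Iterable[int],
        outgroup: str | None = None,
    ) -> "PhyloTree":
        labels = tuple(labels)
        n = len(labels)
        cl = []
        for m in clades:
            size = bin(int(m)).count("1")
            if not 2 <= size <= n - 2:
                raise StemwardError("clades must be non-trivial (neither singleton nor near-full)")
            cl.append(int(m))
        # pairwise nested-or-disjoint check
        for i, a in enumerate(cl):
            for b in cl[i + 1 :]:
                inter = a & b
                if inter and inter != a and inter != b:
                    raise StemwardError("incompatible clades cannot form a tree")
        return cls(labels=labels, clades=frozenset(cl), outgroup=outgroup)

    # ------------------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def clade_set(self) -> frozenset[frozenset[str]]:
        """Non-trivial rooted clades as label sets (the tree's "nodes")."""
        return frozenset(_mask_labels(m, self.labels) for m in self.clades)

    def leaf_root_distance(self, taxon: str) -> int:
        """Internal nodes strictly between the terminal and the root."""
        i = self.labels.index(taxon)
        return sum(1 for m in self.clades if m >> i & 1)

    def is_resolved(self) -> bool:
        return len(self.clades) == self.n_leaves - 3

    def newick(self) -> str:
        """Newick string built from the clade hierarchy."""
        n = self.n_leaves
        og = self.labels.index(self.outgroup) if self.outgroup else None
        members = sorted(self.clades, key=lambda m: bin(m).count("1"))

        def render(mask: int, inner: list[int]) -> str:
            # children of this clade: maximal sub-clades + leftover leaves
            taken = 0
            parts = []
            for m in sorted(inner, key=lambda m: -bin(m).count("1")):
                if m & taken == 0 and (m & mask) == m and m != mask:
                    sub = [x for x in inner if (x & m) == x and x != m]
                    parts.append(render(m, sub))
                    taken |= m
            for i in range(n):
                if mask >> i & 1 and not taken >> i & 1:
                    parts.append(self.labels[i])
            return "(" + ",".join(sorted(parts)) + ")"

        full = (1 << n) - 1
        top = [m for m in members]
        body = render(full, top)
        return body + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.labels == other.labels and self.clades == other.clades

    def __hash__(self) -> int:
        return hash((self.labels, self.clades))


@dataclass
class TreeSet:
    """The most-parsimonious trees of one search, with their common score."""

    labels: tuple[str, ...]
    trees: list[np.ndarray] = field(default_factory=list)  # unrooted edge arrays
    score: int = 0
    outgroup: str | None = None
    seed: int | None = None
    n_addition_replicates: int = 0
    hit_tree_limit: bool = False

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def rooted(self) -> list[PhyloTree]:
        if self.outgroup is None:
            raise StemwardError("TreeSet has no outgroup to root on")
        return [PhyloTree.from_unrooted(e, self.labels, self.outgroup) for e in self.trees]

    def write_newick(self, path) -> None:
        og = self.labels.index(self.outgroup) if self.outgroup else None
        with open(path, "w") as fh:
            for e in self.trees:
                fh.write(newick_from_edges(e, self.labels, og) + "\n")
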