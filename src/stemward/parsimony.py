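"""Maximum-parsimony inference.

Provides tree length (Fitch for unordered, Farris/Wagner for ordered
characters), a random-addition + TBR heuristic search that collects all
equally most-parsimonious trees, an exhaustive-enumeration search for
small taxon counts (the testing oracle), strict consensus, and
root-distance metrics used by the taxon-shift test.

MPTs are kept fully resolved with no branch collapsing: trees that
differ only across zero-length branches are distinct members of the
tree set, which is what unambiguous node counting downstream requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._kernels import BIG, tbr_sweep, tree_length, tree_length_batch
from .matrix import CharacterMatrix, StemwardError, FULL_MASK, N_SYMBOLS
from .trees import PhyloTree, TreeSet, adjacency, canonical_key, root_clades

__all__ = [
    "SearchSettings",
    "fitch_length",
    "heuristic_search",
    "exhaustive_search",
    "strict_consensus",
    "mean_root_distance",
    "acctran_edge_lengths",
]


@dataclass
class SearchSettings:
    """Heuristic search effort and bookkeeping limits.

    Defaults mirror a conventional published search protocol (100 random
    addition sequences, TBR, hold 1000 per replicate, 10000 trees max);
    the ``desk()`` profile trades MPT-set completeness for speed at
    simulation scale.
    """

    n_addition_replicates: int = 100
    hold_per_replicate: int = 1000
    max_trees: int = 10000
    branch_collapsing: str = "none"  # {"none", "min_length_zero"}
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_addition_replicates, self.hold_per_replicate, self.max_trees) < 1:
            raise StemwardError("search limits must be positive")

    @classmethod
    def desk(cls, seed: int | None = None) -> "SearchSettings":
        return cls(n_addition_replicates=3, hold_per_replicate=64,
                   max_trees=64, rng_seed=seed)


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

def _matrix_arrays(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    return matrix.fitch_codes(), matrix.ordered.astype(np.bool_)


def fitch_length(tree, matrix: CharacterMatrix) -> int:
    """Minimum number of state changes of ``tree`` on ``matrix``.

    ``tree`` may be an unrooted edge array over the matrix's taxon
    indices (fast kernel path, binary trees only) or a
    :class:`PhyloTree`, for which a Sankoff dynamic program handles
    arbitrary multifurcations.  The result is invariant to rooting.
    """
    if isinstance(tree, np.ndarray):
        states, ordered = _matrix_arrays(matrix)
        return int(tree_length(np.asarray(tree, dtype=np.int64), matrix.n_taxa,
                               states, ordered))
    if isinstance(tree, PhyloTree):
        return _sankoff_length(tree, matrix)
    raise StemwardError(f"cannot score object of type {type(tree).__name__}")


def _sankoff_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    for label in tree.labels:
        if label not in matrix.taxa:
            raise StemwardError(f"leaf {label!r} absent from matrix")
    n = tree.n_leaves
    full = (1 << n) - 1
    # children structure: nodes are clade masks; leaves are singleton masks
    clades = sorted(tree.clades, key=lambda m: bin(m).count("1"))
    nodes = clades + [full]
    parent_of: dict[int, int] = {}
    for m in nodes:
        cands = [c for c in nodes if c != m and (c & m) == m]
        parent_of[m] = min(cands, key=lambda c: bin(c).count("1")) if cands else full
    for i in range(n):
        leaf = 1 << i
        cands = [c for c in nodes if (c & leaf) == leaf]
        parent_of[leaf] = min(cands, key=lambda c: bin(c).count("1"))
    children: dict[int, list[int]] = {m: [] for m in nodes}
    for child, par in parent_of.items():
        if child != full:
            children[par].append(child)

    C = matrix.n_char
    inf = np.float64(1e18)
    dist = np.abs(np.subtract.outer(np.arange(N_SYMBOLS), np.arange(N_SYMBOLS)))
    unit = (dist > 0).astype(np.float64)

    # iterative postorder over the clade hierarchy
    taxon_rows = {lab: matrix.taxon_index(lab) for lab in tree.labels}
    memo: dict[int, np.ndarray] = {}

    def leaf_cost(i: int) -> np.ndarray:
        row = matrix.codes[taxon_rows[tree.labels[i]]]
        cost = np.full((N_SYMBOLS, C), inf)
        for c in range(C):
            m = int(row[c])
            if m == 0:
                m = FULL_MASK
            for s in range(N_SYMBOLS):
                if m >> s & 1:
                    cost[s, c] = 0.0
        return cost

    stack = [(full, False)]
    while stack:
        node, done = stack.pop()
        if done:
            total = np.zeros((N_SYMBOLS, C))
            for ch in children[node]:
                child_cost = memo[ch]
                # contribution for parent state s: min_j child[j] + d(s, j)
                contrib = np.empty_like(child_cost)
                for c in range(C):
                    d = dist if matrix.ordered[c] else unit
                    contrib[:, c] = (child_cost[:, c][None, :] + d).min(axis=1)
                total += contrib
            memo[node] = total
            continue
        stack.append((node, True))
        for ch in children[node]:
            if bin(ch).count("1") == 1:
                memo[ch] = leaf_cost(ch.bit_length() - 1)
            else:
                stack.append((ch, False))
    root_cost = memo[full]
    return int(np.round(root_cost.min(axis=0).sum()))


# ----------------------------------------------------------------------
# tree manipulation
# ----------------------------------------------------------------------

def _canonical_edges(edge_set: set[tuple[int, int]]) -> np.ndarray:
    return np.array(sorted(edge_set), dtype=np.int64)


def apply_tbr_move(edges: np.ndarray, n_leaves: int, move) -> np.ndarray:
    """Rebuild the tree for one TBR move record from the sweep kernel."""
    _, p, q, fa, fb, ga, gb = (int(x) for x in move[:7])
    es = {(min(int(a), int(b)), max(int(a), int(b))) for a, b in edges}

    def rm(a: int, b: int) -> None:
        es.discard((min(a, b), max(a, b)))

    def ad(a: int, b: int) -> None:
        es.add((min(a, b), max(a, b)))

    rm(p, q)
    if fa != fb:  # p's component is not a single leaf: suppress p, reinsert at fa-fb
        nb = [x for e in es if p in e for x in e if x != p]
        rm(p, nb[0])
        rm(p, nb[1])
        ad(nb[0], nb[1])
        rm(fa, fb)
        ad(fa, p)
        ad(p, fb)
    if ga != gb:
        nb = [x for e in es if q in e for x in e if x != q]
        rm(q, nb[0])
        rm(q, nb[1])
        ad(nb[0], nb[1])
        rm(ga, gb)
        ad(ga, q)
        ad(q, gb)
    ad(p, q)
    return _canonical_edges(es)


def _stepwise_addition(order: list[int], n_leaves: int, states: np.ndarray,
                       ordered: np.ndarray) -> np.ndarray:
    """Build a starting tree by sequential insertion at the best edge."""
    a, b, c = order[:3]
    internal = n_leaves
    edges = [(a, internal), (b, internal), (c, internal)]
    for idx, leaf in enumerate(order[3:], start=1):
        new_node = n_leaves + idx
        best_len = None
        best_edges = None
        for i in range(len(edges)):
            u, v = edges[i]
            cand = edges[:i] + edges[i + 1:] + [(u, new_node), (new_node, v), (leaf, new_node)]
            arr = np.array(cand, dtype=np.int64)
            ln = tree_length(arr, n_leaves, states, ordered)
            if best_len is None or ln < best_len:
                best_len = ln
                best_edges = cand
        edges = best_edges
    return _canonical_edges({(min(u, v), max(u, v)) for u, v in edges})


def _search_from(edges: np.ndarray, n_leaves: int, states: np.ndarray,
                 ordered: np.ndarray, hold: int, max_moves: int):
    """TBR descent then plateau exploration from one starting tree.

    Returns ``(score, pool)`` with pool a dict canonical-key -> edges of
    equally parsimonious trees found (capped at ``hold``).
    """
    score = int(tree_length(edges, n_leaves, states, ordered))
    while True:
        # descend while an improving move exists
        while True:
            best, moves, nm = tbr_sweep(edges, n_leaves, states, ordered,
                                        score - 1, max_moves)
            if best >= score or best >= BIG:
                break
            for m in range(nm):
                if moves[m, 0] == best:
                    edges = apply_tbr_move(edges, n_leaves, moves[m])
                    break
            score = int(best)
        # plateau: breadth-first collection of equal-length trees
        pool = {canonical_key(edges, n_leaves): edges}
        queue = [edges]
        restart = None
        while queue and len(pool) < hold:
            t = queue.pop()
            best, moves, nm = tbr_sweep(t, n_leaves, states, ordered, score, max_moves)
            if best < score:
                for m in range(nm):
                    if moves[m, 0] == best:
                        restart = apply_tbr_move(t, n_leaves, moves[m])
                        break
                break
            for m in range(nm):
                if moves[m, 0] != score:
                    continue
                nt = apply_tbr_move(t, n_leaves, moves[m])
                key = canonical_key(nt, n_leaves)
                if key not in pool:
                    pool[key] = nt
                    queue.append(nt)
                    if len(pool) >= hold:
                        break
        if restart is None:
            return score, pool
        edges = restart
        score = int(tree_length(edges, n_leaves, states, ordered))


def heuristic_search(matrix: CharacterMatrix,
                     settings: SearchSettings | None = None) -> TreeSet:
    """Random-addition-sequence + TBR search collecting all best trees found.

    Reproducible for a given ``settings.rng_seed``; all trees are rooted
    on the matrix outgroup when consumed downstream.
    """
    settings = settings or SearchSettings()
    L = matrix.n_taxa
    if L < 4:
        raise StemwardError("heuristic search requires at least 4 taxa")
    states, ordered = _matrix_arrays(matrix)
    rng = np.random.default_rng(settings.rng_seed)
    E = 2 * L - 3
    max_moves = min(20000, 4 * E * E + 64)
    best_score: int | None = None
    pool: dict = {}
    hit_limit = False
    for _ in range(settings.n_addition_replicates):
        order = [int(x) for x in rng.permutation(L)]
        start = _stepwise_addition(order, L, states, ordered)
        score, rep_pool = _search_from(start, L, states, ordered,
                                       settings.hold_per_replicate, max_moves)
        if best_score is None or score < best_score:
            best_score = score
            pool = {}
        if score == best_score:
            for key, t in rep_pool.items():
                if key in pool:
                    continue
                if len(pool) >= settings.max_trees:
                    hit_limit = True
                    break
                pool[key] = t
    trees = [t for _, t in sorted(pool.items(), key=lambda kv: tuple(sorted(kv[0])))]
    return TreeSet(labels=matrix.taxa, trees=trees, score=int(best_score),
                   outgroup=matrix.outgroup, seed=settings.rng_seed,
                   n_addition_replicates=settings.n_addition_replicates,
                   hit_tree_limit=hit_limit)


def _enumerate_topologies(n_leaves: int) -> list[np.ndarray]:
    """All (2n-5)!! unrooted binary topologies over leaves 0..n-1."""
    base = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    trees = [base]
    for leaf in range(3, n_leaves):
        new_node = n_leaves + leaf - 2
        nxt = []
        for t in trees:
            for i in range(len(t)):
                u, v = t[i]
                nxt.append(t[:i] + t[i + 1:]
                           + [(u, new_node), (new_node, v), (leaf, new_node)])
        trees = nxt
    return [np.array(sorted((min(u, v), max(u, v)) for u, v in t), dtype=np.int64)
            for t in trees]


def exhaustive_search(matrix: CharacterMatrix) -> TreeSet:
    """Enumerate every unrooted binary topology and keep the shortest.

    Refused above 9 taxa (the (2n-5)!! explosion); intended as the
    optimality oracle for the heuristic.
    """
    L = matrix.n_taxa
    if L < 4:
        raise StemwardError("exhaustive search requires at least 4 taxa")
    if L > 9:
        raise StemwardError("exhaustive search is limited to 9 taxa")
    states, ordered = _matrix_arrays(matrix)
    topologies = _enumerate_topologies(L)
    arr = np.stack(topologies)
    scores = tree_length_batch(arr, L, states, ordered)
    best = int(scores.min())
    trees = [topologies[i] for i in np.nonzero(scores == best)[0]]
    ts = TreeSet(labels=matrix.taxa, trees=trees, score=best,
                 outgroup=matrix.outgroup, n_addition_replicates=0)
    ts.n_topologies_examined = len(topologies)  # type: ignore[attr-defined]
    return ts


# ----------------------------------------------------------------------
# consensus and root distances
# ----------------------------------------------------------------------

def strict_consensus(trees: TreeSet) -> PhyloTree:
    """Rooted strict consensus: exactly the clades present in every MPT."""
    if len(trees) == 0:
        raise StemwardError("cannot take the consensus of an empty tree set")
    if trees.outgroup is None:
        raise StemwardError("tree set must carry an outgroup for rooted consensus")
    og = trees.labels.index(trees.outgroup)
    common: set[int] | None = None
    for edges in trees:
        cl = set(root_clades(edges, trees.n_leaves, og))
        common = cl if common is None else common & cl
    return PhyloTree(labels=trees.labels, clades=frozenset(common),
                     outgroup=trees.outgroup)


def _node_distances(edges: np.ndarray, n_leaves: int, og: int) -> np.ndarray:
    """Per-leaf count of internal nodes strictly between leaf and root."""
    clades = root_clades(edges, n_leaves, og)
    out = np.zeros(n_leaves, dtype=np.int64)
    for m in clades:
        for i in range(n_leaves):
            if m >> i & 1:
                out[i] += 1
    return out


def acctran_edge_lengths(edges: np.ndarray, matrix: CharacterMatrix) -> dict:
    """Per-edge parsimony steps under ACCTRAN change resolution.

    The tree is rooted at the outgroup leaf; ambiguous state assignments
    are resolved by the standard accelerated-transformation rules, which
    push changes as close to the root as possible.  Unordered characters
    only.
    """
    if matrix.ordered.any():
        raise StemwardError("ACCTRAN edge lengths support unordered characters only")
    L = matrix.n_taxa
    og = matrix.outgroup_index
    states = matrix.fitch_codes()
    n_nodes = 2 * L - 2
    adj = adjacency(edges, n_nodes)
    # orient from the outgroup leaf
    parent = {og: og}
    order = [og]
    stack = [og]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in parent:
                parent[w] = v
                order.append(w)
                stack.append(w)
    kids: dict[int, list[int]] = {v: [] for v in order}
    for v in order:
        if v != og:
            kids[parent[v]].append(v)
    C = matrix.n_char
    S = N_SYMBOLS
    INF = np.float64(1e12)
    # Sankoff pass: cost[v, s, c] = min changes in subtree(v) with state s at v
    cost = np.zeros((n_nodes, S, C))
    for v in reversed(order):
        if v < L:
            allowed = (states[v][None, :] >> np.arange(S)[:, None]) & 1
            cost[v] = np.where(allowed == 1, 0.0, INF)
        else:
            total = np.zeros((S, C))
            for c in kids[v]:
                m = cost[c].min(axis=0)
                total += np.minimum(cost[c], 1.0 + m[None, :])
            cost[v] = total
    # preorder state selection; ACCTRAN resolves ties by taking the change
    # on the current (rootward) edge rather than deferring it tipward
    sel = np.zeros((n_nodes, C), dtype=np.int64)
    ar = np.arange(C)
    # root (outgroup leaf): any observed state; pick the one that lets the
    # tree below attain the optimum, smallest state on ties
    child = kids[og][0]
    og_allowed = (states[og][None, :] >> np.arange(S)[:, None]) & 1
    root_tot = np.where(og_allowed == 1,
                        np.minimum(cost[child], 1.0 + cost[child].min(axis=0)[None, :]),
                        INF)
    sel[og] = root_tot.argmin(axis=0)
    lengths: dict[tuple[int, int], int] = {}
    for v in order:
        if v == og:
            continue
        u = parent[v]
        sp = sel[u]
        cost_at_sp = cost[v][sp, ar]
        m = cost[v].min(axis=0)
        total = np.minimum(cost_at_sp, 1.0 + m)
        cand = (cost[v] + 1.0 == total[None, :]) & (np.arange(S)[:, None] != sp[None, :])
        has_change = cand.any(axis=0)
        sel[v] = np.where(has_change, cand.argmax(axis=0), sp)
        steps = int((sel[v] != sp).sum())
        lengths[(min(u, v), max(u, v))] = steps
    return lengths


def mean_root_distance(trees: TreeSet, taxon: str, metric: str = "nodes",
                       matrix: CharacterMatrix | None = None) -> float:
    """Mean distance from a terminal to the root over all MPTs.

    ``nodes``: internal nodes strictly between the terminal and the root
    (both endpoints excluded).  ``patristic``: summed ACCTRAN parsimony
    steps along the terminal-to-root path (requires ``matrix``).
    """
    if taxon not in trees.labels:
        raise StemwardError(f"taxon {taxon!r} absent from the tree set")
    if len(trees) == 0:
        raise StemwardError("empty tree set")
    ti = trees.labels.index(taxon)
    og = trees.labels.index(trees.outgroup)
    if metric == "nodes":
        vals = [float(_node_distances(e, trees.n_leaves, og)[ti]) for e in trees]
        return float(np.mean(vals))
    if metric == "patristic":
        if matrix is None:
            raise StemwardError("patristic distances require the character matrix")
        vals = []
        for edges in trees:
            lengths = acctran_edge_lengths(edges, matrix)
            adj = adjacency(edges, 2 * trees.n_leaves - 2)
            root = adj[og][0]
            # walk from the taxon up to the root
            parent = {root: root}
            stack = [root]
            while stack:
                v = stack.pop()
                for w in adj[v]:
                    if w not in parent:
                        parent[w] = v
                        stack.append(w)
            total = 0
            v = ti
            while v != root:
                u = parent[v]
                total += lengths[(min(u, v), max(u, v))]
                v = u
            vals.append(float(total))
        return float(np.mean(vals))
    raise StemwardError(f"unknown metric {metric!r}")
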