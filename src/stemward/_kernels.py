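"""Numba kernels for parsimony scoring and TBR neighborhoods.

Character states are bitmasks (bit *i* = state *i*); MISSING cells must
already be expanded to the full alphabet mask by the caller.  Unordered
characters use Fitch set operations; ordered (additive) characters use
Farris interval operations, for which every state set must be a
contiguous run of bits.

Trees are unrooted and binary: leaves ``0..L-1``, internal nodes
``L..2L-3``, stored as ``(2L-3, 2)`` integer edge arrays.

The TBR sweep scores every tree-bisection-reconnection neighbor
*exactly* in O(chars) per reconnection: cutting edge (p, q) splits the
tree into components A and B whose unrooted lengths and per-edge
directed state sets are computed once per bisection; the length of the
reattached tree is then ``len(A) + len(B) + join(set_A(f), set_B(g))``
for attachment edges f, g (parsimony length is invariant to rooting, so
each component may be treated as rooted at its attachment edge).
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = np.int64(1) << 60


@njit(cache=True, inline="always")
def _combine(a, b, is_ordered):
    """Combine two state sets; returns (result set, added steps)."""
    inter = a & b
    if inter != 0:
        return inter, 0
    if not is_ordered:
        return a | b, 1
    # ordered: disjoint contiguous intervals; cost is the gap size,
    # the result spans the gap between the two nearest endpoints
    lo = a if a < b else b
    hi = b if a < b else a
    lo_max = lo
    while (lo_max & (lo_max - 1)) != 0:
        lo_max &= lo_max - 1  # clear lowest bits, keep highest
    hi_min = hi & (-hi)
    steps = 0
    t = lo_max
    while t < hi_min:
        t <<= 1
        steps += 1
    res = ((hi_min << 1) - 1) & ~(lo_max - 1)
    return res, steps


@njit(cache=True)
def tree_length(edges, n_leaves, states, ordered):
    """Parsimony length of an unrooted (sub)tree.

    Handles partial trees during stepwise addition: any subset of leaf
    ids may appear, but every internal node must be binary (degree 3).
    """
    E = edges.shape[0]
    C = states.shape[1]
    maxn = 0
    for i in range(E):
        if edges[i, 0] > maxn:
            maxn = edges[i, 0]
        if edges[i, 1] > maxn:
            maxn = edges[i, 1]
    N = maxn + 1
    nbrs = np.full((N, 3), -1, np.int64)
    deg = np.zeros(N, np.int64)
    for i in range(E):
        a = edges[i, 0]
        b = edges[i, 1]
        nbrs[a, deg[a]] = b
        deg[a] += 1
        nbrs[b, deg[b]] = a
        deg[b] += 1
    # root the pass at the smallest leaf present
    r = -1
    for i in range(E):
        for k in range(2):
            v = edges[i, k]
            if v < n_leaves and (r == -1 or v < r):
                r = v
    parent = np.full(N, -2, np.int64)
    order = np.empty(E + 1, np.int64)
    stack = np.empty(E + 1, np.int64)
    parent[r] = r
    stack[0] = r
    sp = 1
    cnt = 0
    while sp > 0:
        sp -= 1
        v = stack[sp]
        order[cnt] = v
        cnt += 1
        for k in range(deg[v]):
            w = nbrs[v, k]
            if w == parent[v]:
                continue
            parent[w] = v
            stack[sp] = w
            sp += 1
    sets = np.zeros((N, C), np.int64)
    cost = np.int64(0)
    for idx in range(cnt - 1, -1, -1):
        v = order[idx]
        if v < n_leaves:
            for c in range(C):
                sets[v, c] = states[v, c]
        else:
            first = True
            for k in range(deg[v]):
                w = nbrs[v, k]
                if w == parent[v]:
                    continue
                if first:
                    for c in range(C):
                        sets[v, c] = sets[w, c]
                    first = False
                else:
                    for c in range(C):
                        s, d = _combine(sets[v, c], sets[w, c], ordered[c])
                        sets[v, c] = s
                        cost += d
    ch = nbrs[r, 0]
    for c in range(C):
        s, d = _combine(states[r, c], sets[ch, c], ordered[c])
        cost += d
    return cost


@njit(cache=True)
def tree_length_batch(edges3d, n_leaves, states, ordered):
    T = edges3d.shape[0]
    out = np.empty(T, np.int64)
    for t in range(T):
        out[t] = tree_length(edges3d[t], n_leaves, states, ordered)
    return out


@njit(cache=True)
def _component(root, excl, nbrs, deg, n_leaves, states, ordered,
               parent, order, stack, down, up, SE, EP):
    """Attachment-edge state sets of one component of a bisected tree.

    The component contains ``root``; the cut edge ran from ``root`` to
    ``excl``.  Fills ``SE`` (sets) and ``EP`` (edge endpoints) with one
    row per attachment edge of the component after suppressing the
    degree-2 node ``root``; row 0 is the merged edge.  Returns
    ``(n_edges, unrooted_length)``.
    """
    C = states.shape[1]
    if root < n_leaves:
        for c in range(C):
            SE[0, c] = states[root, c]
        EP[0, 0] = root
        EP[0, 1] = root
        return 1, np.int64(0)
    parent[root] = root
    stack[0] = root
    sp = 1
    cnt = 0
    while sp > 0:
        sp -= 1
        v = stack[sp]
        order[cnt] = v
        cnt += 1
        for k in range(deg[v]):
            w = nbrs[v, k]
            if v == root and w == excl:
                continue
            if w == parent[v]:
                continue
            parent[w] = v
            stack[sp] = w
            sp += 1
    length = np.int64(0)
    for idx in range(cnt - 1, -1, -1):
        v = order[idx]
        if v < n_leaves:
            for c in range(C):
                down[v, c] = states[v, c]
        else:
            first = True
            for k in range(deg[v]):
                w = nbrs[v, k]
                if w == parent[v] or (v == root and w == excl):
                    continue
                if first:
                    for c in range(C):
                        down[v, c] = down[w, c]
                    first = False
                else:
                    for c in range(C):
                        s, d = _combine(down[v, c], down[w, c], ordered[c])
                        down[v, c] = s
                        length += d
    c1 = np.int64(-1)
    c2 = np.int64(-1)
    for k in range(deg[root]):
        w = nbrs[root, k]
        if w == excl:
            continue
        if c1 == -1:
            c1 = w
        else:
            c2 = w
    ne = 0
    for c in range(C):
        SE[ne, c] = down[root, c]  # == combine(down[c1], down[c2]) sets
    EP[ne, 0] = c1
    EP[ne, 1] = c2
    ne += 1
    for c in range(C):
        up[c1, c] = down[c2, c]
        up[c2, c] = down[c1, c]
    for idx in range(cnt):  # preorder: parents before children
        v = order[idx]
        if v == root or v == c1 or v == c2:
            continue
        u = parent[v]
        sib = np.int64(-1)
        for k in range(deg[u]):
            w = nbrs[u, k]
            if w != v and w != parent[u]:
                sib = w
        for c in range(C):
            s, d = _combine(up[u, c], down[sib, c], ordered[c])
            up[v, c] = s
        for c in range(C):
            s, d = _combine(down[v, c], up[v, c], ordered[c])
            SE[ne, c] = s
        EP[ne, 0] = v
        EP[ne, 1] = u
        ne += 1
    return ne, length


@njit(cache=True)
def tbr_sweep(edges, n_leaves, states, ordered, threshold, max_moves):
    """Score all TBR neighbors; record moves with length <= threshold.

    Returns ``(best, moves, n_moves)`` where ``best`` is the minimum
    length among recorded moves (BIG if none) and each move row is
    ``(length, p, q, fa, fb, ga, gb)``: the tree is bisected at edge
    p-q and reattached at edge fa-fb of p's component and ga-gb of q's
    component (fa == fb marks a single-leaf component).
    """
    E = edges.shape[0]
    C = states.shape[1]
    N = 2 * n_leaves - 2
    nbrs = np.full((N, 3), -1, np.int64)
    deg = np.zeros(N, np.int64)
    for i in range(E):
        a = edges[i, 0]
        b = edges[i, 1]
        nbrs[a, deg[a]] = b
        deg[a] += 1
        nbrs[b, deg[b]] = a
        deg[b] += 1
    parent = np.full(N, -2, np.int64)
    order = np.empty(N, np.int64)
    stack = np.empty(N, np.int64)
    down = np.zeros((N, C), np.int64)
    up = np.zeros((N, C), np.int64)
    SA = np.zeros((E, C), np.int64)
    EPA = np.zeros((E, 2), np.int64)
    SB = np.zeros((E, C), np.int64)
    EPB = np.zeros((E, 2), np.int64)
    moves = np.zeros((max_moves, 7), np.int64)
    nmoves = 0
    best = BIG
    for ei in range(E):
        p = edges[ei, 0]
        q = edges[ei, 1]
        na, lenA = _component(p, q, nbrs, deg, n_leaves, states, ordered,
                              parent, order, stack, down, up, SA, EPA)
        nb, lenB = _component(q, p, nbrs, deg, n_leaves, states, ordered,
                              parent, order, stack, down, up, SB, EPB)
        base = lenA + lenB
        for i in range(na):
            for j in range(nb):
                if i == 0 and j == 0:
                    continue  # reconstructs the current tree
                s = base
                ok = True
                for c in range(C):
                    if SA[i, c] & SB[j, c] == 0:
                        _, d = _combine(SA[i, c], SB[j, c], ordered[c])
                        s += d
                        if s > threshold:
                            ok = False
                            break
                if not ok:
                    continue
                if s < best:
                    best = s
                if nmoves < max_moves:
                    moves[nmoves, 0] = s
                    moves[nmoves, 1] = p
                    moves[nmoves, 2] = q
                    moves[nmoves, 3] = EPA[i, 0]
                    moves[nmoves, 4] = EPA[i, 1]
                    moves[nmoves, 5] = EPB[j, 0]
                    moves[nmoves, 6] = EPB[j, 1]
                    nmoves += 1
    return best, moves, nmoves
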