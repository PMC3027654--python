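"""Compiled kernels for Fitch scoring and tree search.

Trees are held as an adjacency array ``adj`` of shape ``(2n-2, 3)`` over
node ids: leaves ``0..n-1`` (one neighbour, padded with -1), internal
nodes ``n..2n-3`` (three neighbours). Character data is a matrix of
4-bit state-set masks (one row per leaf, one column per site pattern)
with integer column weights; missing data is the full set, so it never
forces a change.

Scoring roots the unrooted tree at leaf ``root_leaf`` and runs the Fitch
bottom-up pass: child sets are intersected; an empty intersection is
replaced by the union and counts one weighted change.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tree_length", "stepwise_build", "spr_hillclimb"]


@njit(cache=True)
def _replace(adj, node, old, new):
    for j in range(3):
        if adj[node, j] == old:
            adj[node, j] = new
            return


@njit(cache=True)
def _postorder(adj, root_leaf, n_leaves, c1, c2, nid):
    """Fill postorder child arrays for the tree rooted at ``root_leaf``.

    Returns ``(root_internal, n_internal)``; works on partial trees
    (nodes with all-(-1) rows are simply absent).
    """
    n_nodes = adj.shape[0]
    root = adj[root_leaf, 0]
    parent = np.full(n_nodes, -2, np.int32)
    stack = np.empty(n_nodes, np.int32)
    order = np.empty(n_nodes, np.int32)
    sp = 0
    cnt = 0
    stack[sp] = root
    sp += 1
    parent[root] = root_leaf
    while sp > 0:
        sp -= 1
        u = stack[sp]
        order[cnt] = u
        cnt += 1
        for j in range(3):
            v = adj[u, j]
            if v >= 0 and v != parent[u]:
                parent[v] = u
                if v >= n_leaves:
                    stack[sp] = v
                    sp += 1
    k = 0
    for i in range(cnt - 1, -1, -1):
        u = order[i]
        a = np.int32(-1)
        b = np.int32(-1)
        for j in range(3):
            v = adj[u, j]
            if v >= 0 and v != parent[u]:
                if a < 0:
                    a = v
                else:
                    b = v
        c1[k] = a
        c2[k] = b
        nid[k] = u
        k += 1
    return root, k


@njit(cache=True)
def _fitch(c1, c2, nid, k, root, root_leaf, S, weights):
    total = np.int64(0)
    P = S.shape[1]
    for t in range(k):
        a = c1[t]
        b = c2[t]
        u = nid[t]
        for p in range(P):
            x = S[a, p] & S[b, p]
            if x == 0:
                x = S[a, p] | S[b, p]
                total += weights[p]
            S[u, p] = x
    for p in range(P):
        if S[root, p] & S[root_leaf, p] == 0:
            total += weights[p]
    return total


@njit(cache=True)
def tree_length(adj, root_leaf, n_leaves, S, weights, c1, c2, nid):
    """Weighted Fitch length of the (possibly partial) tree in ``adj``."""
    root, k = _postorder(adj, root_leaf, n_leaves, c1, c2, nid)
    return _fitch(c1, c2, nid, k, root, root_leaf, S, weights)


@njit(cache=True)
def stepwise_build(order, n_leaves, S, weights):
    """Random-addition stepwise tree building.

    Leaves are attached in the given order; each attachment point is the
    edge minimising the Fitch length of the partial tree (first-best on
    ties, so the addition order carries all the stochasticity).
    """
    n_nodes = 2 * n_leaves - 2
    adj = np.full((n_nodes, 3), -1, np.int32)
    c1 = np.empty(n_leaves - 2, np.int32)
    c2 = np.empty(n_leaves - 2, np.int32)
    nid = np.empty(n_leaves - 2, np.int32)
    a, b, c = order[0], order[1], order[2]
    w0 = n_leaves
    adj[a, 0] = w0
    adj[b, 0] = w0
    adj[c, 0] = w0
    adj[w0, 0] = a
    adj[w0, 1] = b
    adj[w0, 2] = c
    root_leaf = a
    next_internal = n_leaves + 1
    for i in range(3, n_leaves):
        leaf = order[i]
        w = next_internal
        best = np.int64(-1)
        bu = np.int32(-1)
        bv = np.int32(-1)
        for u in range(n_nodes):
            if adj[u, 0] < 0:
                continue
            for j in range(3):
                v = adj[u, j]
                if v <= u:
                    continue
                # tentatively insert `leaf` via new internal `w` on (u, v)
                _replace(adj, u, v, w)
                _replace(adj, v, u, w)
                adj[w, 0] = u
                adj[w, 1] = v
                adj[w, 2] = leaf
                adj[leaf, 0] = w
                sc = tree_length(adj, root_leaf, n_leaves, S, weights, c1, c2, nid)
                if best < 0 or sc < best:
                    best = sc
                    bu = u
                    bv = v
                # revert
                _replace(adj, u, w, v)
                _replace(adj, v, w, u)
                adj[w, 0] = -1
                adj[w, 1] = -1
                adj[w, 2] = -1
                adj[leaf, 0] = -1
        _replace(adj, bu, bv, w)
        _replace(adj, bv, bu, w)
        adj[w, 0] = bu
        adj[w, 1] = bv
        adj[w, 2] = leaf
        adj[leaf, 0] = w
        next_internal += 1
    return adj


@njit(cache=True)
def spr_hillclimb(adj, n_leaves, S, weights, nni_only, max_rounds):
    """Best-improvement SPR (or NNI) hill climbing, in place.

    Each round scans the full neighbourhood and applies the best strictly
    improving rearrangement; stops at a local optimum. Returns the final
    Fitch length.
    """
    n_nodes = adj.shape[0]
    c1 = np.empty(n_leaves - 2, np.int32)
    c2 = np.empty(n_leaves - 2, np.int32)
    nid = np.empty(n_leaves - 2, np.int32)
    cur = tree_length(adj, 0, n_leaves, S, weights, c1, c2, nid)
    mark = np.zeros(n_nodes, np.uint8)
    stack = np.empty(n_nodes, np.int32)
    adj2 = np.empty_like(adj)
    for _ in range(max_rounds):
        best = cur
        bs = np.int32(-1)
        bp = np.int32(-1)
        bu = np.int32(-1)
        bv = np.int32(-1)
        for p in range(n_leaves, n_nodes):
            if adj[p, 0] < 0:
                continue
            for jj in range(3):
                s = adj[p, jj]
                if s < 0:
                    continue
                # the two neighbours of p that stay behind
                x = np.int32(-1)
                y = np.int32(-1)
                for j2 in range(3):
                    v2 = adj[p, j2]
                    if v2 != s:
                        if x < 0:
                            x = v2
                        else:
                            y = v2
                # mark the pruned side (subtree containing s, plus p)
                for i in range(n_nodes):
                    mark[i] = 0
                mark[s] = 1
                mark[p] = 1
                sp2 = 0
                if s >= n_leaves:
                    stack[sp2] = s
                    sp2 += 1
                while sp2 > 0:
                    sp2 -= 1
                    u2 = stack[sp2]
                    for j3 in range(3):
                        v3 = adj[u2, j3]
                        if v3 >= 0 and mark[v3] == 0:
                            mark[v3] = 1
                            if v3 >= n_leaves:
                                stack[sp2] = v3
                                sp2 += 1
                # regraft onto every remaining edge except the old spot
                for u in range(n_nodes):
                    if mark[u] == 1 or adj[u, 0] < 0:
                        continue
                    for j4 in range(3):
                        v = adj[u, j4]
                        if v <= u or mark[v] == 1:
                            continue
                        if (u == x and v == y) or (u == y and v == x):
                            continue
                        if nni_only and u != x and u != y and v != x and v != y:
                            continue
                        adj2[:] = adj
                        _replace(adj2, x, p, y)
                        _replace(adj2, y, p, x)
                        _replace(adj2, u, v, p)
                        _replace(adj2, v, u, p)
                        adj2[p, 0] = s
                        adj2[p, 1] = u
                        adj2[p, 2] = v
                        sc = tree_length(adj2, 0, n_leaves, S, weights, c1, c2, nid)
                        if sc < best:
                            best = sc
                            bs = s
                            bp = p
                            bu = u
                            bv = v
        if bs < 0:
            break
        # apply the winning move
        x = np.int32(-1)
        y = np.int32(-1)
        for j2 in range(3):
            v2 = adj[bp, j2]
            if v2 != bs:
                if x < 0:
                    x = v2
                else:
                    y = v2
        _replace(adj, x, bp, y)
        _replace(adj, y, bp, x)
        _replace(adj, bu, bv, bp)
        _replace(adj, bv, bu, bp)
        adj[bp, 0] = bs
        adj[bp, 1] = bu
        adj[bp, 2] = bv
        cur = best
    return cur
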