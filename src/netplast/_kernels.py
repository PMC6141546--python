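"""Numba BFS kernels shared by the perturbation, topology and dissimilarity modules.

All kernels take CSR adjacency arrays plus an ``alive`` mask so percolation
experiments never rebuild subgraphs: removed nodes are simply skipped.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def directed_distance_stats(indptr, indices, alive):
    """BFS from every alive node over alive nodes (directed).

    Returns (sum_inverse_distance, sum_distance, n_reachable_pairs, max_distance)
    over ordered reachable pairs i != j.
    """
    n = alive.size
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    sum_inv = 0.0
    sum_d = 0.0
    n_pairs = 0
    max_d = 0
    for s in range(n):
        if not alive[s]:
            continue
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head = 0
        tail = 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for e in range(indptr[u], indptr[u + 1]):
                v = indices[e]
                if alive[v] and dist[v] < 0:
                    d = du + 1
                    dist[v] = d
                    queue[tail] = v
                    tail += 1
                    sum_inv += 1.0 / d
                    sum_d += d
                    n_pairs += 1
                    if d > max_d:
                        max_d = d
    return sum_inv, sum_d, n_pairs, max_d


@njit(cache=True, inline="always")
def _popcount64(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + \
        ((x >> np.uint64(2)) & np.uint64(0x3333333333333333))
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(cache=True)
def directed_distance_summary(indptr, indices, alive):
    """(sum 1/d, sum d, n reachable ordered pairs, max d) over alive nodes.

    Bit-parallel BFS: every alive node is a source, encoded as one bit, so a
    single sweep over the edge list advances 64 BFS frontiers per word.
    Agrees with directed_distance_stats (kept as the plain reference
    implementation) up to float accumulation order, at a fraction of the
    cost.
    """
    n = alive.size
    nw = (n + 63) // 64
    visited = np.zeros((n, nw), np.uint64)
    frontier = np.zeros((n, nw), np.uint64)
    nxt = np.zeros((n, nw), np.uint64)
    for i in range(n):
        if alive[i]:
            visited[i, i >> 6] |= np.uint64(1) << np.uint64(i & 63)
            frontier[i, i >> 6] = visited[i, i >> 6]
    sum_inv = 0.0
    sum_d = 0.0
    n_pairs = 0
    max_d = 0
    d = 0
    active = True
    while active:
        d += 1
        active = False
        for u in range(n):
            if not alive[u]:
                continue
            nonzero = False
            for w in range(nw):
                if frontier[u, w] != np.uint64(0):
                    nonzero = True
                    break
            if not nonzero:
                continue
            for e in range(indptr[u], indptr[u + 1]):
                v = indices[e]
                if alive[v]:
                    for w in range(nw):
                        nxt[v, w] |= frontier[u, w]
        inv_d = 1.0 / d
        for v in range(n):
            if not alive[v]:
                continue
            for w in range(nw):
                new = nxt[v, w] & ~visited[v, w]
                nxt[v, w] = np.uint64(0)
                if new != np.uint64(0):
                    visited[v, w] |= new
                    frontier[v, w] = new
                    cnt = _popcount64(new)
                    sum_inv += inv_d * cnt
                    sum_d += d * cnt
                    n_pairs += cnt
                    max_d = d
                    active = True
                else:
                    frontier[v, w] = np.uint64(0)
    return sum_inv, sum_d, n_pairs, max_d


@njit(cache=True)
def largest_component_size(indptr, indices, alive):
    """Size of the largest component over alive nodes.

    Pass a symmetrized CSR to get weakly connected components of a digraph.
    """
    n = alive.size
    comp = np.full(n, -1, np.int32)
    queue = np.empty(n, np.int32)
    best = 0
    for s in range(n):
        if alive[s] and comp[s] < 0:
            comp[s] = s
            queue[0] = s
            head = 0
            tail = 1
            size = 1
            while head < tail:
                u = queue[head]
                head += 1
                for e in range(indptr[u], indptr[u + 1]):
                    v = indices[e]
                    if alive[v] and comp[v] < 0:
                        comp[v] = s
                        queue[tail] = v
                        tail += 1
                        size += 1
            if size > best:
                best = size
    return best


@njit(cache=True)
def distance_histogram(indptr, indices):
    """Per-node shortest-path length histogram on the full (alive) graph.

    Returns (hist, diameter): hist[i, d] counts nodes at distance d >= 1 from
    node i; hist[i, 0] counts nodes unreachable from i.  Shape (n, n + 1).
    """
    n = indptr.size - 1
    hist = np.zeros((n, n + 1), np.int64)
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    diam = 0
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        queue[0] = s
        head = 0
        tail = 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for e in range(indptr[u], indptr[u + 1]):
                v = indices[e]
                if dist[v] < 0:
                    d = du + 1
                    dist[v] = d
                    queue[tail] = v
                    tail += 1
                    hist[s, d] += 1
                    if d > diam:
                        diam = d
        hist[s, 0] = n - tail  # unreachable from s
    return hist, diam
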