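"""Numba kernels for the graph-metric hot loops.

All kernels operate on small dense adjacency matrices (N of order 100),
where dense BFS (O(N^2) per source) beats sparse bookkeeping. They are
deliberately free of Python objects so they compile once and stay cached.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "bfs_distances",
    "brandes_betweenness",
    "double_edge_swap",
    "local_efficiency_nodes",
    "louvain_pass",
]


@njit(cache=True)
def bfs_distances(adj):
    """All-pairs shortest-path lengths on a binary graph; -1 = unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    for s in range(n):
        dist[s, s] = 0
        queue[0] = s
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[s, u]
            for v in range(n):
                if adj[u, v] != 0 and dist[s, v] < 0:
                    dist[s, v] = du + 1
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def brandes_betweenness(adj):
    """Betweenness via shortest-path dependency accumulation (undirected).

    Returns the ordered-pair count; divide by two for the unordered
    convention.
    """
    n = adj.shape[0]
    bc = np.zeros(n, dtype=np.float64)
    dist = np.empty(n, dtype=np.int32)
    sigma = np.empty(n, dtype=np.float64)
    delta = np.empty(n, dtype=np.float64)
    order = np.empty(n, dtype=np.int32)
    for s in range(n):
        dist[:] = -1
        sigma[:] = 0.0
        delta[:] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        order[0] = s
        head, tail = 0, 1
        while head < tail:
            u = order[head]
            head += 1
            du = dist[u]
            for v in range(n):
                if adj[u, v] != 0:
                    if dist[v] < 0:
                        dist[v] = du + 1
                        order[tail] = v
                        tail += 1
                    if dist[v] == du + 1:
                        sigma[v] += sigma[u]
        # accumulate dependencies in reverse BFS order
        for idx in range(tail - 1, 0, -1):
            w = order[idx]
            coeff = (1.0 + delta[w]) / sigma[w]
            dw = dist[w]
            for v in range(n):
                if adj[w, v] != 0 and dist[v] == dw - 1:
                    delta[v] += sigma[v] * coeff
            bc[w] += delta[w]
    return bc


@njit(cache=True)
def double_edge_swap(edges, adj, n_attempts, seed):
    """Degree-preserving rewiring by repeated double-edge swaps.

    Picks two edges (a,b), (c,d), rewires to (a,d), (c,b); rejects any
    proposal that would create a self-loop or duplicate edge. Mutates
    ``edges`` and ``adj`` in place; returns the number of accepted swaps.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        if a == d or c == b:
            continue
        if adj[a, d] != 0 or adj[c, b] != 0:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        accepted += 1
    return accepted


@njit(cache=True)
def null_ensemble_cp_lp(adj0, n_nulls, attempts_per_edge, seed):
    """Mean clustering coefficient and characteristic path length over a
    Maslov–Sneppen null ensemble, fused into one pass.

    Each null starts from the original graph and attempts
    ``attempts_per_edge * m`` double-edge swaps from a single seeded
    stream. Lp averages over connected ordered pairs. Returns
    (mean_cp, mean_lp).
    """
    n = adj0.shape[0]
    np.random.seed(seed)
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj0[i, j] != 0:
                m += 1
    edges0 = np.empty((m, 2), dtype=np.int64)
    e = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj0[i, j] != 0:
                edges0[e, 0] = i
                edges0[e, 1] = j
                e += 1
    cp_sum = 0.0
    lp_sum = 0.0
    indptr = np.empty(n + 1, dtype=np.int64)
    indices = np.empty(2 * m, dtype=np.int64)
    deg = np.empty(n, dtype=np.int64)
    dist = np.empty(n, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    for _ in range(n_nulls):
        adj = adj0.copy()
        edges = edges0.copy()
        n_attempts = attempts_per_edge * m
        for _ in range(n_attempts):
            e1 = np.random.randint(0, m)
            e2 = np.random.randint(0, m)
            if e1 == e2:
                continue
            a, b = edges[e1, 0], edges[e1, 1]
            c, d = edges[e2, 0], edges[e2, 1]
            if np.random.randint(0, 2) == 1:
                c, d = d, c
            if a == d or c == b:
                continue
            if adj[a, d] != 0 or adj[c, b] != 0:
                continue
            adj[a, b] = 0
            adj[b, a] = 0
            adj[c, d] = 0
            adj[d, c] = 0
            adj[a, d] = 1
            adj[d, a] = 1
            adj[c, b] = 1
            adj[b, c] = 1
            edges[e1, 0] = a
            edges[e1, 1] = d
            edges[e2, 0] = c
            edges[e2, 1] = b
        # CSR neighbor lists
        for i in range(n):
            deg[i] = 0
        for i in range(n):
            for j in range(n):
                if adj[i, j] != 0:
                    deg[i] += 1
        indptr[0] = 0
        for i in range(n):
            indptr[i + 1] = indptr[i] + deg[i]
        pos = indptr[:-1].copy()
        for i in range(n):
            for j in range(n):
                if adj[i, j] != 0:
                    indices[pos[i]] = j
                    pos[i] += 1
        # clustering
        cp = 0.0
        for i in range(n):
            k = deg[i]
            if k < 2:
                continue
            tri = 0
            for p in range(indptr[i], indptr[i + 1]):
                u = indices[p]
                for q in range(p + 1, indptr[i + 1]):
                    if adj[u, indices[q]] != 0:
                        tri += 1
            cp += 2.0 * tri / (k * (k - 1.0))
        cp_sum += cp / n
        # BFS path lengths
        total = 0.0
        count = 0
        for s in range(n):
            for v in range(n):
                dist[v] = -1
            dist[s] = 0
            queue[0] = s
            head, tail = 0, 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u]
                for p in range(indptr[u], indptr[u + 1]):
                    v = indices[p]
                    if dist[v] < 0:
                        dist[v] = du + 1
                        queue[tail] = v
                        tail += 1
            for v in range(n):
                if v != s and dist[v] > 0:
                    total += dist[v]
                    count += 1
        lp_sum += total / count if count > 0 else np.inf
    return cp_sum / n_nulls, lp_sum / n_nulls


@njit(cache=True)
def local_efficiency_nodes(adj):
    """Per-node efficiency of the subgraph induced by each node's neighbors.

    Nodes with fewer than two neighbors contribute zero.
    """
    n = adj.shape[0]
    out = np.zeros(n, dtype=np.float64)
    nb = np.empty(n, dtype=np.int32)
    sub = np.empty((n, n), dtype=np.int8)
    dist = np.empty(n, dtype=np.int32)
    queue = np.empty(n, dtype=np.int32)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j] != 0:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        for p in range(k):
            for q in range(k):
                sub[p, q] = adj[nb[p], nb[q]]
        total = 0.0
        for s in range(k):
            for v in range(k):
                dist[v] = -1
            dist[s] = 0
            queue[0] = s
            head, tail = 0, 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u]
                for v in range(k):
                    if sub[u, v] != 0 and dist[v] < 0:
                        dist[v] = du + 1
                        queue[tail] = v
                        tail += 1
            for v in range(k):
                if v != s and dist[v] > 0:
                    total += 1.0 / dist[v]
        out[i] = total / (k * (k - 1))
    return out


@njit(cache=True)
def louvain_pass(w, comm, sigma_tot, strength, order, m2):
    """One sweep of Louvain local moving over ``order``; returns #moves.

    ``w`` is the (possibly aggregated) dense weight matrix, ``comm`` the
    community of each node, ``sigma_tot`` the total strength per
    community, ``strength`` the node strengths, ``m2`` twice the total
    edge weight. Gains are the standard modularity increments with
    constant factors dropped; ties keep the current community.
    """
    n = w.shape[0]
    moves = 0
    comm_w = np.zeros(n, dtype=np.float64)
    touched = np.empty(n, dtype=np.int32)
    for idx in range(n):
        i = order[idx]
        ci = comm[i]
        # weights from i to each neighboring community (self excluded)
        n_touched = 0
        for j in range(n):
            if j != i and w[i, j] != 0.0:
                cj = comm[j]
                if comm_w[cj] == 0.0:
                    touched[n_touched] = cj
                    n_touched += 1
                comm_w[cj] += w[i, j]
        sigma_tot[ci] -= strength[i]
        best_c = ci
        best_gain = comm_w[ci] - strength[i] * sigma_tot[ci] / m2
        for t in range(n_touched):
            c = touched[t]
            if c == ci:
                continue
            gain = comm_w[c] - strength[i] * sigma_tot[c] / m2
            if gain > best_gain + 1e-12:
                best_gain = gain
                best_c = c
        comm[i] = best_c
        sigma_tot[best_c] += strength[i]
        if best_c != ci:
            moves += 1
        for t in range(n_touched):
            comm_w[touched[t]] = 0.0
        if comm_w[ci] != 0.0:
            comm_w[ci] = 0.0
    return moves
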