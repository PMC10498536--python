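"""Exhaustive brute-force graph oracles, independent of the implementation.

Everything here works by direct enumeration on small graphs: triangle
counting for clustering, queue-based BFS for distances and shortest-path
counts, and the combinatorial path-through-node identity for betweenness.
"""

from collections import deque

import numpy as np


def clustering_oracle(adj):
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        d = len(nbrs)
        if d < 2:
            continue
        links = sum(adj[u][v] for a, u in enumerate(nbrs) for v in nbrs[a + 1 :])
        out[i] = 2.0 * links / (d * (d - 1))
    return out, float(out.mean())


def bfs_distances_and_counts(adj, source):
    """Distances and number of distinct shortest paths from one source."""
    n = len(adj)
    dist = [np.inf] * n
    npaths = [0] * n
    dist[source] = 0
    npaths[source] = 1
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u][v]:
                if dist[v] == np.inf:
                    dist[v] = dist[u] + 1
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    npaths[v] += npaths[u]
    return np.array(dist), np.array(npaths, dtype=float)


def path_length_oracle(adj):
    n = len(adj)
    dists = []
    n_disc = 0
    for i in range(n):
        d, _ = bfs_distances_and_counts(adj, i)
        for j in range(i + 1, n):
            if np.isfinite(d[j]):
                dists.append(d[j])
            else:
                n_disc += 1
    if not dists:
        raise ValueError("no finite pairs")
    return float(np.mean(dists)), n_disc


def betweenness_oracle(adj):
    """BC by the pair-fraction identity: a shortest j-k path passes through i
    iff d(j,i) + d(i,k) = d(j,k), contributing n(j,i)*n(i,k)/n(j,k)."""
    n = len(adj)
    dist = np.empty((n, n))
    cnt = np.empty((n, n))
    for s in range(n):
        dist[s], cnt[s] = bfs_distances_and_counts(adj, s)
    bc = np.zeros(n)
    for j in range(n):
        for k in range(j + 1, n):
            if not np.isfinite(dist[j][k]):
                continue
            for i in range(n):
                if i in (j, k):
                    continue
                if dist[j][i] + dist[i][k] == dist[j][k]:
                    bc[i] += cnt[j][i] * cnt[i][k] / cnt[j][k]
    return bc


def random_connected_adjacency(n, p, rng):
    """Erdős–Rényi draw; not necessarily connected (callers handle that)."""
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
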