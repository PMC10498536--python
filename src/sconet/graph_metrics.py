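"""Graph-theoretic topology of binarized networks: clustering coefficient,
characteristic path length, small-worldness against degree-preserving random
networks, and betweenness-centrality hub analysis.

Conventions: graphs are undirected and simple (symmetric 0/1 adjacency, zero
diagonal).  Path lengths average over node pairs with a finite distance, and
the count of disconnected pairs is surfaced rather than hidden.  Betweenness
counts each unordered pair once with endpoints excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "clustering_coefficient",
    "characteristic_path_length",
    "betweenness_centrality",
    "random_networks",
    "small_world",
    "normalize_bc",
    "identify_hubs",
    "nodal_metrics",
]


@dataclass
class GlobalMetrics:
    """Global small-world parameters of one binarized network.

    gamma = Cp / mean Cp of the null networks, lambda_ = Lp / mean null Lp,
    sigma = gamma / lambda_ (> 1 indicates small-world organization).
    """

    sparsity: float | None
    clustering: float
    path_length: float
    gamma: float
    lambda_: float
    sigma: float
    n_random: int
    random_clustering_mean: float
    random_path_length_mean: float
    disconnected_pairs: int


@dataclass
class NodalMetrics:
    """Per-node betweenness centrality, its network-mean normalization, and hubs."""

    sparsity: float | None
    bc: np.ndarray
    bc_normalized: np.ndarray
    hubs: np.ndarray  # node indices


def _validate_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal (no self-loops)")
    if not np.all((a == 0) | (a == 1)):
        raise ValueError("adjacency must be binary")
    return a.astype(np.int8)


def clustering_coefficient(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their unweighted network mean.

    Node value = 2 * (triangles through the node) / (deg * (deg - 1)); nodes
    with fewer than two neighbors score zero.
    """
    a = _validate_adjacency(adj).astype(float)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c, float(c.mean())


def characteristic_path_length(adj: np.ndarray) -> tuple[float, int]:
    """Mean shortest-path length over connected node pairs.

    Returns (Lp, number of unordered pairs at infinite distance).  Distances
    come from breadth-first search on the unweighted graph.  An edgeless
    graph has no finite pair and raises.
    """
    a = _validate_adjacency(adj)
    d = shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)
    iu = np.triu_indices(a.shape[0], k=1)
    dists = d[iu]
    finite = np.isfinite(dists)
    n_disc = int((~finite).sum())
    if not finite.any():
        raise ValueError("edgeless graph: no finite node pair distances")
    return float(dists[finite].mean()), n_disc


def betweenness_centrality(adj: np.ndarray) -> np.ndarray:
    """Betweenness centrality per node via Brandes accumulation.

    BC_i is the sum over unordered pairs {j, k} (both != i) of the fraction
    of shortest j-k paths that pass through i.
    """
    a = _validate_adjacency(adj)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(a.shape[0])], dtype=float)


def _rewire(adj: np.ndarray, rng: np.random.Generator, swap_factor: int = 10) -> np.ndarray:
    """Maslov-Sneppen double-edge swaps preserving the exact degree sequence."""
    a = adj.copy()
    iu, ju = np.triu_indices(a.shape[0], k=1)
    sel = a[iu, ju] > 0
    edges = np.column_stack((iu[sel], ju[sel]))
    m = len(edges)
    n_attempts = swap_factor * m
    # batch the randomness: one draw of candidate pairs and orientations
    pick = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip[t]:
            x, y = y, x
        # proposed swap: (u,v),(x,y) -> (u,x),(v,y)
        if u == x or u == y or v == x or v == y:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = (u, x) if u < x else (x, u)
        edges[e2] = (v, y) if v < y else (y, v)
    return a


def random_networks(
    adj: np.ndarray, n: int = 100, seed: int | np.random.Generator | None = None, swap_factor: int = 10
) -> list[np.ndarray]:
    """Degree-preserving random networks matched to ``adj``.

    Each null is produced by attempted double-edge swaps (default 10x the
    edge count), which conserve size, edge count, and the exact degree
    sequence while never introducing self-loops or multi-edges.  For degree
    sequences admitting no swap (e.g. a complete graph) the nulls equal the
    input.
    """
    a = _validate_adjacency(adj)
    if n < 1:
        raise ValueError("need at least one null network")
    if int(a.sum()) // 2 < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [_rewire(a, rng, swap_factor) for _ in range(n)]


def small_world(
    adj: np.ndarray,
    n_random: int = 100,
    seed: int | np.random.Generator | None = None,
    sparsity: float | None = None,
    swap_factor: int = 10,
) -> GlobalMetrics:
    """Small-world parameters normalized by matched random networks.

    gamma = Cp / <Cp_random>, lambda = Lp / <Lp_random>, sigma = gamma/lambda.
    """
    a = _validate_adjacency(adj)
    _, cp = clustering_coefficient(a)
    lp, n_disc = characteristic_path_length(a)
    nulls = random_networks(a, n=n_random, seed=seed, swap_factor=swap_factor)
    cp_r = float(np.mean([clustering_coefficient(r)[1] for r in nulls]))
    lp_r = float(np.mean([characteristic_path_length(r)[0] for r in nulls]))
    if cp_r == 0:
        raise ValueError("null networks have zero mean clustering; gamma undefined")
    gamma = cp / cp_r
    lambda_ = lp / lp_r
    return GlobalMetrics(
        sparsity=sparsity,
        clustering=cp,
        path_length=lp,
        gamma=gamma,
        lambda_=lambda_,
        sigma=gamma / lambda_,
        n_random=n_random,
        random_clustering_mean=cp_r,
        random_path_length_mean=lp_r,
        disconnected_pairs=n_disc,
    )


def normalize_bc(bc: np.ndarray) -> np.ndarray:
    """Divide betweenness values by their network mean (output mean = 1)."""
    bc = np.asarray(bc, dtype=float)
    mean = bc.mean()
    if mean <= 0:
        raise ValueError(
            "network-average betweenness is zero (e.g. complete graph); hub analysis undefined"
        )
    return bc / mean


def identify_hubs(bc_normalized: np.ndarray) -> np.ndarray:
    """Hub nodes: normalized BC more than one sample SD above the mean."""
    v = np.asarray(bc_normalized, dtype=float)
    if len(v) < 2:
        raise ValueError("hub identification needs at least 2 nodes")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(v > v.mean() + sd)


def nodal_metrics(adj: np.ndarray, sparsity: float | None = None) -> NodalMetrics:
    """Betweenness centrality, its normalization, and hubs for one network."""
    bc = betweenness_centrality(adj)
    bc_n = normalize_bc(bc)
    return NodalMetrics(sparsity=sparsity, bc=bc, bc_normalized=bc_n, hubs=identify_hubs(bc_n))
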