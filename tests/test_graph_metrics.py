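"""Small-world and betweenness topology against exhaustive enumeration oracles."""

import networkx as nx
import numpy as np
import pytest

import sconet as sc
from .conftest import adjacency_from_edges
from .oracles import (
    betweenness_oracle,
    clustering_oracle,
    path_length_oracle,
    random_connected_adjacency,
)

K4 = adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
STAR5 = adjacency_from_edges(5, [(0, i) for i in range(1, 5)])
P4 = adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3)])
P5 = adjacency_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
TRIANGLE_PENDANT = adjacency_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
TWO_TRIANGLES = adjacency_from_edges(6, [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)])


class TestClustering:
    def test_complete_and_star(self):
        per, mean = sc.clustering_coefficient(K4)
        assert np.allclose(per, 1.0) and mean == 1.0
        per, mean = sc.clustering_coefficient(STAR5)
        assert np.allclose(per, 0.0) and mean == 0.0

    def test_triangle_with_pendant(self):
        per, mean = sc.clustering_coefficient(TRIANGLE_PENDANT)
        assert per == pytest.approx([1 / 3, 1.0, 1.0, 0.0])
        assert mean == pytest.approx(7 / 12)

    def test_validation(self):
        bad = np.array([[0, 1], [0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            sc.clustering_coefficient(bad)
        loop = np.array([[1, 1], [1, 0]])
        with pytest.raises(ValueError, match="diagonal"):
            sc.clustering_coefficient(loop)


class TestPathLength:
    def test_complete_graph(self):
        lp, n_disc = sc.characteristic_path_length(K4)
        assert lp == 1.0 and n_disc == 0

    def test_path_graph(self):
        lp, n_disc = sc.characteristic_path_length(P4)
        assert lp == pytest.approx(10 / 6)
        assert n_disc == 0

    def test_disconnected_components_counted(self):
        lp, n_disc = sc.characteristic_path_length(TWO_TRIANGLES)
        assert lp == 1.0 and n_disc == 9

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError, match="edgeless"):
            sc.characteristic_path_length(np.zeros((4, 4), dtype=int))


class TestBetweenness:
    def test_complete_graph_all_zero(self):
        assert np.allclose(sc.betweenness_centrality(K4), 0.0)

    def test_star_center(self):
        bc = sc.betweenness_centrality(STAR5)
        assert bc[0] == pytest.approx(6.0)
        assert np.allclose(bc[1:], 0.0)

    def test_path_p5(self):
        assert sc.betweenness_centrality(P5) == pytest.approx([0, 3, 4, 3, 0])


class TestBruteForceAgreement:
    """All three metrics agree exactly with enumeration on random small graphs."""

    def test_thirty_random_graphs(self):
        rng = np.random.default_rng(42)
        done = 0
        while done < 30:
            n = int(rng.integers(4, 13))
            adj = random_connected_adjacency(n, rng.uniform(0.2, 0.7), rng)
            if adj.sum() == 0:
                continue
            per, mean = sc.clustering_coefficient(adj)
            o_per, o_mean = clustering_oracle(adj)
            assert per == pytest.approx(o_per, abs=1e-12)
            assert mean == pytest.approx(o_mean, abs=1e-12)
            lp, nd = sc.characteristic_path_length(adj)
            o_lp, o_nd = path_length_oracle(adj)
            assert lp == pytest.approx(o_lp, abs=1e-12) and nd == o_nd
            bc = sc.betweenness_centrality(adj)
            o_bc = betweenness_oracle(adj)
            assert bc == pytest.approx(o_bc, abs=1e-9)
            done += 1


class TestRandomNetworks:
    def test_degree_sequence_and_edge_count_conserved(self):
        g = nx.watts_strogatz_graph(30, 6, 0.2, seed=1)
        adj = nx.to_numpy_array(g).astype(int)
        nulls = sc.random_networks(adj, n=10, seed=5)
        for r in nulls:
            assert np.array_equal(r.sum(axis=1), adj.sum(axis=1))  # exact per-node degrees
            assert r.sum() == adj.sum()
            assert np.all(np.diag(r) == 0)

    def test_reproducible_and_actually_rewired(self):
        g = nx.watts_strogatz_graph(40, 8, 0.1, seed=2)
        adj = nx.to_numpy_array(g).astype(int)
        a = sc.random_networks(adj, n=3, seed=9)
        b = sc.random_networks(adj, n=3, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        assert any(not np.array_equal(x, adj) for x in a)

    def test_complete_graph_unswappable(self):
        k5 = adjacency_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        for r in sc.random_networks(k5, n=3, seed=0):
            assert np.array_equal(r, k5)


class TestSmallWorld:
    def test_sigma_is_gamma_over_lambda(self):
        g = nx.watts_strogatz_graph(60, 8, 0.1, seed=3)
        gm = sc.small_world(nx.to_numpy_array(g).astype(int), n_random=20, seed=3)
        assert gm.sigma == pytest.approx(gm.gamma / gm.lambda_, abs=1e-12)
        alt = (gm.clustering * gm.random_path_length_mean) / (
            gm.random_clustering_mean * gm.path_length
        )
        assert gm.sigma == pytest.approx(alt, abs=1e-12)

    def test_watts_strogatz_ring_is_small_world(self):
        g = nx.watts_strogatz_graph(90, 10, 0.1, seed=4)
        gm = sc.small_world(nx.to_numpy_array(g).astype(int), n_random=100, seed=4)
        assert gm.sigma > 1.0

    def test_random_graph_near_unity(self):
        g = nx.gnm_random_graph(90, 1001, seed=6)
        gm = sc.small_world(nx.to_numpy_array(g).astype(int), n_random=50, seed=6)
        assert gm.gamma == pytest.approx(1.0, abs=0.3)
        assert gm.lambda_ == pytest.approx(1.0, abs=0.1)
        assert gm.sigma == pytest.approx(1.0, abs=0.35)

    def test_sigma_rises_then_falls_over_rewiring_sweep(self):
        sigmas = []
        for p in (0.01, 0.1, 1.0):
            g = nx.watts_strogatz_graph(90, 10, p, seed=7)
            sigmas.append(sc.small_world(nx.to_numpy_array(g).astype(int), n_random=30, seed=7).sigma)
        assert sigmas[1] > sigmas[2]
        assert sigmas[1] > 1.0
        assert sigmas[2] == pytest.approx(1.0, abs=0.35)


class TestBCNormalizationAndHubs:
    def test_uniform_and_star_normalization(self):
        assert sc.normalize_bc(np.array([2.0, 2.0, 2.0])) == pytest.approx([1, 1, 1])
        assert sc.normalize_bc(np.array([6.0, 0, 0, 0, 0])) == pytest.approx([5, 0, 0, 0, 0])

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(10)
        v = rng.exponential(size=50)
        assert sc.normalize_bc(v).mean() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_bc_rejected(self):
        with pytest.raises(ValueError, match="hub analysis"):
            sc.normalize_bc(np.zeros(4))

    def test_star_hub_is_center(self):
        nm = sc.nodal_metrics(STAR5)
        assert list(nm.hubs) == [0]

    def test_uniform_bc_has_no_hubs(self):
        assert len(sc.identify_hubs(np.ones(10))) == 0

    def test_single_outlier_flagged(self):
        v = np.array([1.0] * 6 + [4.0])
        v = v / v.mean()
        assert list(sc.identify_hubs(v)) == [6]
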