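"""Covariate residualization and covariance network construction."""

import numpy as np
import pandas as pd
import pytest

import sconet as sc
from sconet.covariance import CollinearCovariatesError


def small_table(n=20, p=6, seed=0, tiv_effect=0.0):
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame(
        {
            "age": rng.normal(22, 3, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(15, 1.4, n),
            "tiv": rng.normal(1550, 150, n),
        }
    )
    vols = rng.normal(100, 1, (n, p)) + tiv_effect * cov["tiv"].to_numpy()[:, None]
    return sc.MorphometryTable(
        subjects=[f"s{i}" for i in range(n)],
        regions=[f"r{j}" for j in range(p)],
        volumes=vols,
        covariates=cov.set_axis([f"s{i}" for i in range(n)]),
        group=np.array(["high"] * (n // 2) + ["low"] * (n - n // 2), dtype=object),
    )


class TestResidualize:
    def test_residuals_orthogonal_to_covariates_and_mean_zero(self):
        table = sc.residualize(small_table(tiv_effect=0.5))
        assert np.allclose(table.volumes.mean(axis=0), 0, atol=1e-9)
        for c in ("age", "sex", "education", "tiv"):
            x = table.covariates[c].to_numpy() - table.covariates[c].mean()
            corr = x @ table.volumes / len(x)
            assert np.max(np.abs(corr)) < 1e-8

    def test_exact_tiv_confound_removed(self):
        table = small_table(tiv_effect=0.5)
        res = sc.residualize(table, ["tiv"])
        tiv = res.covariates["tiv"].to_numpy()
        for j in range(res.n_regions):
            r = np.corrcoef(tiv, res.volumes[:, j])[0, 1]
            assert abs(r) < 1e-10

    def test_idempotent(self):
        once = sc.residualize(small_table(seed=3))
        twice = sc.residualize(once)
        assert np.allclose(once.volumes, twice.volumes, atol=1e-9)

    def test_sex_coding_affine_invariance(self):
        t1 = small_table(seed=4)
        t2 = small_table(seed=4)
        t2.covariates = t2.covariates.assign(sex=2 * t2.covariates["sex"] - 1)  # 0/1 -> -1/1
        r1 = sc.residualize(t1)
        r2 = sc.residualize(t2)
        assert np.allclose(r1.volumes, r2.volumes, atol=1e-8)

    def test_constant_covariate_is_collinear(self):
        table = small_table()
        table.covariates = table.covariates.assign(sex=1.0)
        with pytest.raises(CollinearCovariatesError, match="sex"):
            sc.residualize(table)

    def test_planted_confound_recovered_structure(self):
        """Region-region correlations after residualization match the
        confound-free construction within sampling error."""
        cfg = sc.MorphGeneratorConfig(n_subjects=400, n_regions=30, n_communities=3, seed=8)
        clean_cfg = sc.MorphGeneratorConfig(
            n_subjects=400, n_regions=30, n_communities=3, covariate_effects={}, seed=8
        )
        with_conf = sc.generate_morphometry(cfg, cfg, seed=8)
        without = sc.generate_morphometry(clean_cfg, clean_cfg, seed=8)
        r_res = np.corrcoef(sc.residualize(with_conf).volumes, rowvar=False)
        r_clean = np.corrcoef(without.volumes, rowvar=False)
        assert np.max(np.abs(r_res - r_clean)) < 0.05


class TestCovarianceMatrix:
    def test_hand_computed_toy_table(self):
        rng = np.random.default_rng(1)
        vols = rng.normal(size=(6, 4))
        table = small_table(n=6, p=4, seed=1)
        table.volumes = vols
        table.residualized = True
        net = sc.covariance_matrix(table)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert net.weights[i, j] == 0.0
                else:
                    x, y = vols[:, i], vols[:, j]
                    r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                    )
                    assert net.weights[i, j] == pytest.approx(r, abs=1e-12)

    def test_identical_and_negated_columns(self):
        table = small_table(n=8, p=3, seed=2)
        table.volumes[:, 1] = table.volumes[:, 0]
        table.volumes[:, 2] = -table.volumes[:, 0]
        net = sc.covariance_matrix(table)
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.weights[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_region_named(self):
        table = small_table(n=8, p=3)
        table.volumes[:, 1] = 7.0
        with pytest.raises(ValueError, match="r1"):
            sc.covariance_matrix(table)

    def test_group_too_small(self):
        table = small_table(n=6)
        with pytest.raises(ValueError, match="at least 4"):
            sc.covariance_matrix(table, "high")  # only 3 high subjects


class TestZeroNegatives:
    def test_definition_and_identity(self):
        w = np.array([[0.0, 0.5, -0.3], [0.5, 0.0, 0.0], [-0.3, 0.0, 0.0]])
        net = sc.zero_negatives(sc.CovarianceNetwork(labels=list("abc"), weights=w))
        assert np.array_equal(net.weights, np.array([[0, 0.5, 0], [0.5, 0, 0], [0, 0, 0]]))
        assert net.n_zeroed_negative == 1
        again = sc.zero_negatives(net)
        assert np.array_equal(again.weights, net.weights)
        assert again.n_zeroed_negative == 0

    def test_elementwise_property(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(-1, 1, (10, 10))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        out = sc.zero_negatives(sc.CovarianceNetwork(labels=[str(i) for i in range(10)], weights=w))
        assert out.weights.min() >= 0
        mask = w >= 0
        assert np.array_equal(out.weights[mask], w[mask])


class TestBinarize:
    @staticmethod
    def _net(w, labels=None):
        return sc.CovarianceNetwork(labels=labels or [str(i) for i in range(len(w))], weights=np.asarray(w, float))

    def test_90_node_edge_counts(self):
        rng = np.random.default_rng(6)
        w = np.abs(rng.normal(size=(90, 90)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = self._net(w)
        assert sc.binarize_at_sparsity(net, 0.25).n_edges == 1001
        assert sc.binarize_at_sparsity(net, 1.0).n_edges == 4005

    def test_four_node_brute_force(self):
        w = np.zeros((4, 4))
        pairs = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.3, (1, 2): 0.2, (1, 3): 0.1, (2, 3): 0.05}
        for (i, j), v in pairs.items():
            w[i, j] = w[j, i] = v
        b = sc.binarize_at_sparsity(self._net(w), 0.5)
        expected = {(0, 1), (0, 2), (0, 3)}  # top floor(0.5 * 6) = 3 by weight
        got = {(i, j) for i in range(4) for j in range(i + 1, 4) if b.adjacency[i, j]}
        assert got == expected

    def test_nestedness_across_sparsities(self):
        rng = np.random.default_rng(7)
        w = np.abs(rng.normal(size=(20, 20)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        net = self._net(w)
        prev = None
        for s in (0.1, 0.2, 0.3, 0.5):
            adj = sc.binarize_at_sparsity(net, s).adjacency
            if prev is not None:
                assert np.all(adj[prev == 1] == 1)  # edge sets nest
            prev = adj

    def test_invariant_under_monotone_weight_transform(self):
        rng = np.random.default_rng(8)
        w = rng.uniform(0.01, 1, (15, 15))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        a1 = sc.binarize_at_sparsity(self._net(w), 0.3).adjacency
        a2 = sc.binarize_at_sparsity(self._net(np.sqrt(w)), 0.3).adjacency
        assert np.array_equal(a1, a2)

    def test_insufficient_positive_weights(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 0.5
        with pytest.raises(ValueError, match="maximum achievable"):
            sc.binarize_at_sparsity(self._net(w), 0.5)

    def test_invalid_sparsity(self):
        with pytest.raises(ValueError):
            sc.binarize_at_sparsity(self._net(np.zeros((3, 3))), 0.0)


class TestSparsityGrid:
    def test_study_default_grid(self):
        grid = sc.sparsity_grid(0.25, 0.53, 0.01)
        assert len(grid) == 29
        assert grid[0] == 0.25 and grid[-1] == 0.53

    @pytest.mark.parametrize(
        "args, expected",
        [((0.4, 0.4, 0.01), [0.4]), ((0.1, 0.2, 0.05), [0.10, 0.15, 0.20])],
    )
    def test_small_grids(self, args, expected):
        assert sc.sparsity_grid(*args) == pytest.approx(expected)

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            sc.sparsity_grid(0.5, 0.3, 0.01)
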