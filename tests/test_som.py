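import json

import numpy as np
import pytest

from spatialsom import Lattice, SOMConfig, StochasticSOM, load_config
from spatialsom.som import (
    batch_step,
    best_matching_unit,
    init_weights,
    neighborhood_matrix,
    neighborhood_weight,
)

from conftest import make_matrix

LAT = Lattice()


class TestLattice:
    def test_eight_units_binary_coords(self):
        coords = LAT.unit_coords
        assert coords.shape == (8, 3)
        assert set(map(tuple, coords)) == {
            (x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)
        }

    def test_diagonal_pairs_symmetric_and_counted(self):
        pairs = LAT.xy_diagonal_pairs
        assert all((i, c) in pairs for c, i in pairs)
        # each unit has exactly 2 xy-diagonal partners (same z and other z)
        for c in range(8):
            assert sum(1 for (a, b) in pairs if a == c) == 2

    def test_squared_distances(self):
        d2 = LAT.squared_distances()
        assert d2[0, 0] == 0
        assert d2[0, 7] == 3
        np.testing.assert_array_equal(d2, d2.T)


class TestConfig:
    def test_defaults_and_validation(self):
        cfg = SOMConfig()
        assert cfg.sigma0 == 0.6 and cfg.alpha0 == 1.0 and cfg.n_steps == 100
        with pytest.raises(ValueError):
            SOMConfig(sigma0=0)
        with pytest.raises(ValueError):
            SOMConfig(sigma_min=0.7)
        with pytest.raises(ValueError):
            SOMConfig(schedule="bogus")

    def test_linear_schedule_decays_to_floor(self):
        cfg = SOMConfig(sigma0=1.0, sigma_min=0.1, n_steps=10)
        assert cfg.sigma(0) == 1.0
        assert cfg.sigma(5) == pytest.approx(0.5)
        assert cfg.sigma(10) == pytest.approx(0.1)

    def test_exponential_schedule_monotone(self):
        cfg = SOMConfig(sigma0=1.0, sigma_min=0.01, schedule="exponential", n_steps=50)
        sig = [cfg.sigma(t) for t in range(50)]
        assert all(a >= b for a, b in zip(sig, sig[1:]))

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("sigma0: 0.9\nn_steps: 7\nstochastic: false\n")
        cfg = load_config(p)
        assert cfg.sigma0 == 0.9 and cfg.n_steps == 7 and not cfg.stochastic


class TestInitWeights:
    def test_constant_gene_dimension_degenerate(self):
        X = np.column_stack([np.full(10, 3.0), np.linspace(0, 1, 10)])
        W = init_weights(X, LAT, np.random.default_rng(0))
        np.testing.assert_allclose(W[:, 0], 3.0)
        assert (W[:, 1] >= 0).all() and (W[:, 1] <= 1).all()

    def test_seed_determinism_and_difference(self):
        X = np.random.default_rng(1).normal(size=(20, 4))
        w0 = init_weights(X, LAT, np.random.default_rng(0))
        w0b = init_weights(X, LAT, np.random.default_rng(0))
        w1 = init_weights(X, LAT, np.random.default_rng(1))
        np.testing.assert_array_equal(w0, w0b)
        assert not np.allclose(w0, w1)

    def test_zero_features_rejected(self):
        with pytest.raises(ValueError):
            init_weights(np.empty((5, 0)), LAT, np.random.default_rng(0))


class TestBMU:
    def test_exact_match_and_tiebreak(self):
        W = np.zeros((8, 3))
        W[3] = [5, 5, 5]
        assert best_matching_unit(np.array([5.0, 5, 5]), W) == 3
        # all weights identical -> lowest index wins
        assert best_matching_unit(np.array([1.0, 1, 1]), np.ones((8, 3))) == 0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        W = rng.normal(size=(8, 5))
        for _ in range(20):
            x = rng.normal(size=5)
            brute = min(range(8), key=lambda i: np.sum((x - W[i]) ** 2))
            assert best_matching_unit(x, W) == brute

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            best_matching_unit(np.array([np.nan, 0.0]), np.zeros((8, 2)))


class TestNeighborhood:
    def test_self_weight_is_alpha(self):
        cfg = SOMConfig(alpha0=0.7)
        rng = np.random.default_rng(0)
        assert neighborhood_weight(2, 2, 0, cfg, LAT, rng) == 0.7
        # and no draw was consumed for the self pair
        assert rng.uniform(0.5, 1.0) == np.random.default_rng(0).uniform(0.5, 1.0)

    def test_xy_diagonal_is_zero(self):
        cfg = SOMConfig()
        rng = np.random.default_rng(0)
        # unit 0=(0,0,0); its xy-diagonal partners are 3=(1,1,0) and 7=(1,1,1)
        assert neighborhood_weight(0, 3, 0, cfg, LAT, rng) == 0.0
        assert neighborhood_weight(0, 7, 0, cfg, LAT, rng) == 0.0

    def test_stochastic_bounds_at_unit_distance(self):
        # alpha=1, sigma=0.6, d^2=1: h in (exp(-1/0.72), exp(-0.5/0.72)]
        cfg = SOMConfig(sigma0=0.6, sigma_min=0.6)
        lo, hi = np.exp(-1 / 0.72), np.exp(-0.5 / 0.72)
        rng = np.random.default_rng(0)
        for _ in range(50):
            h = neighborhood_weight(0, 1, 0, cfg, LAT, rng)
            assert lo < h <= hi

    def test_deterministic_mode_u_is_one(self):
        cfg = SOMConfig(sigma0=0.6, sigma_min=0.6, stochastic=False)
        h = neighborhood_weight(0, 1, 0, cfg, LAT, np.random.default_rng(0))
        assert h == pytest.approx(np.exp(-1 / 0.72))

    def test_matrix_respects_structure(self):
        cfg = SOMConfig()
        H = neighborhood_matrix(0, cfg, LAT, np.random.default_rng(0))
        np.testing.assert_allclose(np.diag(H), cfg.alpha0)
        for c, i in LAT.xy_diagonal_pairs:
            assert H[c, i] == 0.0
        assert ((H >= 0) & (H <= cfg.alpha0)).all()


class TestBatchStep:
    def _data(self, n=12, p=4, seed=0):
        return np.random.default_rng(seed).normal(size=(n, p))

    def test_single_sample_moves_bmu_to_it(self):
        X = np.array([[2.0, 3.0, 4.0]])
        W = np.zeros((8, 3))
        W[5] = [1.9, 3.1, 4.0]  # closest unit
        cfg = SOMConfig(stochastic=False, sigma0=1e-6, sigma_min=1e-7)
        newW, bmu = batch_step(W, X, 0, cfg, LAT, np.random.default_rng(0))
        assert bmu[0] == 5
        np.testing.assert_allclose(newW[5], X[0])

    def test_two_equal_h_samples_average(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        W = np.full((8, 2), 10.0)
        W[0] = [1.0, 1.0]  # both samples share BMU 0
        cfg = SOMConfig(stochastic=False, sigma0=1e-6, sigma_min=1e-7)
        newW, bmu = batch_step(W, X, 0, cfg, LAT, np.random.default_rng(0))
        assert list(bmu) == [0, 0]
        np.testing.assert_allclose(newW[0], [1.0, 1.0])

    def test_zero_mass_unit_keeps_weight(self):
        X = np.array([[0.0, 0.0]])
        W = np.full((8, 2), 7.0)
        W[0] = [0.1, 0.1]
        cfg = SOMConfig(stochastic=False, sigma0=1e-6, sigma_min=1e-7)
        newW, _ = batch_step(W, X, 0, cfg, LAT, np.random.default_rng(0))
        # units 3 and 7 are xy-diagonal to BMU 0 -> zero mass -> frozen
        np.testing.assert_allclose(newW[3], 7.0)
        np.testing.assert_allclose(newW[7], 7.0)

    @pytest.mark.parametrize("alpha", [0.1, 1.0, 10.0])
    def test_alpha_cancels(self, alpha):
        X = self._data()
        W = self._data(8, 4, seed=1)
        ref, _ = batch_step(
            W, X, 0, SOMConfig(alpha0=1.0), LAT, np.random.default_rng(3)
        )
        got, _ = batch_step(
            W, X, 0, SOMConfig(alpha0=alpha), LAT, np.random.default_rng(3)
        )
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_sample_order_independence(self):
        X = self._data(20, 5)
        W = self._data(8, 5, seed=2)
        cfg = SOMConfig()
        ref, _ = batch_step(W, X, 0, cfg, LAT, np.random.default_rng(9))
        perm = np.random.default_rng(0).permutation(20)
        got, _ = batch_step(W, X[perm], 0, cfg, LAT, np.random.default_rng(9))
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_updated_weights_in_convex_hull(self):
        X = self._data(15, 3)
        W = self._data(8, 3, seed=4) * 5
        newW, _ = batch_step(W, X, 0, SOMConfig(), LAT, np.random.default_rng(1))
        lo, hi = X.min(axis=0), X.max(axis=0)
        updated = ~np.all(newW == W, axis=1)
        assert (newW[updated] >= lo - 1e-9).all()
        assert (newW[updated] <= hi + 1e-9).all()


class TestFit:
    def test_seed_reproducibility(self, embryo, discriminator_genes, fast_cfg):
        data, _ = embryo
        model = StochasticSOM(data, discriminator_genes, fast_cfg)
        a = model.fit(seed=11)
        b = model.fit(seed=11)
        np.testing.assert_array_equal(a.bmu, b.bmu)
        np.testing.assert_array_equal(a.weights, b.weights)
        c = model.fit(seed=12)
        assert not np.array_equal(a.weights, c.weights)

    def test_lloyd_limit_matches_cluster_means(self):
        # stochastic off, sigma -> 0: fit degenerates to Lloyd iterations;
        # every occupied unit's weight equals the mean of its samples
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        m = make_matrix(X.T, transformed=True)
        cfg = SOMConfig(stochastic=False, sigma0=1e-8, sigma_min=1e-9, n_steps=100)
        res = StochasticSOM(m, config=cfg).fit(seed=0)
        for u in np.unique(res.bmu):
            np.testing.assert_allclose(
                res.weights[u], X[res.bmu == u].mean(axis=0), atol=1e-10
            )

    def test_large_sigma_shrinks_unit_spread(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        m = make_matrix(X.T, transformed=True)
        cfg = SOMConfig(stochastic=False, sigma0=50.0, sigma_min=50.0, n_steps=1)
        model = StochasticSOM(m, config=cfg)
        from spatialsom.som import init_weights

        W0 = init_weights(model.exog, model.lattice, np.random.default_rng(0))
        spread = model.fit(seed=0)
        # after one huge-sigma step every unit approaches the same blend:
        # pairwise distances of coupled units shrink sharply from the
        # initial random spread
        non_diag = [
            (a, b)
            for a in range(8)
            for b in range(a + 1, 8)
            if (a, b) not in Lattice().xy_diagonal_pairs
        ]
        before = max(np.linalg.norm(W0[a] - W0[b]) for a, b in non_diag)
        after = max(np.linalg.norm(spread.weights[a] - spread.weights[b]) for a, b in non_diag)
        assert after < 0.3 * before

    def test_missing_feature_gene(self, embryo, fast_cfg):
        data, _ = embryo
        with pytest.raises(KeyError, match="ghost"):
            StochasticSOM(data, ["disc_D1", "ghost"], fast_cfg)

    def test_results_surface(self, embryo, discriminator_genes, fast_cfg):
        data, _ = embryo
        res = StochasticSOM(data, discriminator_genes, fast_cfg).fit(seed=0)
        assert res.sample_coords.shape == (41, 3)
        assert set(np.unique(res.bmu)) <= set(range(8))
        assert (res.similarity() >= 0).all()
        assert "Stochastic SOM fit" in res.summary()

    def test_json_serialization(self, embryo, discriminator_genes, fast_cfg, tmp_path):
        data, _ = embryo
        res = StochasticSOM(data, discriminator_genes, fast_cfg).fit(seed=0)
        out = tmp_path / "model.json"
        res.to_json(out)
        payload = json.loads(out.read_text())
        assert payload["bmu"] == res.bmu.tolist()
        assert len(payload["weights"]) == 8
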