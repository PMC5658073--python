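import numpy as np
import pytest
from scipy.optimize import minimize

import leaf2dcos as l2
from leaf2dcos.chemometrics import FIT_SCALE, FeatureTable
from leaf2dcos.regions import RegionSet

from conftest import grid_spectra


def table(ids, rx, sx=None, bands=None):
    rx = np.atleast_2d(np.asarray(rx, float))
    sx = rx if sx is None else np.atleast_2d(np.asarray(sx, float))
    bands = bands or RegionSet([(500 + 10 * j, 505 + 10 * j) for j in range(rx.shape[1])])
    return FeatureTable(list(ids), bands, rx, sx)


class TestComputeFeatures:
    def test_single_wavelength_band_rx_equals_sx(self):
        ss = grid_spectra([[0.1, 0.25, 0.3]])
        feats = l2.compute_features(ss, RegionSet([(501, 501)]))
        assert feats.rx[0, 0] == feats.sx[0, 0] == 0.25

    def test_constant_band_sum_is_c_times_width(self):
        ss = grid_spectra([[0.2] * 7])
        feats = l2.compute_features(ss, RegionSet([(501, 505)]))
        assert feats.rx[0, 0] == pytest.approx(0.2)
        assert feats.sx[0, 0] == pytest.approx(0.2 * 5)

    def test_tiny_fixture_matches_direct_max_sum(self, tiny):
        spectra, _, _ = tiny
        feats = l2.compute_features(spectra, RegionSet([(501, 503)]))
        for i in range(spectra.n_samples):
            row = spectra.reflectance[i, 1:4]
            assert feats.rx[i, 0] == row.max()
            assert feats.sx[i, 0] == pytest.approx(row.sum())

    def test_band_outside_grid_rejected(self, tiny):
        spectra, _, _ = tiny
        with pytest.raises(KeyError):
            l2.compute_features(spectra, RegionSet([(600, 610)]))

    def test_permutation_and_scaling_equivariance(self, tiny):
        spectra, _, _ = tiny
        bands = RegionSet([(500, 502)])
        feats = l2.compute_features(spectra, bands)
        perm = [2, 0, 3, 1]
        shuffled = l2.SpectrumSet(
            spectra.wavelengths_nm,
            spectra.reflectance[perm],
            [spectra.sample_ids[i] for i in perm],
        )
        f2 = l2.compute_features(shuffled, bands)
        np.testing.assert_allclose(f2.rx, feats.rx[perm])
        scaled = l2.SpectrumSet(
            spectra.wavelengths_nm, 0.5 * spectra.reflectance, spectra.sample_ids
        )
        f3 = l2.compute_features(scaled, bands)
        np.testing.assert_allclose(f3.rx, 0.5 * feats.rx)
        np.testing.assert_allclose(f3.sx, 0.5 * feats.sx)

    def test_sx_at_least_rx_for_nonnegative_reflectance(self, default100):
        spectra, _, _ = default100
        feats = l2.compute_features(spectra, RegionSet([(537, 560), (708, 719)]))
        assert np.all(feats.sx >= feats.rx)


class TestMakeSplit:
    def test_75_25_partition_and_seed_determinism(self):
        ids = [f"s{i}" for i in range(100)]
        s1 = l2.make_split(ids, ratio=0.75, seed=9)
        s2 = l2.make_split(ids, ratio=0.75, seed=9)
        assert len(s1.calibration_ids) == 75 and len(s1.validation_ids) == 25
        assert s1.calibration_ids == s2.calibration_ids

    def test_union_disjointness_over_many_seeds(self):
        ids = [f"s{i}" for i in range(40)]
        for seed in range(1000):
            s = l2.make_split(ids, ratio=0.75, seed=seed)
            cal, val = set(s.calibration_ids), set(s.validation_ids)
            assert not cal & val
            assert cal | val == set(ids)

    def test_too_small_sides_rejected(self):
        with pytest.raises(ValueError):
            l2.make_split(["a", "b", "c"], ratio=0.75, seed=0)


class TestEvaluate:
    def test_perfect_and_mean_predictors(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert l2.evaluate(obs, obs) == (1.0, 0.0)
        r2, _ = l2.evaluate(np.full(3, obs.mean()), obs)
        assert r2 == pytest.approx(0.0)

    def test_hand_evaluated_rmse(self):
        r2, rmse = l2.evaluate(np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0]))
        assert rmse == pytest.approx(np.sqrt(1 / 3))

    def test_zero_variance_observed_reports_missing_r2(self):
        with pytest.warns(UserWarning, match="undefined"):
            r2, rmse = l2.evaluate(np.array([1.0, 2.0]), np.array([5.0, 5.0]))
        assert np.isnan(r2) and rmse > 0

    def test_translation_invariance_of_rmse(self):
        rng = np.random.default_rng(1)
        p, o = rng.normal(size=10), rng.normal(size=10)
        _, r1 = l2.evaluate(p, o)
        _, r2 = l2.evaluate(p + 7.3, o + 7.3)
        assert r1 == pytest.approx(r2)


class TestPlsr:
    def _linear_problem(self, n=40, noise=0.0, seed=4):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.1, 0.5, size=(n, 2))
        y = 30.0 - 8.0 * X[:, 0] - 5.0 * X[:, 1] + rng.normal(0, noise, n)
        ids = [f"s{i}" for i in range(n)]
        return table(ids, X), l2.NitrogenTable(ids, y), ids

    def test_exact_linear_target_fits_perfectly(self):
        feats, nt, ids = self._linear_problem(noise=0.0)
        split = l2.make_split(ids, seed=0)
        model, m = l2.fit_plsr(feats, nt, split, components=2)
        assert m.r2_cal == pytest.approx(1.0, abs=1e-9)
        assert m.rmse_cal == pytest.approx(0.0, abs=1e-6)
        assert m.r2_val == pytest.approx(1.0, abs=1e-9)

    def test_full_components_equal_least_squares_oracle(self):
        feats, nt, ids = self._linear_problem(noise=0.3)
        split = l2.make_split(ids, seed=1)
        model, _ = l2.fit_plsr(feats, nt, split, components=2)
        pos = {s: i for i, s in enumerate(ids)}
        ic = [pos[s] for s in split.calibration_ids]
        Xc = feats.rx[ic]
        yc = nt.nitrogen_g_per_kg[ic] * FIT_SCALE
        A = np.column_stack([np.ones(len(ic)), Xc])
        beta = np.linalg.solve(A.T @ A, A.T @ yc)  # normal equations
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_coefficient_recovery_within_3se(self):
        # y = a + b1*Rx1 + b2*Rx2 + noise; fitted coefs near truth
        rng = np.random.default_rng(12)
        n = 200
        X = rng.uniform(0.1, 0.5, size=(n, 2))
        sigma = 0.05
        b_true = np.array([-8.0, -5.0])
        y = 32.0 + X @ b_true + rng.normal(0, sigma, n)
        ids = [f"s{i}" for i in range(n)]
        feats = table(ids, X)
        nt = l2.NitrogenTable(ids, y)
        split = l2.make_split(ids, ratio=0.9, seed=0)
        model, _ = l2.fit_plsr(feats, nt, split, components=2)
        ic = [ids.index(s) for s in split.calibration_ids]
        A = np.column_stack([np.ones(len(ic)), X[ic]])
        cov = sigma**2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))[1:]
        np.testing.assert_array_less(
            np.abs(model.coefficients / FIT_SCALE - b_true), 3 * se
        )

    def test_rank_deficient_features_reduce_components_with_warning(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.1, 0.5, 30)
        X = np.column_stack([x, 2 * x])  # rank 1
        ids = [f"s{i}" for i in range(30)]
        feats = table(ids, X)
        nt = l2.NitrogenTable(ids, 30.0 - 5 * x)
        with pytest.warns(UserWarning, match="rank"):
            model, m = l2.fit_plsr(feats, nt, l2.make_split(ids, seed=2), components=2)
        assert model.n_components == 1
        assert m.r2_cal == pytest.approx(1.0, abs=1e-9)


def qp_nusvr_oracle(X, y, C=1.0, nu=0.5, gamma=0.5):
    """Independent nu-SVR dual solve (SLSQP) for tiny instances.

    Dual: min ½βᵀKβ − yᵀβ over β = α − α*, with eᵀβ = 0,
    eᵀ(α + α*) = C·ν·l and 0 ≤ α, α* ≤ C. The bias comes from the KKT
    conditions at free support vectors on both sides.
    """
    n = len(y)
    K = np.exp(-gamma * ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))

    def obj(z):
        b = z[:n] - z[n:]
        return 0.5 * b @ K @ b - y @ b

    def jac(z):
        g = K @ (z[:n] - z[n:]) - y
        return np.concatenate([g, -g])

    cons = [
        {"type": "eq", "fun": lambda z: np.sum(z[:n] - z[n:]),
         "jac": lambda z: np.concatenate([np.ones(n), -np.ones(n)])},
        {"type": "eq", "fun": lambda z: np.sum(z) - C * nu * n,
         "jac": lambda z: np.ones(2 * n)},
    ]
    res = minimize(
        obj, np.full(2 * n, C * nu / 2), jac=jac, bounds=[(0, C)] * (2 * n),
        constraints=cons, method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14},
    )
    assert res.success
    a, astar = res.x[:n], res.x[n:]
    beta = a - astar
    g = K @ beta
    tol = 1e-6
    free_a = (a > tol) & (a < C - tol)
    free_as = (astar > tol) & (astar < C - tol)
    bias = None
    if free_a.any() and free_as.any():
        bias = (np.mean((y - g)[free_a]) + np.mean((y - g)[free_as])) / 2
    return beta, bias


class TestSvr:
    def test_dual_solution_matches_qp_oracle(self):
        from sklearn.svm import NuSVR

        rng = np.random.default_rng(1)  # instance with free SVs on both sides
        X = rng.uniform(0.1, 0.9, size=(8, 1))
        y = 2.6 + 0.8 * X[:, 0] + rng.normal(0, 0.05, 8)
        beta, bias = qp_nusvr_oracle(X, y)
        svr = NuSVR(C=1.0, nu=0.5, gamma=0.5, tol=1e-8).fit(X, y)
        sk_beta = np.zeros(8)
        sk_beta[svr.support_] = svr.dual_coef_.ravel()
        np.testing.assert_allclose(beta, sk_beta, atol=1e-4)
        assert bias is not None
        Xt = np.linspace(0.1, 0.9, 7)[:, None]
        Kt = np.exp(-0.5 * ((Xt[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(Kt @ beta + bias, svr.predict(Xt), atol=1e-4)

    def test_constant_target_predicts_constant(self):
        ids = [f"s{i}" for i in range(20)]
        rng = np.random.default_rng(2)
        feats = table(ids, rng.uniform(0.1, 0.9, size=(20, 1)))
        nt = l2.NitrogenTable(ids, np.full(20, 30.0))
        with pytest.warns(UserWarning):
            svr, m = l2.fit_svr(feats, nt, l2.make_split(ids, seed=0))
        assert m.rmse_cal == pytest.approx(0.0, abs=1e-2)

    def test_noiseless_monotone_target_high_calibration_r2(self):
        rng = np.random.default_rng(6)
        n = 60
        rx = rng.uniform(0.1, 0.9, size=(n, 1))
        y = 26.0 + 8.0 * rx[:, 0]  # monotone in Rx, noiseless
        ids = [f"s{i}" for i in range(n)]
        feats = table(ids, rx)
        nt = l2.NitrogenTable(ids, y)
        _, m = l2.fit_svr(feats, nt, l2.make_split(ids, seed=0), family="rx")
        assert m.r2_cal > 0.95

    def test_nonfinite_features_rejected(self):
        ids = ["a", "b", "c", "d", "e", "f"]
        rx = np.ones((6, 1))
        rx[0, 0] = np.nan
        feats = table(ids, rx)
        nt = l2.NitrogenTable(ids, np.linspace(28, 33, 6))
        with pytest.raises(ValueError, match="non-finite"):
            l2.fit_svr(feats, nt, l2.make_split(ids, ratio=0.6, seed=0))


class TestCompareModels:
    def _m(self, r2v, rmsev):
        return l2.FitMetrics(0.8, 0.7, r2v, rmsev)

    def test_better_validation_metrics_rank_first(self):
        ranked = l2.compare_models(
            [("plsr", self._m(0.665, 1.378)), ("svm", self._m(0.768, 1.019))]
        )
        assert [k for k, _ in ranked] == ["svm", "plsr"]

    def test_identical_metrics_keep_input_order(self):
        ranked = l2.compare_models(
            [("a", self._m(0.7, 1.0)), ("b", self._m(0.7, 1.0))]
        )
        assert [k for k, _ in ranked] == ["a", "b"]

    def test_three_distinct_fully_ordered_with_rmse_tiebreak(self):
        ranked = l2.compare_models(
            [("a", self._m(0.7, 1.2)), ("b", self._m(0.9, 1.5)),
             ("c", self._m(0.7, 1.0))]
        )
        assert [k for k, _ in ranked] == ["b", "c", "a"]
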