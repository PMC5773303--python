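import numpy as np
import pytest

from traitshift.synthetic_data import SynthParams, gen_change_scenario
from traitshift.tps_change_maps import (MapEnsemble, bootstrap_maps,
                                        change_map, fit_tps,
                                        grid_prediction_coords)


def random_coords(rng, n):
    return np.column_stack([rng.uniform(40, 45, n), rng.uniform(-80, -74, n),
                            rng.uniform(0, 1500, n)])


class TestFitTPS:
    def test_zero_smoothing_interpolates(self):
        rng = np.random.default_rng(0)
        X = random_coords(rng, 12)
        y = rng.normal(size=12)
        m = fit_tps(X, y, lam=0.0)
        assert np.abs(m.fitted - y).max() < 1e-8
        assert np.abs(m.predict(X) - y).max() < 1e-8

    def test_matches_independent_dense_solve(self):
        """Same kernel, solved as one dense saddle-point system."""
        rng = np.random.default_rng(1)
        X = random_coords(rng, 10)
        y = rng.normal(size=10)
        lam = 0.03
        m = fit_tps(X, y, lam=lam)
        n = 10
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        K = -np.sqrt(((Xs[:, None] - Xs[None]) ** 2).sum(-1))
        T = np.column_stack([np.ones(n), Xs])
        A = np.block([[K + n * lam * np.eye(n), T],
                      [T.T, np.zeros((4, 4))]])
        sol = np.linalg.solve(A, np.concatenate([y, np.zeros(4)]))
        c, d = sol[:n], sol[n:]
        Xnew = random_coords(rng, 6)
        Xns = (Xnew - X.mean(0)) / X.std(0, ddof=1)
        Kn = -np.sqrt(((Xns[:, None] - Xs[None]) ** 2).sum(-1))
        oracle = Kn @ c + np.column_stack([np.ones(6), Xns]) @ d
        assert np.allclose(m.predict(Xnew), oracle, atol=1e-8)
        assert np.allclose(m.rbf_coeffs, c, atol=1e-8)

    def test_affine_functions_reproduced_exactly(self):
        rng = np.random.default_rng(2)
        X = random_coords(rng, 15)
        y = 2.0 + 3.0 * X[:, 0] - 0.5 * X[:, 1] + 0.004 * X[:, 2]
        for lam in (0.0, 0.1, 10.0):
            m = fit_tps(X, y, lam=lam)
            Xnew = random_coords(rng, 8)
            truth = 2.0 + 3.0 * Xnew[:, 0] - 0.5 * Xnew[:, 1] \
                + 0.004 * Xnew[:, 2]
            assert np.allclose(m.predict(Xnew), truth, atol=1e-6)

    def test_side_conditions_hold(self):
        rng = np.random.default_rng(3)
        X = random_coords(rng, 20)
        m = fit_tps(X, rng.normal(size=20), lam=0.05)
        T = np.column_stack([np.ones(20), (X - m.std_mean) / m.std_sd])
        assert np.allclose(T.T @ m.rbf_coeffs, 0.0, atol=1e-8)

    def test_constant_shift_equivariance(self):
        rng = np.random.default_rng(4)
        X = random_coords(rng, 25)
        y = rng.normal(size=25)
        m1 = fit_tps(X, y, lam=0.2)
        m2 = fit_tps(X, y + 7.0, lam=0.2)
        Xn = random_coords(rng, 5)
        assert np.allclose(m2.predict(Xn), m1.predict(Xn) + 7.0, atol=1e-8)

    def test_too_few_points_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            fit_tps(random_coords(rng, 6), rng.normal(size=6))

    def test_gcv_smooths_noise_more_than_signal(self):
        """Median GCV-selected lambda over seeded trials is larger for pure
        noise than for strongly structured data of equal variance."""
        lam_noise, lam_signal = [], []
        for s in range(20):
            rng = np.random.default_rng(s)
            X = random_coords(rng, 60)
            noise = rng.standard_normal(60)
            signal = np.sin(2.0 * X[:, 0]) + np.cos(X[:, 1])
            signal = (signal - signal.mean()) / signal.std()
            lam_noise.append(fit_tps(X, noise, lam="auto").lam)
            lam_signal.append(fit_tps(X, signal, lam="auto").lam)
        assert np.median(lam_noise) >= np.median(lam_signal)


class TestBootstrapMaps:
    def test_noiseless_affine_surface_has_degenerate_ci(self):
        rng = np.random.default_rng(6)
        X = random_coords(rng, 40)
        y = 1.0 + 0.5 * X[:, 0] - 0.2 * X[:, 1] + 0.001 * X[:, 2]
        G = random_coords(rng, 30)
        ens = bootstrap_maps(X, y, G, B=20, seed=3)
        truth = 1.0 + 0.5 * G[:, 0] - 0.2 * G[:, 1] + 0.001 * G[:, 2]
        assert np.max(ens.hi - ens.lo) < 1e-6
        assert np.allclose(ens.mean, truth, atol=1e-6)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        X = random_coords(rng, 40)
        y = rng.normal(size=40)
        G = random_coords(rng, 10)
        a = bootstrap_maps(X, y, G, B=10, seed=11)
        b = bootstrap_maps(X, y, G, B=10, seed=11)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.lo, b.lo)

    def test_ci_orders_and_brackets_mean(self):
        rng = np.random.default_rng(8)
        X = random_coords(rng, 50)
        y = rng.normal(size=50)
        G = random_coords(rng, 15)
        ens = bootstrap_maps(X, y, G, B=30, seed=2)
        assert (ens.lo <= ens.mean + 1e-12).all()
        assert (ens.mean <= ens.hi + 1e-12).all()

    def test_coverage_of_known_smooth_surface(self):
        """Bootstrap CIs cover the true generating surface at close to the
        nominal rate across pixels."""
        pre, _, truth = gen_change_scenario(
            300, delta=0.0, shift_box=(0, 0, 0, 0), seed=9,
            params=SynthParams(grid_shape=(20, 30), seed=9), noise_sd=4.0)
        gc = grid_prediction_coords(truth["grid"], truth["mask"],
                                    truth["dem"])
        ens = bootstrap_maps(pre[["lat", "lon", "elev_m"]].to_numpy(),
                             pre["y"].to_numpy(), gc, B=100, seed=4)
        true_vals = truth["surface"][truth["mask"]]
        covered = (ens.lo <= true_vals) & (true_vals <= ens.hi)
        assert 0.88 <= covered.mean() <= 0.99


def tiny_ensemble(mean, lo, hi):
    m = np.asarray(mean, dtype=float)
    return MapEnsemble(grid_coords=np.zeros((len(m), 3)), mean=m,
                       lo=np.asarray(lo, float), hi=np.asarray(hi, float),
                       pooled_se=np.ones(len(m)), r2_mean=1.0, mspe=0.0,
                       B=2, seed=0)


class TestChangeMap:
    def test_self_comparison_is_null(self):
        e = tiny_ensemble([1.0, 2.0], [0.5, 1.5], [1.5, 2.5])
        cm = change_map(e, e)
        assert np.allclose(cm.delta, 0.0)
        assert not cm.significant.any()

    def test_disjoint_intervals_are_significant(self):
        pre = tiny_ensemble([11.0], [10.0], [12.0])
        post = tiny_ensemble([14.0], [13.0], [15.0])
        cm = change_map(pre, post)
        assert cm.significant[0]
        assert cm.delta[0] == pytest.approx(3.0)
        assert cm.delta_masked[0] == pytest.approx(3.0)

    def test_overlapping_intervals_are_zero_change(self):
        pre = tiny_ensemble([11.0], [10.0], [12.0])
        post = tiny_ensemble([13.0], [11.5], [15.0])
        cm = change_map(pre, post)
        assert not cm.significant[0]
        assert cm.delta_masked[0] == 0.0

    def test_pooled_se_is_root_sum_of_squares(self):
        pre = tiny_ensemble([1.0], [0.0], [2.0])
        post = tiny_ensemble([1.0], [0.0], [2.0])
        pre.pooled_se = np.array([3.0])
        post.pooled_se = np.array([4.0])
        cm = change_map(pre, post)
        assert cm.pooled_se[0] == pytest.approx(5.0)

    def test_grid_mismatch_raises(self):
        a = tiny_ensemble([1.0], [0.0], [2.0])
        b = tiny_ensemble([1.0, 2.0], [0.0, 1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            change_map(a, b)
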