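import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traitshift.spatial_lmm import (FIVE_MODELS, LMMFit, ModelSpec, aicc,
                                    fit_spatial_lmm, lrt, r2_nakagawa,
                                    select_and_average)


def simulate_lmm(seed, n=120, beta=(120.0, -42.4, -1.22), s_year=6.0,
                 s_resid=15.0, rho=2.0, n_years=40):
    """Direct draw from the assumed model (test-side generator)."""
    rng = np.random.default_rng(seed)
    coords = np.column_stack([rng.uniform(40, 48, n), rng.uniform(-85, -70, n)])
    X = np.column_stack([np.ones(n), rng.standard_normal(n),
                         rng.standard_normal(n)])[:, :len(beta)]
    years = rng.integers(1901, 1901 + n_years, n)
    uy, yi = np.unique(years, return_inverse=True)
    D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    L = np.linalg.cholesky(np.exp(-D / rho) + 1e-10 * np.eye(n))
    y = (X @ np.asarray(beta) + rng.normal(0, s_year, len(uy))[yi]
         + s_resid * (L @ rng.standard_normal(n)))
    return y, X, years, coords


class TestAICc:
    def test_worked_arithmetic(self):
        assert aicc(-50.0, 3, 20) == pytest.approx(107.5)

    def test_tends_to_aic_for_large_n(self):
        assert aicc(-50.0, 3, 10**7) == pytest.approx(106.0, abs=1e-5)

    def test_monotone_penalty(self):
        assert aicc(-50.0, 2, 20) < aicc(-50.0, 3, 20)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            aicc(-50.0, 5, 6)


class TestModelSpec:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError):
            ModelSpec("julian_day", ("ffd:precip",))

    def test_candidate_family_is_the_five_models(self):
        assert len(FIVE_MODELS) == 5
        assert () in FIVE_MODELS
        assert ("ffd", "precip", "ffd:precip") in FIVE_MODELS


class TestFit:
    def test_loglik_matches_dense_gaussian_density(self):
        """The reported loglik equals an independent dense evaluation of the
        multivariate normal density at the fitted parameters."""
        y, X, years, coords = simulate_lmm(0, n=60)
        fit = fit_spatial_lmm(y, X, years, coords,
                              term_names=["intercept", "ffd", "precip"],
                              seed=1)
        uy, yi = np.unique(years, return_inverse=True)
        Z = np.eye(len(uy))[yi]
        D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        V = (fit.sigma2_year * (Z @ Z.T)
             + fit.sigma2_resid * np.exp(-D / fit.rho)
             + 1e-8 * fit.sigma2_resid * np.eye(len(y)))
        mu = X @ np.array([fit.beta["intercept"], fit.beta["ffd"],
                           fit.beta["precip"]])
        oracle = stats.multivariate_normal.logpdf(y, mu, V)
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_independence_limit_equals_ols(self):
        """With no year variance and vanishing range the GLS solution is OLS."""
        from traitshift.spatial_lmm import _profile_neg2ll
        y, X, years, coords = simulate_lmm(2, n=50)
        uy, yi = np.unique(years, return_inverse=True)
        Z = np.eye(len(uy))[yi]
        D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        _, aux = _profile_neg2ll(np.array([-30.0, np.log(1e-8)]), y, X,
                                 Z @ Z.T, D, 0.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(aux["beta"], ols, atol=1e-8)

    def test_scale_equivariance(self):
        y, X, years, coords = simulate_lmm(3, n=60)
        f1 = fit_spatial_lmm(y, X, years, coords, seed=0, n_starts=2)
        c = 10.0
        f2 = fit_spatial_lmm(c * y, X, years, coords, seed=0, n_starts=2)
        for k in f1.beta:
            assert f2.beta[k] == pytest.approx(c * f1.beta[k], rel=1e-3)
            assert f2.se_beta[k] == pytest.approx(c * f1.se_beta[k], rel=1e-3)
        assert f2.loglik == pytest.approx(f1.loglik - len(y) * np.log(c),
                                          rel=1e-6)

    def test_preconditions(self):
        y, X, years, coords = simulate_lmm(4, n=12)
        with pytest.raises(ValueError, match="10 records"):
            fit_spatial_lmm(y[:5], X[:5], years[:5], coords[:5])
        with pytest.raises(ValueError, match="distinct years"):
            fit_spatial_lmm(y, X, np.full(12, 1950), coords)

    def test_duplicate_coordinates_are_handled(self):
        y, X, years, coords = simulate_lmm(5, n=40)
        coords[1] = coords[0]
        fit = fit_spatial_lmm(y, X, years, coords, n_starts=2)
        assert np.isfinite(fit.loglik)


class TestLRT:
    def test_identical_models_give_null_result(self):
        y, X, years, coords = simulate_lmm(6, n=40)
        f = fit_spatial_lmm(y, X, years, coords,
                            term_names=["intercept", "ffd", "precip"],
                            n_starts=2)
        chi2, df, p = lrt(f, f)
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_chi_square_quantile(self):
        # chi2 = 3.841 on 1 df sits exactly at p = 0.05
        assert stats.chi2.sf(3.841458820694124, 1) == pytest.approx(0.05)

    def test_non_nested_raises(self):
        y, X, years, coords = simulate_lmm(7, n=40)
        f1 = fit_spatial_lmm(y, X[:, :2], years, coords,
                             term_names=["intercept", "ffd"], n_starts=1)
        f2 = fit_spatial_lmm(y, np.column_stack([X[:, 0], X[:, 2]]), years,
                             coords, term_names=["intercept", "precip"],
                             n_starts=1)
        with pytest.raises(ValueError):
            lrt(f1, f2)

    def test_type_one_error_rate_under_null(self):
        """Testing an absent FFD term rejects at ~the nominal 5% rate."""
        reps, rejections = 150, 0
        for r in range(reps):
            y, X, years, coords = simulate_lmm(
                1000 + r, n=35, beta=(120.0,), s_year=4.0, s_resid=10.0)
            Xf = np.column_stack([X, np.random.default_rng(r).standard_normal(35)])
            full = fit_spatial_lmm(y, Xf, years, coords,
                                   term_names=["intercept", "ffd"], n_starts=1)
            red = fit_spatial_lmm(y, X, years, coords,
                                  term_names=["intercept"], n_starts=1)
            _, _, p = lrt(full, red)
            rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.12


def make_fit(terms, aicc_val, beta, se, n=100):
    names = ["intercept"] + list(terms)
    return LMMFit(terms=tuple(terms), beta=dict(zip(names, beta)),
                  se_beta=dict(zip(names, se)), sigma2_year=1.0,
                  sigma2_resid=2.0, rho=1.0, loglik=-50.0, n=n,
                  k=len(terms) + 4, aicc=aicc_val, r2_marginal=0.1,
                  r2_conditional=0.2, converged=True, var_fixed=0.5)


class TestSelectAndAverage:
    def test_singleton_support_returns_that_model(self):
        fits = [make_fit(("ffd",), 100.0, [1.0, 0.5], [0.1, 0.05]),
                make_fit((), 110.0, [1.2], [0.1])]
        sel = select_and_average(fits)
        row = sel.averaged.set_index("term").loc["ffd"]
        assert row["estimate"] == pytest.approx(0.5)
        assert row["se"] == pytest.approx(0.05)

    def test_equal_weights_zero_substitution_halves_estimate(self):
        fits = [make_fit(("ffd",), 100.0, [1.0, 0.8], [0.1, 0.05]),
                make_fit((), 100.0, [1.0], [0.1])]
        sel = select_and_average(fits)
        row = sel.averaged.set_index("term").loc["ffd"]
        assert row["estimate"] == pytest.approx(0.4)

    def test_weights_sum_to_one(self):
        fits = [make_fit((), 100.0 + i, [1.0], [0.1]) for i in range(5)]
        sel = select_and_average(fits)
        assert sel.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonconverged_excluded_with_warning(self):
        good = make_fit(("ffd",), 100.0, [1.0, 0.5], [0.1, 0.05])
        bad = make_fit((), 99.0, [1.0], [0.1])
        bad.converged = False
        with pytest.warns(UserWarning, match="non-converged"):
            sel = select_and_average([good, bad])
        assert sel.best.terms == ("ffd",)


def test_negative_ffd_phenology_effect_is_flagged_significant():
    """On pre-period-style data generated with a strong negative FFD effect
    on Julian day, the averaged five-model fit flags FFD as significant and
    negative in every replicate (reduced replicate count)."""
    from traitshift.spatial_lmm import fit_candidates

    for r in range(6):
        rng = np.random.default_rng(600 + r)
        n = 350
        records = pd.DataFrame({
            "lat": rng.uniform(40, 48, n), "lon": rng.uniform(-85, -70, n),
            "elev_m": rng.uniform(0, 1200, n),
            "year": rng.integers(1901, 1961, n),
            "scaled_ffd": rng.standard_normal(n),
            "scaled_precip": rng.standard_normal(n),
            "sex": "female", "svl_mm": 45.0,
        })
        coords = records[["lat", "lon"]].to_numpy()
        D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        L = np.linalg.cholesky(np.exp(-D / 2.0) + 1e-10 * np.eye(n))
        uy, yi = np.unique(records["year"], return_inverse=True)
        records["julian_day"] = (
            120.0 - 42.4 * records["scaled_ffd"]
            - 1.22 * records["scaled_precip"]
            + np.random.default_rng(700 + r).normal(0, 6, len(uy))[yi]
            + 15.0 * (L @ np.random.default_rng(800 + r).standard_normal(n)))
        fits = fit_candidates(records, "julian_day", use_elevation=False,
                              n_starts=2, seed=r)
        sel = select_and_average(fits)
        row = sel.averaged.set_index("term").loc["ffd"]
        assert row["significant"] and row["estimate"] < 0


class TestR2:
    def test_intercept_only_marginal_is_zero(self):
        f = make_fit((), 100.0, [1.0], [0.1])
        f.var_fixed = 0.0
        r2m, r2c = r2_nakagawa(f)
        assert r2m == 0.0
        assert r2c == pytest.approx(1.0 / 3.0)

    def test_no_year_variance_collapses_marginal_and_conditional(self):
        f = make_fit(("ffd",), 100.0, [1.0, 0.5], [0.1, 0.05])
        f.sigma2_year = 0.0
        r2m, r2c = r2_nakagawa(f)
        assert r2m == r2c

    def test_vanishing_residual_variance_gives_conditional_one(self):
        f = make_fit(("ffd",), 100.0, [1.0, 0.5], [0.1, 0.05])
        f.sigma2_resid = 1e-12
        _, r2c = r2_nakagawa(f)
        assert r2c == pytest.approx(1.0, abs=1e-9)
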