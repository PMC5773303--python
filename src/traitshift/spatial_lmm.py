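"""Historic climate-trait models: spatial linear mixed models with AICc.

The model for a trait y (log snout-vent length, or breeding Julian day) at
record i is

    y_i = x_i' beta + b_{year(i)} + e_i,
    b_year ~ N(0, sigma2_year),   Cov(e_i, e_j) = sigma2_resid exp(-d_ij / rho),

with d the Euclidean distance between records in coordinate space (lat, lon
and optionally elevation). Fitting is by maximum likelihood: the overall
variance scale is profiled out analytically and the optimizer searches
(log variance ratio, log range) with multiple seeded starts; beta is the GLS
solution given the variance parameters.

The candidate set is the five-model family {intercept-only, FFD,
precipitation, FFD+precipitation, FFD+precipitation+interaction}; models are
ranked by AICc and, when several are within 2 AICc of the best, averaged
with zero substitution (full averaging) using Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .model_average import full_average

TERMS = ("ffd", "precip", "ffd:precip")

FIVE_MODELS: tuple[tuple[str, ...], ...] = (
    (),
    ("ffd",),
    ("precip",),
    ("ffd", "precip"),
    ("ffd", "precip", "ffd:precip"),
)

RESPONSES = ("log_svl_female", "log_svl_male", "julian_day")


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        unknown = set(self.fixed_terms) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown terms {unknown}")
        if "ffd:precip" in self.fixed_terms and not (
                "ffd" in self.fixed_terms and "precip" in self.fixed_terms):
            raise ValueError("interaction requires both main effects")


@dataclass
class LMMFit:
    terms: tuple[str, ...]
    beta: dict[str, float]
    se_beta: dict[str, float]
    sigma2_year: float
    sigma2_resid: float
    rho: float
    loglik: float
    n: int
    k: int
    aicc: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    var_fixed: float = 0.0
    message: str = ""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2 ll + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def design_matrix(records: pd.DataFrame, terms: tuple[str, ...]
                  ) -> tuple[np.ndarray, list[str]]:
    """Intercept plus the requested scaled-climate columns."""
    cols = [np.ones(len(records))]
    names = ["intercept"]
    col_of = {
        "ffd": records["scaled_ffd"].to_numpy(),
        "precip": records["scaled_precip"].to_numpy(),
    }
    for t in terms:
        if t == "ffd:precip":
            cols.append(col_of["ffd"] * col_of["precip"])
        else:
            cols.append(col_of[t])
        names.append(t)
    return np.column_stack(cols), names


def _profile_neg2ll(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                    ZZt: np.ndarray, D: np.ndarray, jitter: float
                    ) -> tuple[float, dict]:
    """-2 log L with the overall variance profiled out.

    theta = (log gamma, log rho); V0 = gamma ZZ' + exp(-D/rho) + jitter I;
    sigma2_hat = r' V0^-1 r / n (ML).
    """
    gamma, rho = np.exp(theta)
    n = len(y)
    V0 = gamma * ZZt + np.exp(-D / rho)
    V0[np.diag_indices_from(V0)] += jitter
    try:
        cf = cho_factor(V0, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, {}
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except np.linalg.LinAlgError:
        return np.inf, {}
    r = y - X @ beta
    q = float(r @ cho_solve(cf, r))
    if q <= 0:
        return np.inf, {}
    sigma2 = q / n
    neg2ll = n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n
    aux = {"beta": beta, "sigma2": sigma2, "cov_beta_unit": XtViX,
           "gamma": gamma, "rho": rho}
    return neg2ll, aux


def fit_spatial_lmm(
    y: np.ndarray,
    X: np.ndarray,
    years: np.ndarray,
    coords: np.ndarray,
    term_names: list[str] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    jitter: float = 1e-8,
) -> LMMFit:
    """ML fit of the spatial year-intercept mixed model (low-level API)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 records")
    uyears, yidx = np.unique(years, return_inverse=True)
    if len(uyears) < 2:
        raise ValueError("need at least 2 distinct years")
    Z = np.zeros((n, len(uyears)))
    Z[np.arange(n), yidx] = 1.0
    ZZt = Z @ Z.T
    D = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    dscale = np.median(D[np.triu_indices(n, 1)])

    rng = np.random.default_rng(seed)
    base = [(np.log(g), np.log(r * dscale))
            for g in (0.1, 1.0) for r in (0.1, 0.5)]
    starts = (base + [
        (float(rng.uniform(-4, 2)), float(np.log(dscale) + rng.uniform(-3, 1)))
        for _ in range(max(n_starts - len(base), 0))
    ])[:max(n_starts, 1)]
    bounds = [(-15.0, 8.0),
              (np.log(dscale) - 9.0, np.log(max(D.max(), dscale)) + 3.0)]

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            lambda th: _profile_neg2ll(th, y, X, ZZt, D, jitter)[0],
            x0=np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 600},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-12):
            best = res
        converged = converged or (np.isfinite(res.fun) and res.success)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("spatial LMM likelihood evaluation failed")

    neg2ll, aux = _profile_neg2ll(best.x, y, X, ZZt, D, jitter)
    sigma2 = aux["sigma2"]
    sigma2_year = aux["gamma"] * sigma2
    sigma2_resid = sigma2
    cov_beta = sigma2 * np.linalg.inv(aux["cov_beta_unit"])
    se = np.sqrt(np.diag(cov_beta))
    loglik = -0.5 * neg2ll
    names = term_names or [f"b{j}" for j in range(p)]
    k = p + 3  # fixed effects incl. intercept + (sigma2_year, sigma2_resid, rho)
    fitted_fixed = X @ aux["beta"]
    var_fixed = float(np.var(fitted_fixed, ddof=1)) if p > 1 else 0.0
    denom = var_fixed + sigma2_year + sigma2_resid
    fit = LMMFit(
        terms=tuple(nm for nm in names if nm != "intercept"),
        beta=dict(zip(names, aux["beta"])),
        se_beta=dict(zip(names, se)),
        sigma2_year=float(sigma2_year),
        sigma2_resid=float(sigma2_resid),
        rho=float(aux["rho"]),
        loglik=float(loglik),
        n=n,
        k=k,
        aicc=aicc(loglik, k, n),
        r2_marginal=var_fixed / denom,
        r2_conditional=(var_fixed + sigma2_year) / denom,
        converged=bool(converged),
        var_fixed=var_fixed,
        message="" if converged else "no optimizer start converged",
    )
    return fit


def response_subset(records: pd.DataFrame, response: str
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Rows and response vector for one of the three modeled traits."""
    if response == "log_svl_female":
        sub = records[records["sex"] == "female"]
        return sub, np.log(sub["svl_mm"].to_numpy())
    if response == "log_svl_male":
        sub = records[records["sex"] == "male"]
        return sub, np.log(sub["svl_mm"].to_numpy())
    return records, records["julian_day"].to_numpy(dtype=float)


def coordinate_matrix(records: pd.DataFrame, mode: str = "raw",
                      use_elevation: bool = True) -> np.ndarray:
    """(lat, lon[, elev]) coordinates, optionally standardized to unit SD."""
    cols = ["lat", "lon"] + (["elev_m"] if use_elevation else [])
    C = records[cols].to_numpy(dtype=float)
    if mode == "normalized":
        C = (C - C.mean(0)) / C.std(0, ddof=1)
    elif mode != "raw":
        raise ValueError("coordinate mode must be 'raw' or 'normalized'")
    return C


def fit_lmm(model: ModelSpec, records: pd.DataFrame,
            coord_mode: str = "raw", use_elevation: bool = True,
            seed: int = 0, n_starts: int = 5) -> LMMFit:
    """Fit one candidate model on records carrying scaled climate columns."""
    sub, y = response_subset(records, model.response)
    X, names = design_matrix(sub, model.fixed_terms)
    coords = coordinate_matrix(sub, coord_mode, use_elevation)
    return fit_spatial_lmm(y, X, sub["year"].to_numpy(), coords,
                           term_names=names, seed=seed, n_starts=n_starts)


@dataclass
class SelectionResult:
    table: pd.DataFrame  # per model: terms, loglik, k, aicc, delta, weight
    best: LMMFit
    averaged: pd.DataFrame  # per term: estimate, se, ci_lo, ci_hi, significant
    support_terms: list[tuple[str, ...]] = field(default_factory=list)


def select_and_average(fits: list[LMMFit],
                       delta_max: float = 2.0) -> SelectionResult:
    """AICc ranking, Akaike weights and full model averaging over the
    Delta-AICc <= ``delta_max`` support set (see :mod:`.model_average`)."""
    table, averaged, support_terms = full_average(fits, TERMS, delta_max)
    ok = [f for f in fits if f.converged]
    best = min(ok, key=lambda f: f.aicc)
    return SelectionResult(table=table, best=best, averaged=averaged,
                           support_terms=support_terms)


def fit_candidates(records: pd.DataFrame, response: str,
                   coord_mode: str = "raw", use_elevation: bool = True,
                   seed: int = 0, n_starts: int = 5) -> list[LMMFit]:
    """Fit the five-model candidate family for one response."""
    return [
        fit_lmm(ModelSpec(response, terms), records, coord_mode,
                use_elevation, seed=seed, n_starts=n_starts)
        for terms in FIVE_MODELS
    ]


def lrt(full: LMMFit, reduced: LMMFit) -> tuple[float, int, float]:
    """Likelihood ratio test of nested ML fits: (chi2, df, p)."""
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("reduced model terms are not a subset of the full's")
    if full.n != reduced.n:
        raise ValueError("fits are not on the same data")
    df = full.k - reduced.k
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """(marginal, conditional) R^2: fixed-effect vs fixed+random variance share."""
    denom = fit.var_fixed + fit.sigma2_year + fit.sigma2_resid
    return fit.var_fixed / denom, (fit.var_fixed + fit.sigma2_year) / denom
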