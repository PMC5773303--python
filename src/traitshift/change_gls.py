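"""Trait change vs proportional climate change: weighted spatial GLS.

From the change maps, n (default 484) cells are sampled uniformly without
replacement; each point carries the trait change delta, the proportional
changes in frost-free days (F) and precipitation (P) relative to the
pre-cutoff mean, and the pooled bootstrap SE of the trait change. The model
is a generalized least-squares regression of delta on a second-order
polynomial in (F, P),

    delta_i = b0 + b1 F + b2 F^2 + b3 P + b4 P^2 + b5 F.P + eps_i,

fit by maximum likelihood with covariance sigma^2 D C(rho) D, where
C(rho)_ij = exp(-d_ij / rho) over (lon, lat) distance and D encodes the
per-point pooled SE (precision weighting: points mapped with low bootstrap
uncertainty count more). All marginality-respecting term subsets are
enumerated, ranked by AICc and full-averaged over the Delta-AICc <= 2 set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .climate_layers import ChangeRasters
from .model_average import Z95, full_average
from .tps_change_maps import ChangeMap

GLS_TERMS = ("F", "F2", "P", "P2", "F:P")

# all subsets respecting marginality (quadratic => linear, interaction =>
# both linear terms), plus the intercept-only model
CANDIDATE_TERMS: tuple[tuple[str, ...], ...] = (
    (),
    ("F",),
    ("P",),
    ("F", "F2"),
    ("P", "P2"),
    ("F", "P"),
    ("F", "P", "F:P"),
    ("F", "F2", "P"),
    ("F", "P", "P2"),
    ("F", "F2", "P", "P2"),
    ("F", "F2", "P", "P2", "F:P"),
)


def sample_change_points(mask: np.ndarray, n: int = 484,
                         seed: int = 0) -> np.ndarray:
    """Uniform without-replacement sample of valid cells; (n, 2) rows/cols."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if len(rows) < n:
        raise ValueError(
            f"only {len(rows)} valid cells for {n} requested points "
            f"(short by {n - len(rows)})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False)
    return np.column_stack([rows[idx], cols[idx]])


def build_change_points(cells: np.ndarray, trait_change: ChangeMap,
                        climate_change: ChangeRasters) -> pd.DataFrame:
    """Extract trait delta, pooled SE and climate change at sampled cells."""
    grid = climate_change.grid
    lat2d, lon2d = grid.cell_centers()
    r, c = cells[:, 0], cells[:, 1]
    delta_r = trait_change.rasterize(trait_change.delta)
    se_r = trait_change.rasterize(trait_change.pooled_se)
    df = pd.DataFrame({
        "lat": lat2d[r, c],
        "lon": lon2d[r, c],
        "delta": delta_r[r, c],
        "pooled_se": se_r[r, c],
        "prop_dffd": climate_change.change["ffd"][r, c],
        "prop_dprecip": climate_change.change["precipitation"][r, c],
    })
    if df.isna().any().any():
        raise ValueError("sampled cells include invalid (masked) data")
    return df


@dataclass
class ChangeGLSFit:
    terms: tuple[str, ...]
    beta: dict[str, float]
    se_beta: dict[str, float]
    ci: dict[str, tuple[float, float]]
    significant: dict[str, bool]
    sigma2: float
    rho: float
    loglik: float
    n: int
    k: int
    aicc: float
    converged: bool


def _design(points: pd.DataFrame, terms: tuple[str, ...]
            ) -> tuple[np.ndarray, list[str]]:
    F = points["prop_dffd"].to_numpy(dtype=float)
    P = points["prop_dprecip"].to_numpy(dtype=float)
    col_of = {"F": F, "F2": F**2, "P": P, "P2": P**2, "F:P": F * P}
    X = np.column_stack([np.ones(len(points))] + [col_of[t] for t in terms])
    return X, ["intercept"] + list(terms)


def _check_marginality(terms: tuple[str, ...]) -> None:
    if "F2" in terms and "F" not in terms:
        raise ValueError("F^2 requires the linear F term")
    if "P2" in terms and "P" not in terms:
        raise ValueError("P^2 requires the linear P term")
    if "F:P" in terms and not ("F" in terms and "P" in terms):
        raise ValueError("F:P requires both linear terms")


def fit_change_gls(points: pd.DataFrame, terms: tuple[str, ...],
                   weight_mode: str = "variance",
                   rho: float | None = None,
                   jitter: float = 1e-8) -> ChangeGLSFit:
    """ML spatial GLS of trait change on polynomial climate change.

    ``weight_mode='variance'`` gives point i a residual SD proportional to
    its pooled SE (precision weights 1/se^2); ``'se'`` uses SD proportional
    to sqrt(pooled SE) (weights 1/se). The range ``rho`` is estimated
    jointly by ML (overall scale sigma^2 profiled out) unless fixed by the
    caller.
    """
    _check_marginality(terms)
    X, names = _design(points, terms)
    y = points["delta"].to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            f"singular design for terms {names}: only rank {rank}; a climate "
            "change column is constant or collinear")
    se = points["pooled_se"].to_numpy(dtype=float)
    if weight_mode == "variance":
        sd = se
    elif weight_mode == "se":
        sd = np.sqrt(se)
    else:
        raise ValueError("weight_mode must be 'variance' or 'se'")
    sd = sd / np.exp(np.mean(np.log(sd)))  # geometric-mean normalized

    pts = points[["lon", "lat"]].to_numpy(dtype=float)
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    dscale = np.median(D[np.triu_indices(n, 1)])
    outer_sd = np.outer(sd, sd)

    def neg2ll(log_rho: float):
        rho_v = float(np.exp(log_rho))
        V0 = np.exp(-D / rho_v) * outer_sd
        V0[np.diag_indices_from(V0)] += jitter
        try:
            cf = cho_factor(V0, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, None
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi_X = cho_solve(cf, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, Vi_X.T @ y)
        r = y - X @ beta
        q = float(r @ cho_solve(cf, r))
        if q <= 0:
            return np.inf, None
        sigma2 = q / n
        val = n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n
        return val, (beta, sigma2, XtViX, rho_v)

    if rho is not None:
        val, aux = neg2ll(np.log(rho))
        success = aux is not None
    else:
        res = optimize.minimize_scalar(
            lambda lr: neg2ll(lr)[0],
            bounds=(np.log(dscale) - 8.0, np.log(max(D.max(), dscale)) + 3.0),
            method="bounded", options={"xatol": 1e-7},
        )
        val, aux = neg2ll(res.x)
        success = res.success
    if aux is None:
        raise RuntimeError("change-GLS likelihood evaluation failed")
    beta, sigma2, XtViX, rho_hat = aux
    cov = sigma2 * np.linalg.inv(XtViX)
    se_b = np.sqrt(np.diag(cov))
    loglik = -0.5 * val
    k = p + 2  # fixed effects + (sigma2, rho)
    ci = {nm: (b - Z95 * s, b + Z95 * s)
          for nm, b, s in zip(names, beta, se_b)}
    return ChangeGLSFit(
        terms=tuple(terms),
        beta=dict(zip(names, beta)),
        se_beta=dict(zip(names, se_b)),
        ci=ci,
        significant={nm: bool(lo > 0 or hi < 0)
                     for nm, (lo, hi) in ci.items()},
        sigma2=float(sigma2), rho=float(rho_hat), loglik=float(loglik),
        n=n, k=k,
        aicc=-2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1),
        converged=bool(success),
    )


@dataclass
class ChangeSelection:
    table: pd.DataFrame
    best: ChangeGLSFit
    averaged: pd.DataFrame
    failures: dict[tuple[str, ...], str]


def enumerate_and_average(points: pd.DataFrame,
                          weight_mode: str = "variance",
                          delta_max: float = 2.0) -> ChangeSelection:
    """Fit all marginality-respecting candidates; AICc-rank and average."""
    fits: list[ChangeGLSFit] = []
    failures: dict[tuple[str, ...], str] = {}
    for terms in CANDIDATE_TERMS:
        try:
            fits.append(fit_change_gls(points, terms, weight_mode))
        except (ValueError, RuntimeError) as exc:
            failures[terms] = str(exc)
    if not fits:
        raise ValueError(f"every candidate model failed: {failures}")
    table, averaged, _ = full_average(fits, GLS_TERMS, delta_max)
    best = min((f for f in fits if f.converged), key=lambda f: f.aicc)
    return ChangeSelection(table=table, best=best, averaged=averaged,
                           failures=failures)


def polynomial_vertex(averaged: pd.DataFrame, var: str = "F"
                      ) -> float:
    """Stationary point -b1/(2 b2) of the averaged quadratic in one variable."""
    est = dict(zip(averaged["term"], averaged["estimate"]))
    b1, b2 = est.get(var, 0.0), est.get(var + "2", 0.0)
    if b2 == 0:
        raise ValueError(f"no quadratic curvature in {var}")
    return -b1 / (2.0 * b2)


def partial_effects(averaged: pd.DataFrame, points: pd.DataFrame,
                    var: str = "F", n_x: int = 50,
                    quantiles: tuple[float, ...] = (0.1, 0.5, 0.9)
                    ) -> pd.DataFrame:
    """Fitted change vs one climate variable at low/median/high values of the
    other, with delta-method bands from the averaged SEs (covariances between
    averaged coefficients are unavailable and taken as zero)."""
    est = dict(zip(averaged["term"], averaged["estimate"]))
    ses = dict(zip(averaged["term"], averaged["se"]))
    xcol = "prop_dffd" if var == "F" else "prop_dprecip"
    ocol = "prop_dprecip" if var == "F" else "prop_dffd"
    xs = np.linspace(points[xcol].min(), points[xcol].max(), n_x)
    rows = []
    for q in quantiles:
        o = float(points[ocol].quantile(q))
        for x in xs:
            f, p = (x, o) if var == "F" else (o, x)
            basis = {"intercept": 1.0, "F": f, "F2": f * f, "P": p,
                     "P2": p * p, "F:P": f * p}
            fit = sum(est.get(t, 0.0) * b for t, b in basis.items())
            var_fit = sum((ses.get(t, 0.0) * b) ** 2
                          for t, b in basis.items())
            sd = np.sqrt(var_fit)
            rows.append({"conditioning_quantile": q, "x": x, "fitted": fit,
                         "lo": fit - Z95 * sd, "hi": fit + Z95 * sd})
    return pd.DataFrame(rows)
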