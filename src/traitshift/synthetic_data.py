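"""Synthetic specimen records and decadal climate grids with known truth.

Emulates the statistical structure the downstream analysis assumes for a
wide-ranging, explosively breeding anuran sampled by museum collections over
a century:

* decadal climate fields (temperature, precipitation, frost-free days) on a
  5-arc-minute grid, smooth with a dominant latitudinal gradient;
  temperature and FFD share a latent gradient field and are calibrated to a
  target cell-wise correlation (default 0.87);
* a post-cutoff additive warming shift;
* log body size (snout-vent length) and breeding Julian day driven linearly
  by centered/scaled FFD and precipitation (sex-specific size coefficients),
  with a collection-year random intercept and spatially autocorrelated
  residuals (exponential correlogram);
* a fraction of collection dates planted far outside the breeding window
  (nonbreeding contaminants for the season filter to find).

Every draw is reproducible from (params, seed); the exact coefficients,
noise components and flags used are returned as :class:`GroundTruth`.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .climate_layers import (
    ClimateStack,
    ScaleTransform,
    extract_records,
    scale_record_climate,
)
from .grids import Grid, write_ascii_grid

FEMALE_FRACTION = 484 / 1264  # observed sex ratio of the mature-specimen dataset

DEFAULT_DECADES = [f"{d + 1}-{d + 10}" for d in range(1900, 2000, 10)]


@dataclass
class SynthParams:
    """Ground-truth parameters of the synthetic study system.

    Coefficients apply to centered/scaled predictors: ``(intercept, ffd,
    precip, ffd:precip)`` for log-SVL and ``(intercept, ffd, precip)`` for
    Julian day. Defaults mirror the magnitudes estimated on the historic
    (pre-1960) museum data: size responses of a few percent per climate SD,
    breeding date tens of days earlier per FFD SD.
    """

    grid_shape: tuple[int, int] = (40, 60)
    cell_size: float = 5 / 60
    lat_min: float = 40.0
    lon_min: float = -80.0
    decades: list[str] = field(default_factory=lambda: list(DEFAULT_DECADES))
    cutoff_year: int = 1960
    beta_size_f: tuple[float, float, float, float] = (3.85, 0.0, 0.112, 0.045)
    beta_size_m: tuple[float, float, float, float] = (3.78, 0.041, 0.008, -0.004)
    beta_phen: tuple[float, float, float] = (120.0, -42.4, -1.22)
    sigma_year_size: float = 0.05
    sigma_resid_size: float = 0.08
    sigma_year_phen: float = 6.0
    sigma_resid_phen: float = 15.0
    spatial_range: float = 2.0
    climate_shift: dict[str, float] = field(
        default_factory=lambda: {"temperature": 1.2, "ffd": 12.0,
                                 "precipitation": 60.0})
    temp_ffd_target_r: float = 0.87
    n_records: dict[str, int] = field(
        default_factory=lambda: {"pre": 679, "post": 585})
    contaminant_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError("grid_shape must be positive")
        if not 0 <= self.contaminant_frac < 0.5:
            raise ValueError("contaminant_frac must be in [0, 0.5)")
        for name in ("sigma_year_size", "sigma_resid_size",
                     "sigma_year_phen", "sigma_resid_phen", "spatial_range"):
            if getattr(self, name) < 0 or (
                    name == "spatial_range" and self.spatial_range <= 0):
                raise ValueError(f"{name} must be positive")
        if abs(self.temp_ffd_target_r) >= 1:
            raise ValueError("temp_ffd_target_r must satisfy |r| < 1")
        ends = [int(d.split("-")[1]) for d in self.decades]
        starts = [int(d.split("-")[0]) for d in self.decades]
        for a, b in zip(ends[:-1], starts[1:]):
            if b != a + 1:
                raise ValueError("decades must partition the study interval")

    @property
    def grid(self) -> Grid:
        return Grid(nrows=self.grid_shape[0], ncols=self.grid_shape[1],
                    lat_min=self.lat_min, lon_min=self.lon_min,
                    cell_size=self.cell_size)

    def years_in_period(self, period: str) -> list[int]:
        first = int(self.decades[0].split("-")[0])
        last = int(self.decades[-1].split("-")[1])
        if period == "pre":
            return list(range(first, self.cutoff_year + 1))
        return list(range(self.cutoff_year + 1, last + 1))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma_cells: float = 4.0) -> np.ndarray:
    """Unit-variance, zero-mean Gaussian-filtered white noise."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells,
                        mode="reflect")
    return (f - f.mean()) / f.std()


def _standardize(arr: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = arr[mask]
    return (arr - vals.mean()) / vals.std()


def elliptical_mask(shape: tuple[int, int]) -> np.ndarray:
    """Default range mask: an ellipse inscribed in the grid (~70% of cells)."""
    nr, nc = shape
    r, c = np.mgrid[0:nr, 0:nc]
    return (((r - (nr - 1) / 2) / (0.48 * nr)) ** 2
            + ((c - (nc - 1) / 2) / (0.48 * nc)) ** 2) <= 1.0


def gen_dem(params: SynthParams) -> np.ndarray:
    """Smooth synthetic digital elevation model (meters), >= 0."""
    rng = np.random.default_rng([params.seed, 11])
    shape = params.grid_shape
    dem = 450 + 320 * _smooth_field(rng, shape, 5.0) + 180 * _smooth_field(
        rng, shape, 2.5)
    return np.clip(dem, 0.0, None)


def gen_climate_stack(params: SynthParams) -> ClimateStack:
    """Decadal rasters of temperature, precipitation and frost-free days.

    Temperature and FFD are built from one latent latitudinal-gradient field
    plus independent smooth noise; the noise SD is calibrated iteratively so
    the cell-wise correlation of the two pre-cutoff mean fields is within
    +/-0.02 of ``temp_ffd_target_r``. Post-cutoff decades receive the
    additive ``climate_shift``.
    """
    r_target = params.temp_ffd_target_r
    if abs(r_target) >= 1:
        raise ValueError("infeasible target correlation: |r| must be < 1")
    grid = params.grid
    shape = params.grid_shape
    mask = elliptical_mask(shape)
    rng = np.random.default_rng([params.seed, 7])
    lat2d, _ = grid.cell_centers()

    gradient = _standardize(-lat2d + 0.25 * _smooth_field(rng, shape, 6.0),
                            mask)
    noise_t = _smooth_field(rng, shape, 3.0)
    noise_f = _smooth_field(rng, shape, 3.0)
    precip_latent = _standardize(
        0.35 * gradient + _smooth_field(rng, shape, 4.0), mask)

    # calibrate shared-latent vs independent-noise mix to the target corr
    s = np.sqrt(max(1.0 / abs(r_target) - 1.0, 1e-6))
    for _ in range(50):
        t_field = _standardize(gradient + s * noise_t, mask)
        f_field = _standardize(np.sign(r_target) * gradient + s * noise_f,
                               mask)
        r_emp = float(np.corrcoef(t_field[mask], f_field[mask])[0, 1])
        if abs(r_emp - r_target) <= 0.02:
            break
        ratio = (1.0 / abs(r_target) - 1.0) / max(1.0 / abs(r_emp) - 1.0, 1e-9)
        s *= np.sqrt(max(ratio, 0.05))

    base = {
        "temperature": 8.0 + 7.0 * t_field,
        "ffd": 170.0 + 45.0 * f_field,
        "precipitation": np.clip(1000.0 + 250.0 * precip_latent, 100.0, None),
    }
    anomaly_sd = {"temperature": 0.3, "ffd": 2.0, "precipitation": 25.0}
    values: dict[str, dict[str, np.ndarray]] = {v: {} for v in base}
    for dec in params.decades:
        start = int(dec.split("-")[0])
        post = start > params.cutoff_year
        for var in base:
            layer = base[var] + anomaly_sd[var] * _smooth_field(rng, shape, 4.0)
            if post:
                layer = layer + params.climate_shift.get(var, 0.0)
            values[var][dec] = layer
    return ClimateStack(grid=grid, decades=list(params.decades),
                        values=values, mask=mask)


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the noiseless generative process."""

    params: SynthParams
    transforms: dict[str, ScaleTransform]
    year_effects_size: dict[int, float]
    year_effects_phen: dict[int, float]
    records: pd.DataFrame  # linear predictors, noise components, flags

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": {k: v for k, v in asdict(self.params).items()},
            "transforms": {k: asdict(v) for k, v in self.transforms.items()},
            "year_effects_size": {str(k): v for k, v
                                  in self.year_effects_size.items()},
            "year_effects_phen": {str(k): v for k, v
                                  in self.year_effects_phen.items()},
            "records": self.records.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, default=list))

    def trait_surface(self, stack: ClimateStack, response: str,
                      period: str) -> np.ndarray:
        """Noiseless per-pixel trait surface from the period-mean climate."""
        p = self.params
        ffd = stack.period_mean("ffd", p.cutoff_year, period)
        pr = stack.period_mean("precipitation", p.cutoff_year, period)
        zf = self.transforms["ffd"].apply(ffd)
        zp = self.transforms["precipitation"].apply(pr)
        if response == "julian_day":
            b = p.beta_phen
            surf = b[0] + b[1] * zf + b[2] * zp
        else:
            b = p.beta_size_f if response == "log_svl_female" else p.beta_size_m
            surf = b[0] + b[1] * zf + b[2] * zp + b[3] * zf * zp
        return np.where(stack.mask, surf, np.nan)


def _exp_corr_chol(lat: np.ndarray, lon: np.ndarray, rho: float,
                   jitter: float = 1e-8) -> np.ndarray:
    pts = np.column_stack([lat, lon])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    c = np.exp(-d / rho)
    c[np.diag_indices_from(c)] += jitter
    return np.linalg.cholesky(c)


def gen_specimens(
    params: SynthParams, stack: ClimateStack
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw specimen records over the stack's mask; returns (table, truth).

    Records carry both traits (snout-vent length and collection date); the
    climate scaling used by the linear predictors is fitted on the
    pre-cutoff records, as the historic model fit would do.
    """
    if not stack.mask.any():
        raise ValueError("empty range mask: cannot place specimens")
    rng = np.random.default_rng([params.seed, 23])
    grid = stack.grid
    dem = gen_dem(params)
    rows_m, cols_m = np.nonzero(stack.mask)

    recs = []
    for period in ("pre", "post"):
        n = params.n_records[period]
        years = params.years_in_period(period)
        # every year in the period gets at least one record, rest uniform
        yr = np.concatenate([
            np.array(years), rng.choice(years, size=max(n - len(years), 0))
        ])[:n]
        rng.shuffle(yr)
        idx = rng.integers(0, len(rows_m), size=n)
        r, c = rows_m[idx], cols_m[idx]
        lat = grid.lat_min + (r + rng.random(n)) * grid.cell_size
        lon = grid.lon_min + (c + rng.random(n)) * grid.cell_size
        recs.append(pd.DataFrame({
            "period": period, "year": yr.astype(int),
            "lat": lat, "lon": lon, "elev_m": dem[r, c],
            "sex": np.where(rng.random(n) < FEMALE_FRACTION, "female", "male"),
        }))
    df = pd.concat(recs, ignore_index=True)
    df.insert(0, "id", [f"SYN{i:05d}" for i in range(len(df))])

    df = extract_records(stack, df)
    pre = df[df["period"] == "pre"]
    _, transforms = scale_record_climate(pre)
    df, _ = scale_record_climate(df, transforms)

    years_all = sorted(df["year"].unique())
    ye_size = {int(y): float(rng.normal(0, params.sigma_year_size))
               for y in years_all}
    ye_phen = {int(y): float(rng.normal(0, params.sigma_year_phen))
               for y in years_all}

    n = len(df)
    zf = df["scaled_ffd"].to_numpy()
    zp = df["scaled_precip"].to_numpy()
    female = (df["sex"] == "female").to_numpy()
    bf, bm, bp = params.beta_size_f, params.beta_size_m, params.beta_phen
    mu_size = np.where(
        female,
        bf[0] + bf[1] * zf + bf[2] * zp + bf[3] * zf * zp,
        bm[0] + bm[1] * zf + bm[2] * zp + bm[3] * zf * zp,
    )
    mu_phen = bp[0] + bp[1] * zf + bp[2] * zp

    chol = _exp_corr_chol(df["lat"].to_numpy(), df["lon"].to_numpy(),
                          params.spatial_range)
    resid_size = params.sigma_resid_size * (chol @ rng.standard_normal(n))
    resid_phen = params.sigma_resid_phen * (chol @ rng.standard_normal(n))
    yeff_size = df["year"].map(ye_size).to_numpy()
    yeff_phen = df["year"].map(ye_phen).to_numpy()

    log_svl = mu_size + yeff_size + resid_size
    jd_clean = mu_phen + yeff_phen + resid_phen

    n_contam = int(round(params.contaminant_frac * n))
    contam_idx = rng.choice(n, size=n_contam, replace=False)
    is_contam = np.zeros(n, dtype=bool)
    is_contam[contam_idx] = True
    # nonbreeding collections: >= 90 days after the local (latitude-band)
    # mean breeding day -- the breeding season is a property of the latitude,
    # so the contaminant window clears the whole band's breeding cluster
    band = np.floor(df["lat"].to_numpy())
    band_mu = pd.Series(mu_phen).groupby(band).transform("mean").to_numpy()
    jd = jd_clean.copy()
    jd[is_contam] = band_mu[is_contam] + rng.uniform(90, 210, size=n_contam)
    jd = np.clip(np.rint(jd), 1, 360).astype(int)

    dates = [dt.date(int(y), 1, 1) + dt.timedelta(days=int(d) - 1)
             for y, d in zip(df["year"], jd)]

    table = pd.DataFrame({
        "id": df["id"],
        "sex": df["sex"],
        "svl_mm": np.round(np.exp(log_svl) / 0.05) * 0.05,
        "date": [d.isoformat() for d in dates],
        "julian_day": jd,
        "lat": df["lat"],
        "lon": df["lon"],
        "elev_m": df["elev_m"],
        "year": df["year"],
    })
    truth_records = df[["id", "period", "ffd", "temperature", "precipitation",
                        "scaled_ffd", "scaled_precip"]].copy()
    truth_records["mu_log_svl"] = mu_size
    truth_records["mu_julian"] = mu_phen
    truth_records["resid_size"] = resid_size
    truth_records["resid_phen"] = resid_phen
    truth_records["year_effect_size"] = yeff_size
    truth_records["year_effect_phen"] = yeff_phen
    truth_records["is_contaminant"] = is_contam
    truth = GroundTruth(params=params, transforms=transforms,
                        year_effects_size=ye_size, year_effects_phen=ye_phen,
                        records=truth_records)
    return table, truth


def write_specimens(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_dem(params: SynthParams, path: str | Path) -> None:
    write_ascii_grid(path, params.grid, gen_dem(params))


def gen_gls_point_set(
    seed: int,
    n: int = 484,
    beta: dict[str, float] | None = None,
    noise_scale: float = 1.5,
    spatial_range: float = 1.0,
) -> pd.DataFrame:
    """Change-GLS point set from a known polynomial surface.

    Trait change delta at each of n points is a quadratic in proportional
    FFD change (F) and proportional precipitation change (P) plus spatially
    correlated noise whose SD is proportional to the point's pooled SE
    (emulating the heteroscedastic map uncertainty the weights encode).
    Default coefficients follow the magnitudes of the published female
    body-size change model.
    """
    beta = beta or {"intercept": 0.0, "F": 23.87, "F2": -76.39, "P": 11.67,
                    "P2": 9.95, "F:P": -98.70}
    rng = np.random.default_rng(seed)
    lon = rng.uniform(-80, -75, n)
    lat = rng.uniform(40, 43, n)
    F = rng.normal(0.07, 0.05, n)
    P = rng.normal(0.05, 0.08, n)
    mu = (beta["intercept"] + beta["F"] * F + beta["F2"] * F**2
          + beta["P"] * P + beta["P2"] * P**2 + beta["F:P"] * F * P)
    pts = np.column_stack([lon, lat])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    L = np.linalg.cholesky(np.exp(-d / spatial_range) + 1e-8 * np.eye(n))
    se = rng.uniform(0.5, 2.0, n)
    noise = noise_scale * se * (L @ rng.standard_normal(n))
    return pd.DataFrame({"lat": lat, "lon": lon, "delta": mu + noise,
                         "pooled_se": se, "prop_dffd": F, "prop_dprecip": P})


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def gen_change_scenario(
    n_per_period: int,
    delta: float,
    shift_box: tuple[float, float, float, float],
    seed: int,
    params: SynthParams | None = None,
    noise_sd: float = 5.0,
    taper: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired pre/post record sets with a known subregional trait shift.

    The trait is a smooth deterministic surface of (lat, lon, elev) plus iid
    noise. Post-period records gain ``delta`` inside ``shift_box``
    (lat_min, lat_max, lon_min, lon_max): exactly ``delta`` in the box core,
    smoothly tapered to exactly zero at the box edge over ``taper`` degrees
    (a climate-driven subregional shift has smooth edges; a discontinuity
    would be unresolvable by any smooth surface estimator). The returned
    truth carries the per-pixel shift weight so tests can label core /
    no-change / transition pixels.
    """
    params = params or SynthParams(seed=seed)
    rng = np.random.default_rng([seed, 41])
    grid = params.grid
    dem = gen_dem(params)
    mask = elliptical_mask(params.grid_shape)
    rows_m, cols_m = np.nonzero(mask)

    def surface(lat, lon, elev):
        return (120.0 - 3.0 * (lat - grid.lat_min)
                + 0.8 * (lon - grid.lon_min) - 0.01 * elev)

    la0, la1, lo0, lo1 = shift_box

    def shift_weight(lat, lon):
        if la1 <= la0 or lo1 <= lo0:
            return np.zeros_like(np.asarray(lat, dtype=float))
        tw = max(taper, 1e-12)
        w_lat = np.minimum(_smoothstep((lat - la0) / tw),
                           _smoothstep((la1 - lat) / tw))
        w_lon = np.minimum(_smoothstep((lon - lo0) / tw),
                           _smoothstep((lo1 - lon) / tw))
        inside = (la0 <= lat) & (lat < la1) & (lo0 <= lon) & (lon < lo1)
        return np.where(inside, w_lat * w_lon, 0.0)

    out = []
    for period in ("pre", "post"):
        idx = rng.integers(0, len(rows_m), size=n_per_period)
        r, c = rows_m[idx], cols_m[idx]
        lat = grid.lat_min + (r + rng.random(n_per_period)) * grid.cell_size
        lon = grid.lon_min + (c + rng.random(n_per_period)) * grid.cell_size
        elev = dem[r, c]
        y = surface(lat, lon, elev) + rng.normal(0, noise_sd, n_per_period)
        if period == "post":
            y = y + delta * shift_weight(lat, lon)
        out.append(pd.DataFrame({"lat": lat, "lon": lon, "elev_m": elev,
                                 "y": y, "period": period}))
    lat2d, lon2d = grid.cell_centers()
    truth = {
        "delta": delta,
        "shift_box": shift_box,
        "surface": np.where(mask, surface(lat2d, lon2d, dem), np.nan),
        "shift_weight": shift_weight,
        "dem": dem,
        "mask": mask,
        "grid": grid,
    }
    return out[0], out[1], truth
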