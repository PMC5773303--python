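"""Bootstrap thin-plate-spline trait maps and CI-overlap change detection.

For each period (pre/post cutoff) a trait (body size or breeding Julian
day) is smoothed over (latitude, longitude, elevation) with a thin plate
spline and mapped onto the range grid. Case-resampling the records B times
(default 100) yields a per-pixel mean map, 2.5/97.5 percentile confidence
bounds and a bootstrap SD ("pooled SE"). A pixel changed significantly
between periods exactly when its two bootstrap CIs are disjoint; elsewhere
change is taken as zero. The spline uses the 3-D order-2 kernel
phi(r) = -r (affine null space); the smoothing parameter is selected per
fit by generalized cross-validation, V(lambda) = n RSS / (n - tr A)^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import Grid, write_ascii_grid


@dataclass
class TPSModel:
    """Fitted 3-D thin plate spline y ~ f(lat, lon, elev)."""

    knots: np.ndarray          # original-unit training coordinates (n, 3)
    rbf_coeffs: np.ndarray     # c, orthogonal to the affine space (T'c = 0)
    affine_coeffs: np.ndarray  # d = (intercept, 3 linear terms), std units
    lam: float
    gcv: float
    std_mean: np.ndarray
    std_sd: np.ndarray
    fitted: np.ndarray
    r2: float

    def predict(self, coords: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(coords, dtype=float) - self.std_mean) / self.std_sd
        Ks = -np.sqrt(
            ((Xs[:, None, :] - self._knots_std[None, :, :]) ** 2).sum(-1))
        Ts = np.column_stack([np.ones(len(Xs)), Xs])
        return Ks @ self.rbf_coeffs + Ts @ self.affine_coeffs

    @property
    def _knots_std(self) -> np.ndarray:
        return (self.knots - self.std_mean) / self.std_sd


def _tps_system(Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = -np.sqrt(((Xs[:, None, :] - Xs[None, :, :]) ** 2).sum(-1))
    T = np.column_stack([np.ones(len(Xs)), Xs])
    return K, T


def fit_tps(coords: np.ndarray, y: np.ndarray,
            lam: float | str = "auto",
            weights: np.ndarray | None = None) -> TPSModel:
    """Penalized thin plate spline: solves [K + n*lam*I, T; T', 0][c;d]=[y;0].

    Coordinates are standardized internally to unit SD so that elevation in
    meters does not dominate degrees. ``lam='auto'`` minimizes the GCV
    score over a log-spaced grid; ``lam=0`` interpolates exactly.

    Optional ``weights`` are case weights (e.g. bootstrap resample
    frequencies): the criterion becomes sum_i w_i (y_i - f(x_i))^2 plus the
    bending penalty. Whitening by sqrt(w) reduces the weighted system to
    the unweighted eigenstructure, with n = sum(w) in the penalty and GCV.
    """
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 8:
        raise ValueError("need at least 8 points for a 3-D spline")
    if weights is None:
        w = np.ones(len(y))
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("case weights must be positive")
    n = float(w.sum())
    sw = np.sqrt(w)
    mean, sd = coords.mean(0), coords.std(0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (coords - mean) / sd
    K, T = _tps_system(Xs)
    if np.linalg.matrix_rank(T) < 4:
        raise ValueError("coplanar point configuration: affine part is "
                         "rank-deficient; perturb the coordinates")
    Kw = K * np.outer(sw, sw)
    Tw = T * sw[:, None]
    yw = y * sw
    Q, R = np.linalg.qr(Tw, mode="complete")
    Q1, Q2 = Q[:, :4], Q[:, 4:]
    R1 = R[:4]
    B = Q2.T @ Kw @ Q2
    B = 0.5 * (B + B.T)
    evals, U = np.linalg.eigh(B)
    # phi(r) = -r is conditionally positive definite on the affine-orthogonal
    # space; tiny/negative eigenvalues only arise from near-duplicate points
    floor = 1e-10 * max(abs(evals).max(), 1.0)
    evals = np.clip(evals, floor, None)
    ytil = U.T @ (Q2.T @ yw)

    def gcv_score(lmb: float) -> float:
        w_denom = evals + n * lmb
        rss = float(((n * lmb) ** 2) * np.sum((ytil / w_denom) ** 2))
        tr_imA = n * lmb * float(np.sum(1.0 / w_denom))
        if tr_imA <= 0:
            return np.inf
        return n * rss / tr_imA**2

    if lam == "auto":
        scale = float(evals.mean()) / n
        grid = scale * np.logspace(-8, 3, 60)
        scores = np.array([gcv_score(g) for g in grid])
        lam_v = float(grid[int(np.argmin(scores))])
        gcv = float(scores.min())
    else:
        lam_v = float(lam)
        gcv = gcv_score(lam_v) if lam_v > 0 else np.nan
    u = Q2 @ (U @ (ytil / (evals + n * lam_v)))
    c = sw * u
    # Tw d = yw - (Kw + n lam I) u, solved in the Q1 basis
    d = np.linalg.solve(R1, Q1.T @ (yw - Kw @ u - n * lam_v * u))
    fitted = K @ c + T @ d
    ybar = float(np.average(y, weights=w))
    ss_tot = float(w @ (y - ybar) ** 2)
    ss_res = float(w @ (y - fitted) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TPSModel(knots=coords, rbf_coeffs=c, affine_coeffs=d, lam=lam_v,
                    gcv=gcv, std_mean=mean, std_sd=sd, fitted=fitted, r2=r2)


@dataclass
class MapEnsemble:
    """Bootstrap prediction maps over a fixed set of grid points."""

    grid_coords: np.ndarray  # (m, 3): lat, lon, elev of predicted pixels
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    pooled_se: np.ndarray
    r2_mean: float
    mspe: float
    B: int
    seed: int
    n_redraws: int = 0
    grid: Grid | None = None
    mask: np.ndarray | None = None

    def rasterize(self, values: np.ndarray) -> np.ndarray:
        if self.grid is None or self.mask is None:
            raise ValueError("ensemble carries no raster georeference")
        out = np.full(self.grid.shape, np.nan)
        out[self.mask] = values
        return out

    def write(self, outdir: str | Path, prefix: str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("mean", "lo", "hi", "pooled_se"):
            write_ascii_grid(outdir / f"{prefix}_{name}.asc", self.grid,
                             self.rasterize(getattr(self, name)))
        (outdir / f"{prefix}_diagnostics.json").write_text(json.dumps({
            "r2_mean": self.r2_mean, "mspe": self.mspe, "B": self.B,
            "seed": self.seed, "n_redraws": self.n_redraws,
        }))


def grid_prediction_coords(grid: Grid, mask: np.ndarray, dem: np.ndarray
                           ) -> np.ndarray:
    """(m, 3) lat/lon/elev coordinates of masked cell centers."""
    lat2d, lon2d = grid.cell_centers()
    m = np.asarray(mask, dtype=bool)
    return np.column_stack([lat2d[m], lon2d[m], dem[m]])


def bootstrap_maps(
    coords: np.ndarray,
    y: np.ndarray,
    grid_coords: np.ndarray,
    B: int = 100,
    seed: int = 0,
    lam: float | str = "auto",
    grid: Grid | None = None,
    mask: np.ndarray | None = None,
    max_redraws: int = 10,
) -> MapEnsemble:
    """B case-resampled spline fits, aggregated per pixel.

    Per replicate: resample records with replacement (redrawn, up to
    ``max_redraws`` times, if fewer than 8 unique points land in the
    resample), fit with GCV-selected smoothing, record the in-sample r2 and
    the mean squared prediction error on that replicate's out-of-bag
    records, and predict every grid point. Replicate b is seeded from
    (seed, b), so ensembles are reproducible and replicates independent.
    """
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 records per period")
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    preds = np.empty((B, len(grid_coords)))
    r2s = np.empty(B)
    mspes = np.full(B, np.nan)
    n_redraws = 0
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            uniq, counts = np.unique(idx, return_counts=True)
            if len(uniq) >= 8:
                try:
                    # duplicates collapse to frequency weights: GCV treats a
                    # k-fold repeat as one point weighted k, not as k
                    # noise-free replicates
                    model = fit_tps(coords[uniq], y[uniq], lam=lam,
                                    weights=counts)
                    break
                except ValueError:
                    pass
            n_redraws += 1
        else:
            raise RuntimeError(f"replicate {b}: no usable resample after "
                               f"{max_redraws} redraws")
        r2s[b] = model.r2
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) > 0:
            mspes[b] = float(np.mean((y[oob] - model.predict(coords[oob])) ** 2))
        preds[b] = model.predict(grid_coords)
    return MapEnsemble(
        grid_coords=grid_coords,
        mean=preds.mean(0),
        lo=np.percentile(preds, 2.5, axis=0),
        hi=np.percentile(preds, 97.5, axis=0),
        pooled_se=preds.std(0, ddof=1),
        r2_mean=float(r2s.mean()),
        mspe=float(np.nanmean(mspes)),
        B=B, seed=seed, n_redraws=n_redraws, grid=grid, mask=mask,
    )


@dataclass
class ChangeMap:
    """Post-minus-pre trait change with CI-overlap significance."""

    grid_coords: np.ndarray
    delta: np.ndarray
    significant: np.ndarray
    delta_masked: np.ndarray
    pooled_se: np.ndarray  # sqrt(se_pre^2 + se_post^2), for GLS weighting
    grid: Grid | None = None
    mask: np.ndarray | None = None

    def rasterize(self, values: np.ndarray) -> np.ndarray:
        if self.grid is None or self.mask is None:
            raise ValueError("change map carries no raster georeference")
        out = np.full(self.grid.shape, np.nan)
        out[self.mask] = values
        return out

    def write(self, outdir: str | Path, prefix: str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        layers = {"delta": self.delta,
                  "significant": self.significant.astype(float),
                  "delta_masked": self.delta_masked,
                  "pooled_se": self.pooled_se}
        for name, vals in layers.items():
            write_ascii_grid(outdir / f"{prefix}_{name}.asc", self.grid,
                             self.rasterize(vals))


def change_map(pre: MapEnsemble, post: MapEnsemble) -> ChangeMap:
    """Per-pixel change: significant exactly where the two CIs are disjoint."""
    if pre.grid_coords.shape != post.grid_coords.shape or not np.allclose(
            pre.grid_coords, post.grid_coords):
        raise ValueError("pre and post ensembles are on different grids")
    delta = post.mean - pre.mean
    significant = (pre.hi < post.lo) | (post.hi < pre.lo)
    return ChangeMap(
        grid_coords=pre.grid_coords,
        delta=delta,
        significant=significant,
        delta_masked=np.where(significant, delta, 0.0),
        pooled_se=np.sqrt(pre.pooled_se**2 + post.pooled_se**2),
        grid=pre.grid, mask=pre.mask,
    )
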