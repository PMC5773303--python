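"""Decadal climate rasters: extraction, scaling, collinearity and change.

A :class:`ClimateStack` holds decadal mean rasters of three variables —
temperature (degC), precipitation (mm) and frost-free days (FFD, days) — on a
shared lat/lon grid with a range mask. Operations here assign climate to
specimen records (nearest containing cell, no interpolation), center/scale
predictors, compute correlation t statistics and variance inflation factors,
and build per-cell proportional-change rasters between a pre- and
post-cutoff period.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid, read_ascii_grid, write_ascii_grid

VARIABLES = ("temperature", "precipitation", "ffd")


def parse_decade(label: str) -> tuple[int, int]:
    """'1901-1910' -> (1901, 1910)."""
    start, end = label.split("-")
    return int(start), int(end)


@dataclass
class ClimateStack:
    """Decadal climate rasters sharing one grid and range mask.

    ``values[var][decade]`` is a south-up 2-D array; cells outside ``mask``
    are ignored (may hold NaN). No NaN is permitted inside the mask.
    """

    grid: Grid
    decades: list[str]
    values: dict[str, dict[str, np.ndarray]]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        for var in VARIABLES:
            if var not in self.values:
                raise ValueError(f"missing variable {var!r}")
            for dec in self.decades:
                arr = self.values[var][dec]
                if arr.shape != self.grid.shape:
                    raise ValueError(f"layer {var}/{dec} shape mismatch")
                if np.isnan(arr[self.mask]).any():
                    raise ValueError(f"NaN inside mask in layer {var}/{dec}")

    def decade_of(self, year: int) -> str:
        for dec in self.decades:
            start, end = parse_decade(dec)
            if start <= year <= end:
                return dec
        raise ValueError(f"year {year} not covered by decades {self.decades}")

    def decades_in_period(self, cutoff_year: int, period: str) -> list[str]:
        """Decade labels whose interval ends at/before (pre) or starts after (post)."""
        out = []
        for dec in self.decades:
            start, end = parse_decade(dec)
            if period == "pre" and end <= cutoff_year:
                out.append(dec)
            elif period == "post" and start > cutoff_year:
                out.append(dec)
        return out

    def period_mean(self, var: str, cutoff_year: int, period: str) -> np.ndarray:
        decs = self.decades_in_period(cutoff_year, period)
        if not decs:
            raise ValueError(f"no decades on the {period!r} side of {cutoff_year}")
        return np.mean([self.values[var][d] for d in decs], axis=0)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(outdir / "mask.asc", self.grid, self.mask.astype(float))
        for var in VARIABLES:
            for dec in self.decades:
                write_ascii_grid(
                    outdir / f"{var}_{dec}.asc", self.grid,
                    self.values[var][dec], mask=self.mask,
                )
        (outdir / "stack.json").write_text(json.dumps({"decades": self.decades}))

    @classmethod
    def read(cls, indir: str | Path) -> "ClimateStack":
        indir = Path(indir)
        decades = json.loads((indir / "stack.json").read_text())["decades"]
        grid, mask_arr = read_ascii_grid(indir / "mask.asc")
        mask = np.nan_to_num(mask_arr, nan=0.0) > 0.5
        values: dict[str, dict[str, np.ndarray]] = {v: {} for v in VARIABLES}
        for var in VARIABLES:
            for dec in decades:
                g, arr = read_ascii_grid(indir / f"{var}_{dec}.asc")
                if not g.same_as(grid):
                    raise ValueError(f"grid mismatch in {var}_{dec}.asc")
                values[var][dec] = arr
        return cls(grid=grid, decades=decades, values=values, mask=mask)


class ExtractionError(ValueError):
    """A record's location falls outside the stack's range mask."""


def extract_at(stack: ClimateStack, lat: float, lon: float, decade: str,
               record_id: str | None = None) -> tuple[float, float, float]:
    """(ffd, temperature, precipitation) of the cell containing the point."""
    try:
        row, col = stack.grid.cell_of(lat, lon)
    except ValueError as exc:
        raise ExtractionError(f"record {record_id}: {exc}") from exc
    if not stack.mask[row, col]:
        raise ExtractionError(
            f"record {record_id}: point ({lat}, {lon}) outside range mask"
        )
    return (
        float(stack.values["ffd"][decade][row, col]),
        float(stack.values["temperature"][decade][row, col]),
        float(stack.values["precipitation"][decade][row, col]),
    )


def extract_records(stack: ClimateStack, records: pd.DataFrame) -> pd.DataFrame:
    """Per-record climate for each record's collection decade.

    Returns a copy of ``records`` with ffd/temperature/precipitation columns.
    """
    vals = np.empty((len(records), 3))
    for i, rec in enumerate(records.itertuples()):
        dec = stack.decade_of(int(rec.year))
        vals[i] = extract_at(stack, rec.lat, rec.lon, dec, record_id=str(rec.id))
    out = records.copy()
    out[["ffd", "temperature", "precipitation"]] = vals
    return out


@dataclass(frozen=True)
class ScaleTransform:
    """Stored center/scale parameters of a fitted z-transform."""

    mean: float
    sd: float

    def apply(self, x: np.ndarray | float) -> np.ndarray | float:
        return (x - self.mean) / self.sd


def center_scale(x: np.ndarray) -> tuple[np.ndarray, ScaleTransform]:
    """z-scores with sample SD (n-1); raises on constant input."""
    x = np.asarray(x, dtype=float)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("cannot scale a constant (or length-1) column")
    tr = ScaleTransform(mean=mean, sd=sd)
    return tr.apply(x), tr


def scale_record_climate(
    records: pd.DataFrame,
    transforms: dict[str, ScaleTransform] | None = None,
) -> tuple[pd.DataFrame, dict[str, ScaleTransform]]:
    """Add scaled_ffd / scaled_precip columns; fit or re-use the transforms."""
    out = records.copy()
    if transforms is None:
        z_f, tr_f = center_scale(out["ffd"].to_numpy())
        z_p, tr_p = center_scale(out["precipitation"].to_numpy())
        transforms = {"ffd": tr_f, "precipitation": tr_p}
        out["scaled_ffd"], out["scaled_precip"] = z_f, z_p
    else:
        out["scaled_ffd"] = transforms["ffd"].apply(out["ffd"].to_numpy())
        out["scaled_precip"] = transforms["precipitation"].apply(
            out["precipitation"].to_numpy())
    return out, transforms


def pearson_t(r: float, df: int) -> float:
    """t statistic of a Pearson correlation: t = r * sqrt(df / (1 - r^2))."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    return r * np.sqrt(df / (1.0 - r * r))


def correlation_diagnostics(records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r and t (df = n - 2) among the three climate columns."""
    cols = ["temperature", "ffd", "precipitation"]
    n = len(records)
    rows = []
    for i in range(3):
        for j in range(i + 1, 3):
            r = float(np.corrcoef(records[cols[i]], records[cols[j]])[0, 1])
            rows.append({"var1": cols[i], "var2": cols[j], "r": r,
                         "df": n - 2, "t": pearson_t(r, n - 2)})
    return pd.DataFrame(rows)


def vif(predictors: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    R^2_j comes from regressing column j on the remaining columns plus an
    intercept. Perfect collinearity yields inf, not an exception.
    """
    X = np.asarray(predictors, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two predictor columns")
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        ss_res = float(np.sum(resid**2))
        if ss_tot <= 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class ChangeRasters:
    """Per-variable proportional change (post mean - pre mean) / pre mean."""

    grid: Grid
    change: dict[str, np.ndarray]
    mask: np.ndarray
    n_zero_pre: dict[str, int] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for var, arr in self.change.items():
            write_ascii_grid(outdir / f"prop_change_{var}.asc", self.grid,
                             arr, mask=self.mask)


def proportional_change(stack: ClimateStack, cutoff_year: int) -> ChangeRasters:
    """Proportional climate change per cell relative to the pre-cutoff mean.

    Cells where the pre-period mean is zero are removed from the joint mask
    and counted per variable.
    """
    mask = stack.mask.copy()
    change: dict[str, np.ndarray] = {}
    n_zero: dict[str, int] = {}
    for var in VARIABLES:
        pre = stack.period_mean(var, cutoff_year, "pre")
        post = stack.period_mean(var, cutoff_year, "post")
        zero_pre = (pre == 0) & stack.mask
        n_zero[var] = int(zero_pre.sum())
        mask &= ~zero_pre
        with np.errstate(divide="ignore", invalid="ignore"):
            change[var] = (post - pre) / pre
    for var in VARIABLES:
        change[var] = np.where(mask, change[var], np.nan)
    return ChangeRasters(grid=stack.grid, change=change, mask=mask,
                         n_zero_pre=n_zero)
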