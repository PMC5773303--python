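"""Specimen ingestion, validation and breeding-season separation.

Museum collections of explosive breeders are made mostly during the short
spring breeding window, so the Julian day of collection proxies breeding
date — except for a minority of records collected later in the year. Within
each degree-of-latitude band, a two-cluster 1-D k-means on Julian day
separates the breeding cluster (earlier center) from nonbreeding
collections; nonbreeding records are dropped from phenology analyses only
and retained for body-size analyses.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["id", "sex", "svl_mm", "date", "lat", "lon", "elev_m",
                    "year"]


class FormatError(ValueError):
    """Input file is missing required structure."""


@dataclass
class IngestReport:
    n_read: int = 0
    n_kept: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def _julian_day(date: dt.date) -> int:
    return date.timetuple().tm_yday


def read_specimens(path: str | Path, cutoff_year: int = 1960
                   ) -> tuple[pd.DataFrame, IngestReport]:
    """Read and validate a specimen CSV.

    Rows with unparseable dates, coordinates out of range, or nonpositive
    SVL are rejected individually with a logged reason; a missing required
    column is a format error. The returned table adds ``julian_day``
    (computed from the date, leap years honored) and ``period``
    (pre iff year <= cutoff_year).
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    report = IngestReport(n_read=len(df))
    keep = np.ones(len(df), dtype=bool)
    julian = np.zeros(len(df), dtype=int)
    for i, row in enumerate(df.itertuples()):
        rid = str(row.id)
        try:
            date = dt.date.fromisoformat(str(row.date))
        except (ValueError, TypeError):
            keep[i] = False
            report.dropped.append((rid, f"unparseable date {row.date!r}"))
            continue
        if not np.isfinite(row.lat) or not -90 <= row.lat <= 90:
            keep[i] = False
            report.dropped.append((rid, "lat out of range"))
            continue
        if not np.isfinite(row.lon) or not -180 <= row.lon <= 180:
            keep[i] = False
            report.dropped.append((rid, "lon out of range"))
            continue
        if not np.isfinite(row.svl_mm) or row.svl_mm <= 0:
            keep[i] = False
            report.dropped.append((rid, "nonpositive SVL"))
            continue
        if date.year != int(row.year):
            keep[i] = False
            report.dropped.append((rid, "date/year mismatch"))
            continue
        if str(row.sex) not in ("female", "male"):
            keep[i] = False
            report.dropped.append((rid, f"unknown sex {row.sex!r}"))
            continue
        julian[i] = _julian_day(date)
    out = df.loc[keep].copy()
    out["julian_day"] = julian[keep]
    out["year"] = out["year"].astype(int)
    out["period"] = np.where(out["year"] <= cutoff_year, "pre", "post")
    report.n_kept = len(out)
    return out.reset_index(drop=True), report


def kmeans2_1d(values: np.ndarray) -> tuple[int, tuple[float, float]]:
    """Exact 1-D 2-means: the optimal partition is a cut in sorted order.

    Returns (cut_index, (lower_center, upper_center)) where the lower
    cluster holds the ``cut_index`` smallest values. Deterministic and
    permutation-invariant: enumerates all n-1 sorted cuts and minimizes the
    within-cluster sum of squares (prefix-sum arithmetic, O(n) after sort).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 values for a 2-partition")
    csum = np.cumsum(x)
    csum2 = np.cumsum(x**2)
    k = np.arange(1, n)  # size of lower cluster
    sum_lo, sum_hi = csum[k - 1], csum[-1] - csum[k - 1]
    ss_lo = csum2[k - 1] - sum_lo**2 / k
    ss_hi = (csum2[-1] - csum2[k - 1]) - sum_hi**2 / (n - k)
    cut = int(k[np.argmin(ss_lo + ss_hi)])
    return cut, (float(x[:cut].mean()), float(x[cut:].mean()))


@dataclass
class SeasonSplit:
    """Breeding/nonbreeding partition with per-band cluster centers."""

    breeding: pd.DataFrame
    nonbreeding: pd.DataFrame
    band_centers: dict[float, tuple[float, float] | None]

    def to_table(self) -> pd.DataFrame:
        b = self.breeding.copy()
        b["season"] = "breeding"
        nb = self.nonbreeding.copy()
        nb["season"] = "nonbreeding"
        return pd.concat([b, nb], ignore_index=True)

    def write_report(self, path: str | Path) -> None:
        payload = {
            "n_breeding": len(self.breeding),
            "n_nonbreeding": len(self.nonbreeding),
            "band_centers": {str(k): v for k, v in self.band_centers.items()},
        }
        Path(path).write_text(json.dumps(payload))


def split_breeding(records: pd.DataFrame, band_width: float = 1.0,
                   separation_days: float = 45.0,
                   min_band_size: int = 4) -> SeasonSplit:
    """Separate breeding from nonbreeding collections per latitude band.

    Within each band of ``band_width`` degrees, the exact two-cluster 1-D
    k-means of Julian day is computed; if the band has at least
    ``min_band_size`` records and the two centers are more than
    ``separation_days`` apart, the later cluster is labeled nonbreeding
    (explosive breeders: the breeding cluster is the earlier one).
    Degenerate bands pass through as breeding.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    bands = np.floor(records["lat"].to_numpy() / band_width) * band_width
    nonbreeding_mask = np.zeros(len(records), dtype=bool)
    centers: dict[float, tuple[float, float] | None] = {}
    for band in np.unique(bands):
        sel = np.nonzero(bands == band)[0]
        days = records["julian_day"].to_numpy()[sel]
        if len(sel) < min_band_size or np.ptp(days) == 0:
            centers[float(band)] = None
            continue
        cut, (c_lo, c_hi) = kmeans2_1d(days)
        centers[float(band)] = (c_lo, c_hi)
        if c_hi - c_lo > separation_days:
            threshold = np.sort(days)[cut - 1]  # upper edge of lower cluster
            nonbreeding_mask[sel[days > threshold]] = True
    return SeasonSplit(
        breeding=records.loc[~nonbreeding_mask].reset_index(drop=True),
        nonbreeding=records.loc[nonbreeding_mask].reset_index(drop=True),
        band_centers=centers,
    )
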