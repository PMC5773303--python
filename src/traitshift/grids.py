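"""Lightweight geographic grids and ESRI ASCII raster I/O.

All rasters in this package live on a plain geographic (lat/lon) grid of
square cells. Arrays are stored south-up: row 0 is the southernmost row,
column 0 the westernmost column. ESRI ASCII files are north-up, so arrays
are flipped on read/write.

Cell membership uses half-open cells [west, east) x [south, north): a point
exactly on a cell's south or west edge belongs to that cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Georeference of a regular lat/lon grid (south-up array convention)."""

    nrows: int
    ncols: int
    lat_min: float
    lon_min: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid shape must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nrows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/col of the half-open cell containing (lat, lon).

        Raises ValueError for points outside the grid extent.
        """
        if not (self.lat_min <= lat < self.lat_max) or not (
            self.lon_min <= lon < self.lon_max
        ):
            raise ValueError(
                f"point ({lat}, {lon}) outside grid extent "
                f"[{self.lat_min}, {self.lat_max}) x [{self.lon_min}, {self.lon_max})"
            )
        row = int(np.floor((lat - self.lat_min) / self.cell_size))
        col = int(np.floor((lon - self.lon_min) / self.cell_size))
        # guard against float roundoff at the extreme edge
        row = min(row, self.nrows - 1)
        col = min(col, self.ncols - 1)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat2d, lon2d) arrays of cell-center coordinates, shape (nrows, ncols)."""
        lats = self.lat_min + (np.arange(self.nrows) + 0.5) * self.cell_size
        lons = self.lon_min + (np.arange(self.ncols) + 0.5) * self.cell_size
        lon2d, lat2d = np.meshgrid(lons, lats)
        return lat2d, lon2d

    def same_as(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and abs(self.lat_min - other.lat_min) < tol
            and abs(self.lon_min - other.lon_min) < tol
            and abs(self.cell_size - other.cell_size) < tol
        )


def write_ascii_grid(path: str | Path, grid: Grid, values: np.ndarray,
                     mask: np.ndarray | None = None) -> None:
    """Write a south-up array as a north-up ESRI ASCII grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"array shape {values.shape} != grid shape {grid.shape}")
    out = values.copy()
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = NODATA
    out = np.where(np.isnan(out), NODATA, out)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.lon_min!r}\n"
        f"yllcorner {grid.lat_min!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[Grid, np.ndarray]:
    """Read an ESRI ASCII grid; returns (Grid, south-up array with NaN nodata)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = Grid(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        lat_min=header["yllcorner"],
        lon_min=header["xllcorner"],
        cell_size=header["cellsize"],
    )
    data = np.atleast_2d(data)[::-1].copy()
    nodata = header.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    return grid, data
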