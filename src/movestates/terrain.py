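"""Planar raster grids: terrain ruggedness and covariate extraction.

Rasters are plain numpy grids with square cells on a projected (metre)
coordinate system, read and written as ESRI ASCII grids (a simple text
format with an ``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value``
header).  Dynamic covariates live on a space-time grid (a time-stacked
raster) sampled at the grid time nearest each fix, earlier slice on ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Raster",
    "SpaceTimeGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "compute_tri",
    "extract_static",
    "extract_dynamic",
]


@dataclass
class Raster:
    """Single-band planar raster; row 0 is the northern edge.

    ``xll``/``yll`` are the coordinates of the lower-left corner of the
    grid, ``cell`` the square cell size in the same units as x/y.
    """

    values: np.ndarray
    xll: float
    yll: float
    cell: float

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self):
        return self.values.shape

    def rowcol(self, x, y):
        """Row/column of the cell containing each point; -1 out of extent."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        nrows, ncols = self.values.shape
        col = np.floor((x - self.xll) / self.cell).astype(int)
        row_from_bottom = np.floor((y - self.yll) / self.cell).astype(int)
        row = nrows - 1 - row_from_bottom
        bad = (col < 0) | (col >= ncols) | (row < 0) | (row >= nrows)
        bad |= ~np.isfinite(x) | ~np.isfinite(y)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    vals = np.loadtxt(lines[i:], ndmin=2)
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data does not match its header dimensions")
    return Raster(
        values=vals,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell=header["cellsize"],
    )


def write_ascii_grid(raster: Raster, path, nodata: float = -9999.0):
    nrows, ncols = raster.shape
    vals = np.where(np.isfinite(raster.values), raster.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xll}\n")
        fh.write(f"yllcorner {raster.yll}\n")
        fh.write(f"cellsize {raster.cell}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def compute_tri(elevation: Raster) -> Raster:
    """Terrain ruggedness index: mean absolute elevation difference
    between each cell and its 8 neighbours (edge cells use the
    neighbours they have)."""
    z = elevation.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("raster must be at least 3x3 for a ruggedness index")
    pad = np.full((z.shape[0] + 2, z.shape[1] + 2), np.nan)
    pad[1:-1, 1:-1] = z
    acc = np.zeros_like(z)
    cnt = np.zeros_like(z)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nb = pad[1 + di : 1 + di + z.shape[0], 1 + dj : 1 + dj + z.shape[1]]
            d = np.abs(z - nb)
            ok = np.isfinite(d)
            acc[ok] += d[ok]
            cnt[ok] += 1
    tri = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return Raster(values=tri, xll=elevation.xll, yll=elevation.yll, cell=elevation.cell)


def extract_static(raster: Raster, x, y) -> np.ndarray:
    """Value of the cell containing each fix; NaN out of extent."""
    row, col = raster.rowcol(x, y)
    out = np.full(row.shape, np.nan)
    ok = row >= 0
    out[ok] = raster.values[row[ok], col[ok]]
    return out


@dataclass
class SpaceTimeGrid:
    """Time-stacked raster for dynamic covariates (e.g. 3-hourly snow)."""

    values: np.ndarray  # (n_times, nrows, ncols)
    times: pd.DatetimeIndex
    xll: float
    yll: float
    cell: float

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.times = pd.DatetimeIndex(self.times)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.times):
            raise ValueError("values must be (n_times, nrows, ncols)")
        if not self.times.is_monotonic_increasing:
            raise ValueError("grid times must be sorted")

    def nearest_time_index(self, timestamps) -> np.ndarray:
        """Index of the grid time nearest each timestamp, earlier on ties."""
        ts = pd.DatetimeIndex(timestamps).asi8
        gt = self.times.asi8
        pos = np.searchsorted(gt, ts)
        left = np.clip(pos - 1, 0, len(gt) - 1)
        right = np.clip(pos, 0, len(gt) - 1)
        use_left = (ts - gt[left]) <= (gt[right] - ts)  # earlier wins ties
        return np.where(use_left, left, right)


def extract_dynamic(grid: SpaceTimeGrid, x, y, timestamps) -> np.ndarray:
    """Cell value at each fix position and its nearest grid time."""
    r = Raster(grid.values[0], grid.xll, grid.yll, grid.cell)
    row, col = r.rowcol(x, y)
    ti = grid.nearest_time_index(timestamps)
    out = np.full(row.shape, np.nan)
    ok = row >= 0
    out[ok] = grid.values[ti[ok], row[ok], col[ok]]
    return out
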