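"""Georeferenced single-band rasters: DEM, DSM and CHM construction.

Grids follow the usual north-up raster convention: ``(x0, y0)`` is the
top-left corner, cell ``(i, j)`` (0-based, row-major) covers the half-open
square ``[x0 + j*c, x0 + (j+1)*c) × (y0 - (i+1)*c, y0 - i*c]`` for cell
size ``c``.  The working resolution is 1 m.

Rasters are stored on disk as ESRI ASCII grid (.asc), a plain-text format
whose header carries the same geotransform information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from crowncloud.pointcloud import ColoredPointCloud

NODATA = -9999.0


@dataclass
class RasterGrid:
    """Single-band raster with top-left origin ``(x0, y0)`` and square cells."""

    x0: float
    y0: float
    cell: float
    values: np.ndarray  # (n_rows, n_cols) float64

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (self.values.shape == other.values.shape
                and np.isclose(self.x0, other.x0)
                and np.isclose(self.y0, other.y0)
                and np.isclose(self.cell, other.cell))

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cells containing planimetric points."""
        j = np.floor((np.asarray(x) - self.x0) / self.cell).astype(np.int64)
        i = np.floor((self.y0 - np.asarray(y)) / self.cell).astype(np.int64)
        return i, j

    def cell_center(self, i: np.ndarray, j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Planimetric coordinates of cell centers."""
        x = self.x0 + (np.asarray(j) + 0.5) * self.cell
        y = self.y0 - (np.asarray(i) + 0.5) * self.cell
        return x, y

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=np.float64))


def _grid_for_extent(x: np.ndarray, y: np.ndarray, cell: float) -> RasterGrid:
    x0 = np.floor(x.min() / cell) * cell
    y_top = np.ceil(y.max() / cell) * cell
    n_cols = max(1, int(np.ceil((x.max() - x0) / cell)))
    n_rows = max(1, int(np.ceil((y_top - y.min()) / cell)))
    # points exactly on the right/bottom edge still need a cell
    if x0 + n_cols * cell <= x.max():
        n_cols += 1
    if y_top - n_rows * cell >= y.min():
        n_rows += 1
    return RasterGrid(float(x0), float(y_top), cell,
                      np.full((n_rows, n_cols), NODATA))


def _bin_aggregate(grid: RasterGrid, x: np.ndarray, y: np.ndarray,
                   z: np.ndarray, how: str) -> np.ndarray:
    i, j = grid.cell_of(x, y)
    inb = (i >= 0) & (i < grid.n_rows) & (j >= 0) & (j < grid.n_cols)
    i, j, z = i[inb], j[inb], np.asarray(z)[inb]
    flat = i * grid.n_cols + j
    out = np.full(grid.n_rows * grid.n_cols, NODATA)
    if how == "min":
        out_valid = np.full_like(out, np.inf)
        np.minimum.at(out_valid, flat, z)
        filled = np.isfinite(out_valid) & (out_valid < np.inf)
        out[filled] = out_valid[filled]
    elif how == "max":
        out_valid = np.full_like(out, -np.inf)
        np.maximum.at(out_valid, flat, z)
        filled = out_valid > -np.inf
        out[filled] = out_valid[filled]
    else:
        raise ValueError(how)
    return out.reshape(grid.n_rows, grid.n_cols)


def make_dem(ground: ColoredPointCloud, cell: float = 1.0,
             grid: RasterGrid | None = None) -> RasterGrid:
    """Bare-earth DEM from ground/nonvegetation points.

    Each non-empty cell takes the minimum z of its points (robust against
    residual canopy returns); empty cells are filled by linear interpolation
    over the Delaunay triangulation of non-empty cell centers, and by
    nearest-neighbor extrapolation beyond their convex hull, so the result
    has no nodata cells.
    """
    if len(ground) == 0:
        raise ValueError("cannot build a DEM from an empty point set")
    if grid is None:
        grid = _grid_for_extent(ground.x, ground.y, cell)
    values = _bin_aggregate(grid, ground.x, ground.y, ground.z, "min")
    values = _fill_nodata(grid, values)
    return grid.copy_with(values)


def _fill_nodata(grid: RasterGrid, values: np.ndarray) -> np.ndarray:
    filled = values != NODATA
    if filled.all():
        return values
    ii, jj = np.nonzero(filled)
    cx, cy = grid.cell_center(ii, jj)
    pts = np.column_stack([cx, cy])
    vals = values[filled]
    mi, mj = np.nonzero(~filled)
    qx, qy = grid.cell_center(mi, mj)
    query = np.column_stack([qx, qy])
    out = values.copy()
    if len(pts) >= 3:
        est = LinearNDInterpolator(pts, vals)(query)
    else:
        est = np.full(len(query), np.nan)
    hole = np.isnan(est)
    if hole.any():
        est[hole] = NearestNDInterpolator(pts, vals)(query[hole])
    out[mi, mj] = est
    return out


def make_dsm(points: ColoredPointCloud, grid: RasterGrid) -> RasterGrid:
    """Per-cell maximum elevation; cells with no points stay nodata."""
    values = _bin_aggregate(grid, points.x, points.y, points.z, "max")
    return grid.copy_with(values)


def make_chm(points: ColoredPointCloud, dem: RasterGrid) -> RasterGrid:
    """Canopy height model: per-cell highest point minus the DEM, floored at 0.

    Cells containing no points get height 0.  The CHM shares the DEM's grid
    geometry exactly.
    """
    dsm = make_dsm(points, dem)
    chm = dsm.values - dem.values
    chm[dsm.values == NODATA] = 0.0
    np.clip(chm, 0.0, None, out=chm)
    return dem.copy_with(chm)


def gaussian_smooth(raster: RasterGrid, window: int = 3,
                    sigma: float = 0.5) -> RasterGrid:
    """Convolve with a normalized ``window`` × ``window`` Gaussian kernel.

    ``sigma`` is in cells.  Edges are handled by reflection, so a constant
    raster is unchanged and the global mean is preserved.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    half = window // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    kernel1d = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    kernel = np.outer(kernel1d, kernel1d)
    kernel /= kernel.sum()
    smoothed = ndimage.convolve(raster.values, kernel, mode="reflect")
    return raster.copy_with(smoothed)


def percentiles(raster: RasterGrid, q: np.ndarray | list[float]) -> np.ndarray:
    """Value percentiles over all cells (utility for model summaries)."""
    return np.percentile(raster.values.ravel(), q)


# -- ESRI ASCII grid --------------------------------------------------------

def write_ascii_grid(raster: RasterGrid, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.x0:.6f}\n")
        fh.write(f"yllcorner {raster.y0 - raster.n_rows * raster.cell:.6f}\n")
        fh.write(f"cellsize {raster.cell:.6f}\n")
        fh.write(f"NODATA_value {NODATA:.1f}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")
    return path


def read_ascii_grid(path: str | Path) -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    values = np.array(rows)
    cell = header["cellsize"]
    y0 = header["yllcorner"] + header["nrows"] * cell
    return RasterGrid(header["xllcorner"], y0, cell, values)
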