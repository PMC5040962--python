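"""Bathymetric raster container and file I/O.

Depths are metres, positive down. The grid is stored row-major with row 0
at the SOUTH edge (y increasing with row index); origin is the lower-left
corner of the lower-left cell. ESRI ASCII files are written/read with the
usual top-down row order and flipped on the way in/out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["BathymetryGrid", "read_ascii_grid", "write_ascii_grid",
           "read_tiff_grid", "write_tiff_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class BathymetryGrid:
    """2-D depth raster (m, positive down) on a square-celled planar grid."""

    depths: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 2:
            raise ValueError("depths must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depths.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        return np.isfinite(self.depths) & (self.depths != self.nodata)

    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        x0, y0 = self.origin
        return (x0 + (np.asarray(col) + 0.5) * self.cell_size,
                y0 + (np.asarray(row) + 0.5) * self.cell_size)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full raster."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncol * self.cell_size, y0 + nrow * self.cell_size)

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def locate(self, x, y):
        """Cell (row, col) containing a point; half-open cell membership.

        A point exactly on a shared edge belongs to the higher-index cell
        (the floor of the scaled coordinate), matching the documented
        convention.
        """
        inside = self.contains(x, y)
        if not np.all(inside):
            raise ValueError("point(s) outside raster extent")
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, dtype=float) - x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - y0) / self.cell_size).astype(int)
        return row, col

    def interpolate_depth(self, x, y):
        """Bilinear interpolation of depth at planar point(s), from cell centres."""
        from scipy.ndimage import map_coordinates

        if not np.all(self.contains(x, y)):
            raise ValueError("point(s) outside raster extent")
        x0, y0 = self.origin
        # fractional (row, col) in cell-centre coordinates
        fc = (np.asarray(x, dtype=float) - x0) / self.cell_size - 0.5
        fr = (np.asarray(y, dtype=float) - y0) / self.cell_size - 0.5
        return map_coordinates(self.depths, [np.atleast_1d(fr), np.atleast_1d(fc)],
                               order=1, mode="nearest")


def write_ascii_grid(grid: BathymetryGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (text; top-down row order)."""
    nrow, ncol = grid.shape
    x0, y0 = grid.origin
    data = np.where(grid.valid, grid.depths, grid.nodata)
    header = (f"ncols {ncol}\nnrows {nrow}\n"
              f"xllcorner {x0:.6f}\nyllcorner {y0:.6f}\n"
              f"cellsize {grid.cell_size:.6f}\nNODATA_value {grid.nodata:.1f}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data[::-1], fmt="%.6f")


def read_ascii_grid(path: str | Path) -> BathymetryGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1].copy()
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    data[data == nodata] = np.nan
    return BathymetryGrid(data, header["cellsize"],
                          (header["xllcorner"], header["yllcorner"]), nodata=nodata)


def write_tiff_grid(grid: BathymetryGrid, path: str | Path) -> None:
    """Single-band float32 TIFF + JSON sidecar with georeferencing.

    rasterio is not available in the target environment, so geokeys are
    carried in a ``<path>.json`` sidecar rather than in GeoTIFF tags.
    """
    import tifffile

    data = np.where(grid.valid, grid.depths, np.nan).astype(np.float32)
    tifffile.imwrite(str(path), data[::-1])
    sidecar = {"cell_size": grid.cell_size, "origin": list(grid.origin),
               "nodata": "nan", "row_order": "north-up"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_tiff_grid(path: str | Path) -> BathymetryGrid:
    import tifffile

    data = tifffile.imread(str(path)).astype(float)[::-1].copy()
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    return BathymetryGrid(data, float(sidecar["cell_size"]),
                          tuple(sidecar["origin"]))
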