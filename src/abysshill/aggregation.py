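"""Spatial aggregation: attach terrain attributes by geolocation, average
observations in bathymetric-model grid cells with minimum-count filters,
and split turbidity records into water-column / benthic-boundary-layer
groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import BathymetryGrid
from .terrain import assign_depth_bands

__all__ = ["locate", "summarise_cells", "find_crest", "distance_from_crest",
           "layer_turbidity", "BBL_ALTITUDE_M"]

BBL_ALTITUDE_M = 10.0


def locate(x, y, grid: BathymetryGrid):
    """Cell (row, col) of point(s); half-open membership, boundary points to
    the higher-index cell. Raises for points outside the extent."""
    return grid.locate(x, y)


def find_crest(grid: BathymetryGrid, primary: np.ndarray,
               crest_xy: tuple[float, float] | None = None) -> tuple[float, float]:
    """Hill-crest position: the minimum-depth cell centre within the largest
    connected Hill-class component (or a configured override)."""
    if crest_xy is not None:
        return crest_xy
    hill = primary == "Hill"
    if not hill.any():
        raise ValueError("no Hill cells and no configured crest position")
    labels, n = ndimage.label(hill, structure=np.ones((3, 3), bool))
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    comp = labels == sizes.argmax()
    depths = np.where(comp, grid.depths, np.inf)
    r, c = np.unravel_index(np.argmin(depths), depths.shape)
    cx, cy = grid.cell_center(int(r), int(c))
    return float(cx), float(cy)


def distance_from_crest(x, y, crest_xy: tuple[float, float]):
    """Planar Euclidean distance (m) from point(s) to the crest."""
    out = np.hypot(np.asarray(x, dtype=float) - crest_xy[0],
                   np.asarray(y, dtype=float) - crest_xy[1])
    return float(out) if np.ndim(x) == 0 else out


def summarise_cells(pom_results: pd.DataFrame | None,
                    tile_biomass: pd.DataFrame | None,
                    terrain: dict[str, np.ndarray],
                    grid: BathymetryGrid,
                    min_images: int = 50,
                    min_tiles: int = 5,
                    crest_xy: tuple[float, float] | None = None) -> pd.DataFrame:
    """Per-grid-cell means of POM cover and tile biomass with the published
    minimum-count filters applied per variable independently.

    ``pom_results`` needs columns x, y, total_cover (optionally
    light_cover/dark_cover); ``tile_biomass`` needs x, y, biomass.
    ``terrain`` maps attribute name -> raster aligned with ``grid``
    (expected keys: bpi, slope, rugosity, curvature, primary, secondary).
    Cells passing neither filter are dropped.
    """
    nrow, ncol = grid.shape

    def _cell_frame(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        row, col = locate(df["x"].to_numpy(), df["y"].to_numpy(), grid)
        g = df.assign(_row=row, _col=col).groupby(["_row", "_col"])
        out = g[cols].mean()
        out["n"] = g.size()
        return out.reset_index()

    frames = []
    if pom_results is not None and len(pom_results):
        cols = [c for c in ("total_cover", "light_cover", "dark_cover")
                if c in pom_results.columns]
        pc = _cell_frame(pom_results, cols)
        pc = pc[pc["n"] >= min_images]
        pc = pc.rename(columns={"n": "n_images",
                                **{c: f"mean_{c}" for c in cols}})
        frames.append(pc)
    if tile_biomass is not None and len(tile_biomass):
        bc = _cell_frame(tile_biomass, ["biomass"])
        bc = bc[bc["n"] >= min_tiles]
        bc = bc.rename(columns={"n": "n_tiles", "biomass": "mean_biomass"})
        frames.append(bc)
    if not frames:
        return pd.DataFrame()
    cells = frames[0]
    for f in frames[1:]:
        cells = cells.merge(f, on=["_row", "_col"], how="outer")
    cells = cells.rename(columns={"_row": "row", "_col": "col"})

    r = cells["row"].to_numpy()
    c = cells["col"].to_numpy()
    cells["depth"] = grid.depths[r, c]
    for key, raster in terrain.items():
        cells[key] = np.asarray(raster, dtype=object if raster.dtype == object else None)[r, c]
    cx, cy = grid.cell_center(r, c)
    cells["x"] = cx
    cells["y"] = cy
    try:
        crest = find_crest(grid, np.asarray(terrain.get("primary")), crest_xy)
        cells["distance_from_crest"] = distance_from_crest(cx, cy, crest)
    except (ValueError, TypeError):
        cells["distance_from_crest"] = np.nan
    return cells


def layer_turbidity(records: pd.DataFrame, min_n: int = 50) -> pd.DataFrame:
    """Assign each turbidity record a layer and a 12.5 m depth band.

    Layer: BBL when vehicle altitude <= 10 m, water_column above. Bands
    are assigned on seabed depth (record depth + altitude when a
    ``seabed_depth`` column is absent), with terminal amalgamation as for
    the image analysis.
    """
    alt = records["altitude"].to_numpy(dtype=float)
    if np.any(alt < 0):
        raise ValueError("negative vehicle altitude")
    out = records.copy()
    out["layer"] = np.where(alt <= BBL_ALTITUDE_M, "BBL", "water_column")
    if "seabed_depth" in out.columns:
        seabed = out["seabed_depth"].to_numpy(dtype=float)
    else:
        seabed = out["depth"].to_numpy(dtype=float) + alt
    out["depth_band"] = assign_depth_bands(seabed, min_n=min_n)
    return out
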