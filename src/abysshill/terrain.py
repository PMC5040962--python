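"""Terrain derivatives, bathymetric position index (BPI), and terrain classes.

All derivatives operate on depth (m, positive down). BPI is computed on
positive-down depth, so crests (locally shallow cells) yield NEGATIVE BPI;
the class bounds below follow that convention (hills at strongly negative
BPI).

Class bounds (metres for BPI, degrees for slope):

    primary  : Hill   BPI < -25
               Plain  -25 <= BPI <= 50 and slope < 2
               Slope  otherwise
    secondary: 4 BPI bands {< -100, [-100, -25), [-25, 50], > 50}
               x 3 slope bands {< 2, [2, 5], > 5}

Boundary values -25, 50 (BPI) and 2, 5 (slope) belong to the closed middle
bands.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .grids import BathymetryGrid

__all__ = [
    "compute_slope", "compute_rugosity", "compute_curvature", "compute_bpi",
    "classify_primary", "classify_secondary", "annulus_offsets",
    "PRIMARY_CLASSES", "SECONDARY_CLASSES",
    "natural_depth_bins", "depth_band_edges", "assign_depth_band",
    "assign_depth_bands", "band_label",
]

PRIMARY_CLASSES = ("Hill", "Slope", "Plain")

# secondary classes laid out as [bpi_band][slope_band]; the seven occupied
# combinations carry the published names, the remaining five follow the
# same per-band lettering scheme
_SECONDARY_TABLE = [
    ["Hill A", "Hill B", "Hill C"],     # BPI < -100
    ["Hill D", "Hill E", "Hill F"],     # -100 <= BPI < -25
    ["Plain", "Slope A", "Slope B"],    # -25 <= BPI <= 50
    ["Slope C", "Slope D", "Slope E"],  # BPI > 50
]
SECONDARY_CLASSES = tuple(name for row in _SECONDARY_TABLE for name in row)

BIN_WIDTH_M = 12.5


# ---------------------------------------------------------------------------
# derivatives

def _padded(grid: BathymetryGrid) -> np.ndarray:
    z = np.where(grid.valid, grid.depths, np.nan)
    if not np.any(np.isfinite(z)):
        raise ValueError("all-nodata grid")
    return z


def _window9(z: np.ndarray):
    """The nine 3x3-window views (z1..z9 row-major, z5 centre), interior only."""
    return [z[r:r + z.shape[0] - 2, c:c + z.shape[1] - 2]
            for r in (0, 1, 2) for c in (0, 1, 2)]


def compute_slope(grid: BathymetryGrid) -> np.ndarray:
    """Slope angle (degrees) by Horn's 3x3 weighted finite differences.

    Border cells (and any cell whose 3x3 window touches nodata) are NaN.
    """
    z = _padded(grid)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("need at least a 3x3 grid")
    s = grid.cell_size
    z1, z2, z3, z4, _, z6, z7, z8, z9 = _window9(z)
    dzdx = ((z3 + 2 * z6 + z9) - (z1 + 2 * z4 + z7)) / (8 * s)
    dzdy = ((z7 + 2 * z8 + z9) - (z1 + 2 * z2 + z3)) / (8 * s)
    out = np.full(z.shape, np.nan)
    out[1:-1, 1:-1] = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return out


def compute_rugosity(grid: BathymetryGrid) -> np.ndarray:
    """3x3 surface-area to planar-area ratio (>= 1).

    The 3x3 neighbourhood is triangulated as the 8 triangles joining the
    centre cell point to consecutive pairs of its ring neighbours; the
    ratio is total 3-D triangle area over its planar projection. For a
    dipping plane this is exactly 1/cos(slope).
    """
    z = _padded(grid)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("need at least a 3x3 grid")
    s = grid.cell_size
    z1, z2, z3, z4, z5, z6, z7, z8, z9 = _window9(z)
    # ring points in circular order with planar offsets from the centre
    ring = [(z1, -s, -s), (z2, 0, -s), (z3, s, -s), (z6, s, 0),
            (z9, s, s), (z8, 0, s), (z7, -s, s), (z4, -s, 0)]
    area3d = np.zeros_like(z5)
    planar = 0.0
    for i in range(8):
        za, xa, ya = ring[i]
        zb, xb, yb = ring[(i + 1) % 8]
        # triangle (centre, a, b); depth positive-down is a valid z-axis
        ux, uy, uz = xa, ya, za - z5
        vx, vy, vz = xb, yb, zb - z5
        cx = uy * vz - uz * vy
        cy = uz * vx - ux * vz
        cz = ux * vy - uy * vx
        area3d = area3d + 0.5 * np.sqrt(cx ** 2 + cy ** 2 + cz ** 2)
        planar += 0.5 * abs(xa * yb - ya * xb)
    out = np.full(z.shape, np.nan)
    out[1:-1, 1:-1] = area3d / planar
    return out


def compute_curvature(grid: BathymetryGrid) -> np.ndarray:
    """Profile curvature (1/m) by the Zevenbergen-Thorne quadratic fit.

    Computed on elevation (negative depth) with the sign convention that a
    convex-up surface (hill crest) is NEGATIVE. Flat and uniformly dipping
    surfaces give 0. At zero-gradient cells the directional formula is
    indeterminate; the limit D + E (which equals it for locally symmetric
    surfaces) is used there, so crests/pits still carry a convexity sign.
    """
    z = -_padded(grid)  # elevation
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("need at least a 3x3 grid")
    L = grid.cell_size
    z1, z2, z3, z4, z5, z6, z7, z8, z9 = _window9(z)
    # Zevenbergen & Thorne quadratic coefficients (z2 north of z5, z8 south)
    D = ((z4 + z6) / 2 - z5) / L ** 2
    E = ((z2 + z8) / 2 - z5) / L ** 2
    F = (-z1 + z3 + z7 - z9) / (4 * L ** 2)
    G = (-z4 + z6) / (2 * L)
    H = (z2 - z8) / (2 * L)
    g2 = G ** 2 + H ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = 2 * (D * G ** 2 + E * H ** 2 + F * G * H) / g2
    prof = np.where(g2 > 0, prof, D + E)
    prof = np.where(np.isnan(z5) | np.isnan(D + E + F), np.nan, prof)
    out = np.full(z.shape, np.nan)
    out[1:-1, 1:-1] = prof
    return out


# ---------------------------------------------------------------------------
# BPI

def annulus_offsets(inner_m: float, outer_m: float, cell_size: float) -> np.ndarray:
    """Boolean kernel of cells whose centre distance d satisfies
    inner <= d <= outer (inclusive both ends); the centre cell itself is
    excluded even when inner == 0."""
    if not (outer_m > inner_m >= 0):
        raise ValueError("need outer > inner >= 0")
    r = int(np.floor(outer_m / cell_size))
    if r < 1:
        raise ValueError("outer radius smaller than one cell")
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    d = np.hypot(dx, dy) * cell_size
    ker = (d >= inner_m) & (d <= outer_m)
    ker[r, r] = False
    if not ker.any():
        raise ValueError("annulus contains no cells at this cell size")
    return ker


def compute_bpi(grid: BathymetryGrid, inner_radius_m: float = 400.0,
                outer_radius_m: float = 1200.0,
                min_valid_fraction: float = 0.5) -> np.ndarray:
    """BPI (m, signed): depth(cell) minus the mean depth over an annulus
    neighbourhood. Cells where fewer than ``min_valid_fraction`` of the
    annulus is available (nodata or off-grid) are NaN.
    """
    z = _padded(grid)
    ker = annulus_offsets(inner_radius_m, outer_radius_m, grid.cell_size).astype(float)
    vals = np.where(np.isfinite(z), z, 0.0)
    ok = np.isfinite(z).astype(float)
    ssum = fftconvolve(vals, ker, mode="same")
    scount = fftconvolve(ok, ker, mode="same")
    scount = np.round(scount)  # fft jitter on integer counts
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = ssum / scount
    bpi = z - mean
    bpi[scount < min_valid_fraction * ker.sum()] = np.nan
    bpi[~np.isfinite(z)] = np.nan
    return bpi


# ---------------------------------------------------------------------------
# classification

def _bpi_band(bpi):
    bpi = np.asarray(bpi, dtype=float)
    band = np.full(bpi.shape, -1, dtype=int)
    band[bpi < -100] = 0
    band[(bpi >= -100) & (bpi < -25)] = 1
    band[(bpi >= -25) & (bpi <= 50)] = 2
    band[bpi > 50] = 3
    return band


def _slope_band(slope):
    slope = np.asarray(slope, dtype=float)
    band = np.full(slope.shape, -1, dtype=int)
    band[slope < 2] = 0
    band[(slope >= 2) & (slope <= 5)] = 1
    band[slope > 5] = 2
    return band


def classify_primary(bpi, slope):
    """Primary terrain class for scalar or array inputs.

    Returns an object array of {'Hill','Slope','Plain'}; NaN inputs give
    None (scalar) / None entries (array).
    """
    bpi = np.asarray(bpi, dtype=float)
    slope = np.asarray(slope, dtype=float)
    out = np.full(bpi.shape, None, dtype=object)
    ok = np.isfinite(bpi) & np.isfinite(slope)
    hill = ok & (bpi < -25)
    plain = ok & (bpi >= -25) & (bpi <= 50) & (slope < 2)
    slope_c = ok & ~hill & ~plain
    out[hill] = "Hill"
    out[plain] = "Plain"
    out[slope_c] = "Slope"
    return out[()] if out.ndim == 0 else out


def classify_secondary(bpi, slope):
    """Secondary terrain class (12-class scheme) for scalar or array input."""
    bb = _bpi_band(bpi)
    sb = _slope_band(slope)
    out = np.full(bb.shape, None, dtype=object)
    ok = (bb >= 0) & (sb >= 0)
    table = np.array(_SECONDARY_TABLE, dtype=object)
    out[ok] = table[bb[ok], sb[ok]]
    return out[()] if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# depth bands

def natural_depth_bins(depths) -> np.ndarray:
    """Bin index k of the natural interval [12.5 k, 12.5 (k+1)), lower-
    inclusive."""
    depths = np.asarray(depths, dtype=float)
    if np.any(depths <= 0):
        raise ValueError("depths must be positive (metres, positive down)")
    return np.floor(depths / BIN_WIDTH_M).astype(int)


def _display(bound: float) -> int:
    # half-up rounding so 4787.5 displays as 4788
    return int(np.floor(bound + 0.5))


def band_label(lo: float | None, hi: float | None) -> str:
    """Human label: '<4788' / '4788-4800' / '>4838' with bounds shown as
    rounded integers (computation keeps exact 12.5-multiples)."""
    if lo is None and hi is None:
        return "all"
    if lo is None:
        return f"<{_display(hi)}"
    if hi is None:
        return f">{_display(lo)}"
    return f"{_display(lo)}-{_display(hi)}"


def depth_band_edges(depths, min_n: int = 50) -> list[tuple[float | None, float | None]]:
    """Edges of the 12.5 m depth bands after terminal amalgamation.

    Terminal bins with fewer than ``min_n`` members are merged inward until
    every band meets min_n; the resulting first and last bands are
    open-ended (None bound).
    """
    ks = natural_depth_bins(depths)
    kmin, kmax = int(ks.min()), int(ks.max())
    counts = np.bincount(ks - kmin, minlength=kmax - kmin + 1)
    bands = [[k, k, int(c)] for k, c in zip(range(kmin, kmax + 1), counts)]
    # merge from the shallow end, then the deep end
    while len(bands) > 1 and bands[0][2] < min_n:
        k0, _, c = bands.pop(0)
        bands[0][0] = k0
        bands[0][2] += c
    while len(bands) > 1 and bands[-1][2] < min_n:
        _, k1, c = bands.pop()
        bands[-1][1] = k1
        bands[-1][2] += c
    edges: list[tuple[float | None, float | None]] = []
    for i, (k0, k1, _c) in enumerate(bands):
        lo = None if i == 0 else k0 * BIN_WIDTH_M
        hi = None if i == len(bands) - 1 else (k1 + 1) * BIN_WIDTH_M
        edges.append((lo, hi))
    return edges


def assign_depth_band(depth_m: float,
                      edges: list[tuple[float | None, float | None]]) -> str:
    """Band label for one depth given amalgamated band edges."""
    for lo, hi in edges:
        if (lo is None or depth_m >= lo) and (hi is None or depth_m < hi):
            return band_label(lo, hi)
    raise ValueError(f"depth {depth_m} not covered by bands")


def assign_depth_bands(depths, min_n: int = 50) -> np.ndarray:
    """Vectorised: amalgamated band labels for an array of depths."""
    depths = np.asarray(depths, dtype=float)
    edges = depth_band_edges(depths, min_n=min_n)
    return np.array([assign_depth_band(d, edges) for d in depths.ravel()],
                    dtype=object).reshape(depths.shape)
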