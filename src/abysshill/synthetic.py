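"""Synthetic survey generator with known ground truth.

Produces the full input suite the downstream analysis needs: a plain-plus-
Gaussian-hills bathymetric grid, boustrophedon AUV survey tracks, rendered
seabed photographs with exact per-pixel class masks, Poisson/lognormal
megafauna annotations with analytic expected biomass, and depth-trended
turbidity and sediment-core records. Every operation takes an explicit
seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as _ellipse

from .biomass import Annotation, MorphotypeLUT, MorphotypeEntry, Tile
from .grids import BathymetryGrid
from .pom import SurveyImage, BACKGROUND, LIGHT, DARK

__all__ = [
    "HillSpec", "TrackSpec", "RenderParams", "MorphotypeSpec", "SceneTruth",
    "EnvironmentConfig", "GeneratorConfig",
    "make_bathymetry", "make_survey", "render_image", "make_annotations",
    "make_environment", "default_morphotypes", "tune_densities",
    "expected_tile_biomass", "demo_config",
]


# ---------------------------------------------------------------------------
# configuration types

@dataclass
class HillSpec:
    """Isotropic Gaussian hill: elevation h * exp(-(d/radius)^2)."""

    center_x: float
    center_y: float
    height: float
    radius: float

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError("hill height must be positive")
        if not self.radius > 0:
            raise ValueError("hill radius must be positive")


@dataclass
class TrackSpec:
    line_spacing: float = 1000.0
    line_length: float = 1000.0
    n_lines: int = 1
    image_spacing: float = 1.0
    x_start: float = 0.0
    y_start: float = 0.0
    altitude: float = 3.2
    footprint_area: float = 1.6


@dataclass
class RenderParams:
    size: tuple[int, int] = (160, 160)          # (height, width)
    bg_mean: tuple[float, float, float] = (125.0, 122.0, 118.0)
    bg_speckle: float = 4.0
    light_delta: float = 45.0
    dark_delta: float = -45.0
    pixel_noise: float = 2.0
    log_area_mean: float = 5.0                  # ln(pixels); median ~148 px
    log_area_sd: float = 0.5
    min_aggregate_px: int = 30
    max_aspect: float = 2.5
    tolerance_pp: float = 0.25                  # percentage points
    illumination_falloff: float = 0.0           # fractional dimming at corners


@dataclass
class MorphotypeSpec:
    """Generator-side morphotype: allometry + lognormal size distribution +
    per-terrain-class numerical density (individuals m^-2)."""

    name: str
    a: float
    b: float
    feeding_type: str
    log_size_mean: float        # mean of ln(L), L in mm
    log_size_sd: float
    density: dict = field(default_factory=dict)

    def expected_mass(self) -> float:
        """E[a L^b] for lognormal L (closed form)."""
        return self.a * np.exp(self.b * self.log_size_mean
                               + 0.5 * (self.b * self.log_size_sd) ** 2)

    def lut_entry(self) -> MorphotypeEntry:
        return MorphotypeEntry(a=self.a, b=self.b, feeding_type=self.feeding_type)


@dataclass
class SceneTruth:
    """Ground truth for one rendered image: the mask IS the truth, the
    recorded covers are its exact pixel fractions."""

    light_cover: float
    dark_cover: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        for c in (self.light_cover, self.dark_cover):
            if not 0 <= c <= 100:
                raise ValueError("covers must lie in [0, 100]")

    @property
    def total_cover(self) -> float:
        return self.light_cover + self.dark_cover


@dataclass
class EnvironmentConfig:
    plain_depth: float = 4850.0
    # turbidity
    ftu_baseline: float = 0.10
    bbl_increment: float = 0.065     # fractional BBL elevation effect at ref elevation
    elevation_ref: float = 70.0      # m above plain giving the full increment
    ftu_noise: float = 0.004
    n_turbidity: int = 4000
    bbl_altitude: float = 3.2
    wc_altitude: float = 50.0
    # sediments (linear in depth around the elevation threshold)
    n_sites_plain: int = 9
    n_sites_elevated: int = 12
    depth_ref: float = 4840.0
    mud_at_ref: float = 80.0
    mud_slope: float = 0.18          # % per m of depth
    mud_noise: float = 2.0
    tn_at_ref: float = 0.060
    tn_slope: float = 1.7e-4
    tn_noise: float = 0.0015
    cn_mean: float = 5.7
    cn_noise: float = 0.12


@dataclass
class GeneratorConfig:
    plain_depth: float = 4850.0
    hills: list = field(default_factory=list)
    cell_size: float = 100.0
    grid_shape: tuple[int, int] = (60, 60)      # (nrow, ncol)
    depth_noise: float = 0.0                    # m, additive grid noise
    track: TrackSpec = field(default_factory=TrackSpec)
    render: RenderParams = field(default_factory=RenderParams)
    # class targets (Hill/Slope/Plain): total POM cover % and biomass g m^-2
    class_total_cover: dict = field(default_factory=lambda: {
        "Hill": 45.4, "Slope": 44.7, "Plain": 43.4})
    light_fraction: float = 0.5                 # light share of total cover
    class_biomass: dict = field(default_factory=lambda: {
        "Hill": 5.2, "Slope": 3.4, "Plain": 2.1})
    morphotypes: list = field(default_factory=list)
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for v in self.class_total_cover.values():
            if not 0 <= v <= 100:
                raise ValueError("class mean covers must lie in [0, 100]")
        for v in self.class_biomass.values():
            if v < 0:
                raise ValueError("class biomass must be >= 0")


# ---------------------------------------------------------------------------
# bathymetry

def make_bathymetry(config: GeneratorConfig) -> BathymetryGrid:
    """Plain depth minus summed Gaussian hill elevations, plus optional
    small-amplitude noise. Rejects hills narrower than one grid cell."""
    if config.cell_size <= 0:
        raise ValueError("cell size must be positive")
    if config.plain_depth <= 0:
        raise ValueError("plain depth must be positive")
    nrow, ncol = config.grid_shape
    x = (np.arange(ncol) + 0.5) * config.cell_size
    y = (np.arange(nrow) + 0.5) * config.cell_size
    xx, yy = np.meshgrid(x, y)
    depth = np.full((nrow, ncol), config.plain_depth, dtype=float)
    for hill in config.hills:
        if hill.radius < config.cell_size:
            raise ValueError(
                f"hill radius {hill.radius} m is below the cell size "
                f"{config.cell_size} m (unresolvable feature)")
        d2 = (xx - hill.center_x) ** 2 + (yy - hill.center_y) ** 2
        depth -= hill.height * np.exp(-d2 / hill.radius ** 2)
    if config.depth_noise > 0:
        rng = np.random.default_rng(config.seed)
        depth += rng.normal(0.0, config.depth_noise, size=depth.shape)
    return BathymetryGrid(depth, config.cell_size, origin=(0.0, 0.0))


# ---------------------------------------------------------------------------
# survey track

def make_survey(grid: BathymetryGrid, config: GeneratorConfig) -> list[SurveyImage]:
    """Images along boustrophedon lines (east-west lines stacked north-
    ward), endpoints inclusive; per-image depth by bilinear interpolation."""
    t = config.track
    xs: list[float] = []
    ys: list[float] = []
    n_img = int(np.floor(t.line_length / t.image_spacing)) + 1
    along = np.arange(n_img) * t.image_spacing
    for line in range(t.n_lines):
        y = t.y_start + line * t.line_spacing
        x = t.x_start + (along if line % 2 == 0 else along[::-1])
        xs.extend(x.tolist())
        ys.extend([y] * n_img)
    xs_a = np.array(xs)
    ys_a = np.array(ys)
    if not np.all(grid.contains(xs_a, ys_a)):
        raise ValueError("survey track extends outside the raster extent")
    depths = grid.interpolate_depth(xs_a, ys_a)
    return [SurveyImage(id=f"img{i:06d}", x=float(xs_a[i]), y=float(ys_a[i]),
                        depth=float(depths[i]), altitude=t.altitude,
                        footprint_area=t.footprint_area)
            for i in range(len(xs_a))]


# ---------------------------------------------------------------------------
# image rendering

def _place_class(mask: np.ndarray, cls: int, target_pct: float,
                 params: RenderParams, rng: np.random.Generator) -> None:
    h, w = mask.shape
    n = mask.size
    target_px = int(round(target_pct / 100.0 * n))
    tol_px = max(1, int(round(params.tolerance_pp / 100.0 * n)))
    if np.exp(params.log_area_mean) > 0.5 * n:
        raise ValueError("aggregate size exceeds image; target unreachable")
    painted = int(np.count_nonzero(mask == cls))
    for _ in range(100_000):
        deficit = target_px - painted
        if deficit <= tol_px:
            return
        area = float(np.exp(rng.normal(params.log_area_mean, params.log_area_sd)))
        area = min(area, float(deficit))
        area = max(area, float(params.min_aggregate_px))
        aspect = rng.uniform(1.0, params.max_aspect)
        ra = np.sqrt(area * aspect / np.pi)
        rb = np.sqrt(area / (np.pi * aspect))
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        rot = rng.uniform(0, np.pi)
        rr, cc = _ellipse(cy, cx, ra, rb, shape=mask.shape, rotation=rot)
        free = mask[rr, cc] == BACKGROUND
        mask[rr[free], cc[free]] = cls
        painted += int(np.count_nonzero(free))
    raise RuntimeError("aggregate placement failed to converge")


def render_image(true_cover_light: float, true_cover_dark: float,
                 params: RenderParams | None = None,
                 seed: int | np.random.Generator = 0,
                 ) -> tuple[np.ndarray, SceneTruth]:
    """Render an RGB seabed image plus its exact ground-truth class mask.

    Elliptical aggregates of each class are placed (background pixels
    only) until the mask fraction is within ``tolerance_pp`` of the
    target; the SceneTruth covers are then read back from the mask, so
    truth and mask agree exactly by construction.
    """
    params = params or RenderParams()
    if true_cover_light < 0 or true_cover_dark < 0:
        raise ValueError("target covers must be >= 0")
    if true_cover_light + true_cover_dark > 100:
        raise ValueError("target covers must sum to <= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = params.size
    mask = np.zeros((h, w), dtype=np.uint8)
    _place_class(mask, LIGHT, true_cover_light, params, rng)
    _place_class(mask, DARK, true_cover_dark, params, rng)

    rgb = np.empty((h, w, 3), dtype=float)
    base = np.array(params.bg_mean)
    speckle = rng.normal(0.0, params.bg_speckle, size=(h, w))
    for ch in range(3):
        rgb[..., ch] = base[ch] + speckle
    rgb[mask == LIGHT] += params.light_delta
    rgb[mask == DARK] += params.dark_delta
    rgb += rng.normal(0.0, params.pixel_noise, size=rgb.shape)
    if params.illumination_falloff > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot((yy - h / 2) / (h / 2), (xx - w / 2) / (w / 2)) / np.sqrt(2)
        rgb *= (1.0 - params.illumination_falloff * r ** 2)[..., None]
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    n = mask.size
    truth = SceneTruth(
        light_cover=100.0 * np.count_nonzero(mask == LIGHT) / n,
        dark_cover=100.0 * np.count_nonzero(mask == DARK) / n,
        mask=mask,
    )
    return rgb, truth


# ---------------------------------------------------------------------------
# megafauna annotations

def default_morphotypes() -> list[MorphotypeSpec]:
    """Demo morphotype table (documented invention, not field values).

    Densities are per terrain class and are meant to be rescaled against
    class biomass targets with :func:`tune_densities`.
    """
    return [
        MorphotypeSpec("holothurian", a=2.0e-4, b=2.2, feeding_type="deposit",
                       log_size_mean=np.log(60.0), log_size_sd=0.35,
                       density={"Hill": 0.10, "Slope": 0.10, "Plain": 0.10}),
        MorphotypeSpec("anemone", a=1.0e-3, b=2.0, feeding_type="suspension",
                       log_size_mean=np.log(35.0), log_size_sd=0.30,
                       density={"Hill": 0.10, "Slope": 0.04, "Plain": 0.02}),
        MorphotypeSpec("shrimp", a=5.0e-5, b=2.5, feeding_type="predator/scavenger",
                       log_size_mean=np.log(45.0), log_size_sd=0.25,
                       density={"Hill": 0.03, "Slope": 0.03, "Plain": 0.03}),
        MorphotypeSpec("xenophyophore", a=3.0e-4, b=1.8, feeding_type="other",
                       log_size_mean=np.log(50.0), log_size_sd=0.30,
                       density={"Hill": 0.02, "Slope": 0.02, "Plain": 0.02}),
    ]


def expected_tile_biomass(morphotypes: list[MorphotypeSpec], terrain_class: str) -> float:
    """Analytic E[biomass] (g m^-2) for a terrain class:
    sum over morphotypes of density * E[a L^b]."""
    return float(sum(m.density.get(terrain_class, 0.0) * m.expected_mass()
                     for m in morphotypes))


def tune_densities(morphotypes: list[MorphotypeSpec],
                   targets: dict[str, float]) -> list[MorphotypeSpec]:
    """Rescale per-class densities so the analytic expected biomass equals
    each class target exactly (preserving the density mix within a class)."""
    tuned = [replace(m, density=dict(m.density)) for m in morphotypes]
    for cls, target in targets.items():
        current = expected_tile_biomass(tuned, cls)
        if current <= 0:
            raise ValueError(f"no density in class {cls!r} to scale")
        f = target / current
        for m in tuned:
            if cls in m.density:
                m.density[cls] *= f
    return tuned


def make_annotations(tiles: list[Tile], class_of_tile: dict[str, str],
                     morphotypes: list[MorphotypeSpec],
                     seed: int | np.random.Generator = 0,
                     ) -> tuple[list[Annotation], dict[str, float]]:
    """Poisson counts at class density, lognormal sizes; returns the
    annotations plus the realized per-tile truth biomass (g m^-2), computed
    with the same allometry the analysis LUT will apply."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    annotations: list[Annotation] = []
    truth: dict[str, float] = {}
    for tile in tiles:
        cls = class_of_tile[tile.id]
        mass_sum = 0.0
        for m in morphotypes:
            dens = m.density.get(cls, 0.0)
            if dens < 0:
                raise ValueError("negative density")
            k = rng.poisson(dens * tile.area)
            if k == 0:
                continue
            sizes = np.exp(rng.normal(m.log_size_mean, m.log_size_sd, size=k))
            for L in sizes:
                annotations.append(Annotation(tile_id=tile.id, morphotype=m.name,
                                              dimension_mm=float(L), count=1))
                mass_sum += m.a * float(L) ** m.b
        truth[tile.id] = mass_sum / tile.area
    return annotations, truth


def generator_lut(morphotypes: list[MorphotypeSpec]) -> MorphotypeLUT:
    lut = MorphotypeLUT()
    for m in morphotypes:
        lut[m.name] = m.lut_entry()
    return lut


# ---------------------------------------------------------------------------
# environment: turbidity + sediments

def make_environment(grid: BathymetryGrid, sites: np.ndarray | None,
                     config: GeneratorConfig,
                     seed: int | np.random.Generator = 0):
    """Turbidity records and sediment-core samples.

    Turbidity: baseline plus a BBL-only increment proportional to seabed
    elevation above the plain, plus noise. Sediments: mud/TN linear in
    depth, C/N constant (all plus noise), TOC = TN * C/N — giving the
    positive-with-depth trends for mud, TN and TOC and a trend-free C/N.

    Returns ``(turbidity, sediments)`` as pandas DataFrames.
    """
    import pandas as pd

    env = config.environment
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent

    # --- turbidity records ---------------------------------------------
    n = env.n_turbidity
    x = rng.uniform(xmin, xmax - 1e-9, size=n)
    y = rng.uniform(ymin, ymax - 1e-9, size=n)
    seabed = grid.interpolate_depth(x, y)
    elevation = np.maximum(env.plain_depth - seabed, 0.0)
    bbl = rng.random(n) < 0.5
    altitude = np.where(bbl, env.bbl_altitude, env.wc_altitude)
    ftu = np.full(n, env.ftu_baseline)
    ftu = np.where(bbl,
                   ftu * (1.0 + env.bbl_increment * elevation / env.elevation_ref),
                   ftu)
    ftu = ftu + rng.normal(0.0, env.ftu_noise, size=n)
    turbidity = pd.DataFrame({
        "x": x, "y": y, "ftu": ftu, "altitude": altitude,
        "depth": seabed - altitude, "seabed_depth": seabed,
    })

    # --- sediment sites -------------------------------------------------
    if sites is None:
        sites = _pick_sites(grid, env, rng)
    sites = np.asarray(sites, dtype=float)
    if not np.all(grid.contains(sites[:, 0], sites[:, 1])):
        raise ValueError("sediment site(s) outside raster extent")
    depth = grid.interpolate_depth(sites[:, 0], sites[:, 1])
    dd = depth - env.depth_ref
    mud = np.clip(env.mud_at_ref + env.mud_slope * dd
                  + rng.normal(0.0, env.mud_noise, size=len(depth)), 0.0, 100.0)
    tn = np.maximum(env.tn_at_ref + env.tn_slope * dd
                    + rng.normal(0.0, env.tn_noise, size=len(depth)), 1e-4)
    cn = env.cn_mean + rng.normal(0.0, env.cn_noise, size=len(depth))
    toc = tn * cn
    sediments = pd.DataFrame({
        "site": [f"site{i:02d}" for i in range(len(depth))],
        "x": sites[:, 0], "y": sites[:, 1], "depth": depth,
        "mud": mud, "tn": tn, "toc": toc, "cn": cn,
    })
    return turbidity, sediments


def _pick_sites(grid: BathymetryGrid, env: EnvironmentConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Random sites split between plain (> threshold+2 m) and elevated
    (< threshold-2 m) seabed, mirroring the published 9/12 design."""
    xmin, ymin, xmax, ymax = grid.extent
    thr = env.depth_ref
    plain_pts, elev_pts = [], []
    for _ in range(20000):
        if len(plain_pts) >= env.n_sites_plain and len(elev_pts) >= env.n_sites_elevated:
            break
        x = rng.uniform(xmin, xmax - 1e-9)
        y = rng.uniform(ymin, ymax - 1e-9)
        d = float(grid.interpolate_depth(x, y)[0])
        if d > thr + 2 and len(plain_pts) < env.n_sites_plain:
            plain_pts.append((x, y))
        elif d < thr - 2 and len(elev_pts) < env.n_sites_elevated:
            elev_pts.append((x, y))
    if len(plain_pts) < env.n_sites_plain or len(elev_pts) < env.n_sites_elevated:
        raise ValueError("could not place the requested sediment sites on this grid")
    return np.array(elev_pts + plain_pts)


# ---------------------------------------------------------------------------

def demo_config(seed: int = 0) -> GeneratorConfig:
    """A small, fast end-to-end demonstration configuration: one 70 m hill
    on a 6 x 6 km grid with a serpentine survey."""
    cfg = GeneratorConfig(
        hills=[HillSpec(center_x=3000.0, center_y=3000.0, height=70.0, radius=900.0)],
        grid_shape=(60, 60),
        track=TrackSpec(line_spacing=250.0, line_length=5000.0, n_lines=20,
                        image_spacing=20.0, x_start=500.0, y_start=600.0),
        seed=seed,
    )
    cfg.morphotypes = tune_densities(default_morphotypes(), cfg.class_biomass)
    return cfg
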