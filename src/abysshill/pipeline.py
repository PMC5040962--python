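"""End-to-end pipeline driver: simulate -> terrain -> pom -> biomass ->
stats -> report, with a run manifest for reproducibility.

Each stage reads its inputs from, and writes versioned CSV/raster outputs
to, a single output directory; rerunning with the same configuration and
seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import aggregation, biomass as bm, nullmodel, pom, sediments, stats, synthetic, terrain
from .grids import BathymetryGrid, read_ascii_grid, write_ascii_grid

log = logging.getLogger("abysshill")

STAGES = ("simulate", "terrain", "pom", "biomass", "stats", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "render_images": True,
    "generator": {},                 # overrides for synthetic.demo_config
    "terrain": {"inner_radius_m": 200.0, "outer_radius_m": 1000.0,
                "depth_band_min_n": 50},
    "segmentation": {},
    "thresholds": {"min_images": 50, "min_tiles": 5,
                   "elevation_threshold_m": 4840.0},
    "null_model": {"z_ref_m": 4850.0, "z_hill_m": 4780.0},
    "lut": None,                     # path to LUT YAML; None -> generator LUT
    "tile_group_size": 10,
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _generator_config(cfg: dict) -> synthetic.GeneratorConfig:
    g = synthetic.demo_config(seed=int(cfg["seed"]))
    over = cfg.get("generator") or {}
    for key, val in over.items():
        if key == "hills":
            g.hills = [synthetic.HillSpec(**h) for h in val]
        elif key == "track":
            g.track = synthetic.TrackSpec(**{**g.track.__dict__, **val})
        elif key == "render":
            d = {**g.render.__dict__, **val}
            d["size"] = tuple(d["size"])
            g.render = synthetic.RenderParams(**d)
        elif key == "environment":
            g.environment = synthetic.EnvironmentConfig(
                **{**g.environment.__dict__, **val})
        elif key == "grid_shape":
            g.grid_shape = tuple(val)
        elif hasattr(g, key):
            setattr(g, key, val)
        else:
            raise KeyError(f"unknown generator option {key!r}")
    g.morphotypes = synthetic.tune_densities(synthetic.default_morphotypes(),
                                             g.class_biomass)
    return g


def _terrain_rasters(grid: BathymetryGrid, cfg: dict) -> dict[str, np.ndarray]:
    t = cfg["terrain"]
    return {
        "slope": terrain.compute_slope(grid),
        "rugosity": terrain.compute_rugosity(grid),
        "curvature": terrain.compute_curvature(grid),
        "bpi": terrain.compute_bpi(grid, t["inner_radius_m"], t["outer_radius_m"]),
    }


def _classify(rasters: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = dict(rasters)
    out["primary"] = terrain.classify_primary(rasters["bpi"], rasters["slope"])
    out["secondary"] = terrain.classify_secondary(rasters["bpi"], rasters["slope"])
    return out


def _image_classes(images, grid, primary) -> np.ndarray:
    row, col = grid.locate(np.array([im.x for im in images]),
                           np.array([im.y for im in images]))
    cls = primary[row, col]
    # survey lines may cross cells where BPI is undefined near the grid
    # edge; treat those as plain background terrain
    cls[cls == None] = "Plain"  # noqa: E711
    return cls


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: dict, outdir: Path) -> None:
    g = _generator_config(cfg)
    rng = np.random.default_rng(int(cfg["seed"]))
    grid = synthetic.make_bathymetry(g)
    write_ascii_grid(grid, outdir / "bathymetry.asc")

    rasters = _classify(_terrain_rasters(grid, cfg))
    images = synthetic.make_survey(grid, g)
    classes = _image_classes(images, grid, rasters["primary"])

    meta_rows = []
    img_dir = outdir / "images"
    if cfg["render_images"]:
        img_dir.mkdir(exist_ok=True)
    for im, cls in zip(images, classes):
        total = g.class_total_cover[cls]
        light = total * g.light_fraction
        dark = total - light
        row = {"id": im.id, "x": im.x, "y": im.y, "depth": im.depth,
               "altitude": im.altitude, "footprint_area": im.footprint_area,
               "terrain_class": cls, "true_light": np.nan, "true_dark": np.nan,
               "true_total": np.nan}
        if cfg["render_images"]:
            rgb, truth = synthetic.render_image(light, dark, g.render, rng)
            Image.fromarray(rgb).save(img_dir / f"{im.id}.png")
            row.update(true_light=truth.light_cover, true_dark=truth.dark_cover,
                       true_total=truth.total_cover)
        meta_rows.append(row)
    pd.DataFrame(meta_rows).to_csv(outdir / "image_metadata.csv", index=False)

    tiles = bm.mosaic_tiles(images, group_size=int(cfg["tile_group_size"]))
    trow, tcol = grid.locate(np.array([t.x for t in tiles]),
                             np.array([t.y for t in tiles]))
    tile_cls = rasters["primary"][trow, tcol]
    tile_cls[tile_cls == None] = "Plain"  # noqa: E711
    class_of_tile = {t.id: c for t, c in zip(tiles, tile_cls)}
    annotations, truth = synthetic.make_annotations(tiles, class_of_tile,
                                                    g.morphotypes, rng)
    pd.DataFrame([{"tile_id": a.tile_id, "morphotype": a.morphotype,
                   "dimension_mm": a.dimension_mm, "count": a.count}
                  for a in annotations]).to_csv(outdir / "annotations.csv",
                                                index=False)
    pd.DataFrame([{"tile_id": t.id, "x": t.x, "y": t.y, "depth": t.depth,
                   "area": t.area, "terrain_class": class_of_tile[t.id],
                   "true_biomass": truth[t.id],
                   "image_ids": ";".join(t.image_ids)} for t in tiles]
                 ).to_csv(outdir / "tiles.csv", index=False)
    synthetic.generator_lut(g.morphotypes).to_yaml(outdir / "lut.yaml")

    turbidity, seds = synthetic.make_environment(grid, None, g, rng)
    turbidity.to_csv(outdir / "turbidity.csv", index=False)
    seds.to_csv(outdir / "sediments.csv", index=False)


def stage_terrain(cfg: dict, outdir: Path) -> None:
    grid = read_ascii_grid(outdir / "bathymetry.asc")
    rasters = _classify(_terrain_rasters(grid, cfg))
    for name in ("slope", "rugosity", "curvature", "bpi"):
        write_ascii_grid(BathymetryGrid(np.nan_to_num(rasters[name], nan=-9999.0),
                                        grid.cell_size, grid.origin),
                         outdir / f"{name}.asc")
    codes = {name: i for i, name in enumerate(terrain.SECONDARY_CLASSES, start=1)}
    (outdir / "class_legend.json").write_text(json.dumps(codes, indent=2))
    nrow, ncol = grid.shape
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    pd.DataFrame({
        "row": rr.ravel(), "col": cc.ravel(),
        "depth": grid.depths.ravel(),
        "bpi": rasters["bpi"].ravel(), "slope": rasters["slope"].ravel(),
        "rugosity": rasters["rugosity"].ravel(),
        "curvature": rasters["curvature"].ravel(),
        "primary": rasters["primary"].ravel(),
        "secondary": rasters["secondary"].ravel(),
    }).to_csv(outdir / "terrain_cells.csv", index=False)


def stage_pom(cfg: dict, outdir: Path) -> None:
    meta = pd.read_csv(outdir / "image_metadata.csv")
    params = pom.SegmentationParams(**(cfg.get("segmentation") or {}))
    img_dir = outdir / "images"
    rows = []
    for rec in meta.itertuples():
        path = img_dir / f"{rec.id}.png"
        if not path.exists():
            raise FileNotFoundError(
                f"image {path} missing; run simulate with render_images: true")
        pixels = np.asarray(Image.open(path).convert("RGB"))
        res = pom.pom_cover(pom.segment_pom(pixels, params), image_id=rec.id)
        rows.append({"image_id": rec.id, "x": rec.x, "y": rec.y,
                     "depth": rec.depth, "light_cover": res.light_cover,
                     "dark_cover": res.dark_cover,
                     "total_cover": res.total_cover,
                     "n_light_objects": res.n_light_objects,
                     "n_dark_objects": res.n_dark_objects})
    pd.DataFrame(rows).to_csv(outdir / "pom.csv", index=False)


def stage_biomass(cfg: dict, outdir: Path) -> None:
    lut_path = Path(cfg["lut"]) if cfg.get("lut") else outdir / "lut.yaml"
    if not lut_path.exists():
        raise FileNotFoundError(
            f"morphotype LUT not found at {lut_path}; supply 'lut' in the "
            "config or run the simulate stage first")
    lut = bm.MorphotypeLUT.from_yaml(lut_path)
    tiles_df = pd.read_csv(outdir / "tiles.csv")
    ann_df = pd.read_csv(outdir / "annotations.csv")
    anns = [bm.Annotation(r.tile_id, r.morphotype, r.dimension_mm, int(r.count))
            for r in ann_df.itertuples()]
    by_tile: dict[str, list] = {}
    for a in anns:
        by_tile.setdefault(a.tile_id, []).append(a)
    rows = []
    for r in tiles_df.itertuples():
        tile = bm.Tile(r.tile_id, r.image_ids.split(";"), r.area, r.x, r.y, r.depth)
        tb = bm.tile_biomass(by_tile.get(tile.id, []), tile, lut)
        row = {"tile_id": tile.id, "x": tile.x, "y": tile.y,
               "depth": tile.depth, "area": tile.area,
               "biomass": tb.biomass, "density": tb.density}
        for ft, val in tb.by_feeding_type.items():
            row[f"biomass_{ft.replace('/', '_')}"] = val
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "tile_biomass.csv", index=False)


def _class_summary(df: pd.DataFrame, value: str, by: str) -> pd.DataFrame:
    g = df.groupby(by)[value]
    out = g.agg(["count", "mean", "std"]).rename(columns={"count": "n"})
    half = 1.96 * out["std"] / np.sqrt(out["n"])
    out["ci_lo"] = out["mean"] - half
    out["ci_hi"] = out["mean"] + half
    return out.reset_index()


def stage_stats(cfg: dict, outdir: Path) -> None:
    grid = read_ascii_grid(outdir / "bathymetry.asc")
    rasters = _classify(_terrain_rasters(grid, cfg))
    pom_df = pd.read_csv(outdir / "pom.csv") if (outdir / "pom.csv").exists() else None
    bio_df = pd.read_csv(outdir / "tile_biomass.csv")
    thr = cfg["thresholds"]
    cells = aggregation.summarise_cells(pom_df, bio_df, rasters, grid,
                                        min_images=thr["min_images"],
                                        min_tiles=thr["min_tiles"])
    cells.to_csv(outdir / "cells.csv", index=False)

    min_n = cfg["terrain"]["depth_band_min_n"]
    summaries = []
    welch_rows, gh_rows = [], []

    def _attach(df, value):
        row, col = grid.locate(df["x"].to_numpy(), df["y"].to_numpy())
        df = df.assign(primary=rasters["primary"][row, col],
                       secondary=rasters["secondary"][row, col])
        df = df[df["primary"].notna()]
        df["depth_band"] = terrain.assign_depth_bands(
            df["depth"].to_numpy(), min_n=min_n)
        for by in ("depth_band", "primary", "secondary"):
            s = _class_summary(df, value, by)
            s.insert(0, "grouping", by)
            s.insert(0, "variable", value)
            s = s.rename(columns={by: "group"})
            summaries.append(s)
        return df

    datasets = []
    if pom_df is not None:
        pdf = _attach(pom_df, "total_cover")
        pdf["transformed"] = pom.logit_transform(pdf["total_cover"].to_numpy(),
                                                 n=10_000)
        datasets.append(("pom", pdf))
    bdf = _attach(bio_df, "biomass")
    bdf["transformed"] = bm.log_transform(bdf["biomass"].to_numpy())
    datasets.append(("biomass", bdf))

    for name, df in datasets:
        groups = {cls: sub["transformed"].to_numpy()
                  for cls, sub in df.groupby("primary") if len(sub) >= 2}
        if len(groups) >= 2:
            wa = stats.welch_anova(groups)
            lv = stats.levene(groups)
            welch_rows.append({"dataset": name, "welch_F": wa.statistic,
                               "welch_df1": wa.df[0], "welch_df2": wa.df[1],
                               "welch_p": wa.p, "levene_W": lv.statistic,
                               "levene_p": lv.p})
            for res in stats.games_howell(groups):
                gh_rows.append({"dataset": name, **res.extra,
                                "t": res.statistic, "df": res.df, "p": res.p,
                                "diff": res.effect_size,
                                "ci_lo": res.ci[1], "ci_hi": res.ci[2]})

    pd.concat(summaries).to_csv(outdir / "table1.csv", index=False)
    pd.DataFrame(welch_rows).to_csv(outdir / "anova.csv", index=False)
    pd.DataFrame(gh_rows).to_csv(outdir / "games_howell.csv", index=False)

    seds = pd.read_csv(outdir / "sediments.csv")
    sediments.sediment_report(
        seds, threshold=thr["elevation_threshold_m"]).to_csv(
        outdir / "table2.csv", index=False)
    turb = pd.read_csv(outdir / "turbidity.csv")
    layered = aggregation.layer_turbidity(turb, min_n=min_n)
    sediments.turbidity_summary(layered).to_csv(outdir / "turbidity_summary.csv",
                                                index=False)


def stage_report(cfg: dict, outdir: Path) -> None:
    table1 = pd.read_csv(outdir / "table1.csv")
    nm = cfg["null_model"]
    z_ref, z_hill = float(nm["z_ref_m"]), float(nm["z_hill_m"])
    rows = []
    for variable, factor_fn in (("total_cover", nullmodel.flux_factor),
                                ("biomass", nullmodel.biomass_factor)):
        sub = table1[(table1["variable"] == variable)
                     & (table1["grouping"] == "primary")]
        means = dict(zip(sub["group"], sub["mean"]))
        if "Plain" not in means:
            continue
        observed = nullmodel.normalise_to_plain(means, "Plain")
        predicted = {cls: factor_fn(z_ref, z_ref if cls == "Plain" else z_hill)
                     for cls in means}
        cmp = nullmodel.observed_vs_predicted(observed, predicted)
        cmp.insert(0, "variable", variable)
        rows.append(cmp)
    report = pd.concat(rows) if rows else pd.DataFrame()
    report.to_csv(outdir / "observed_vs_predicted.csv", index=False)
    lines = ["observed vs depth-only predicted enhancement factors",
             report.to_string(index=False)]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")


_STAGE_FN = {"simulate": stage_simulate, "terrain": stage_terrain,
             "pom": stage_pom, "biomass": stage_biomass,
             "stats": stage_stats, "report": stage_report}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | Path | None, outdir: str | Path,
                 stages=STAGES) -> dict:
    """Run pipeline stages in order and write a run manifest.

    Returns the manifest dict (config hash, seed, per-file checksums). A
    failing stage aborts with the stage named.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        t0 = time.perf_counter()
        try:
            _STAGE_FN[stage](cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)
    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": int(cfg["seed"]),
        "files": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
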