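# abysshill

Analysis pipeline linking modest abyssal-hill topography to seafloor
phytodetritus (POM) cover and megafauna biomass, with a synthetic survey
generator so every stage is testable end-to-end with known ground truth.

Components (one module per stage, `src/abysshill/`):

- `synthetic` — bathymetry (plain + Gaussian hills), boustrophedon AUV
  survey tracks, rendered seabed photographs with exact per-pixel class
  masks, Poisson/lognormal megafauna annotations with analytic expected
  biomass, depth-trended turbidity and sediment cores.
- `terrain` — slope (Horn), rugosity (surface/planar area ratio), profile
  curvature (Zevenbergen–Thorne), bathymetric position index (BPI) in an
  annulus neighbourhood, primary (Hill/Slope/Plain) and 12-class secondary
  terrain classification, 12.5 m depth bands with terminal amalgamation.
  BPI is computed on positive-down depth, so hill crests are *negative*.
- `pom` — illumination crop, robust colour segmentation into light/dark
  POM classes with an object-area filter, percent cover, logit transform.
- `biomass` — 10-image tile mosaicking, allometric mass (`a·L^b`) from a
  morphotype lookup table, tile biomass by feeding type, log transform.
- `aggregation` — geolocation of records into 100 m grid cells with
  minimum-count filters (≥50 images, ≥5 tiles), crest distance, turbidity
  layering (BBL = altitude ≤ 10 m).
- `stats` — Welch ANOVA, Games–Howell, Cohen's d, Brown–Forsythe Levene,
  Spearman and partial Spearman, Mood's median test, Wilcoxon signed-rank
  median confidence intervals with achieved levels, trend lines,
  empirical variograms.
- `nullmodel` — depth-only predictions: POM flux ∝ Z^−0.7 (Z in m) and
  biomass ∝ 10^(−0.4 Z) (Z in km); normalisation to the plain and the
  observed-vs-predicted contrast.
- `sediments` — sediment-core medians/CIs, depth correlations,
  plain-vs-elevated contrasts; per-band turbidity summaries.
- `pipeline` / `cli` — YAML-configured driver with a checksum manifest;
  reruns are byte-identical for a fixed seed.

## CLI

```sh
abysshill all --config examples/config.yaml --outdir runs/demo
# or stage by stage:
abysshill simulate --config examples/config.yaml --outdir runs/demo
abysshill terrain  --config examples/config.yaml --outdir runs/demo
abysshill pom      --config examples/config.yaml --outdir runs/demo
abysshill biomass  --config examples/config.yaml --outdir runs/demo
abysshill stats    --config examples/config.yaml --outdir runs/demo
abysshill report   --config examples/config.yaml --outdir runs/demo
```

Outputs per run directory: `bathymetry.asc`, terrain rasters and
`terrain_cells.csv`, `image_metadata.csv` + `images/*.png`, `pom.csv`,
`tiles.csv`/`annotations.csv`/`tile_biomass.csv`, grid-cell summaries
(`cells.csv`), class/depth-band summary tables (`table1.csv`), ANOVA and
pairwise-comparison tables, sediment (`table2.csv`) and turbidity
summaries, the observed-vs-predicted report, and `manifest.json` with a
config hash and per-file checksums.

`abysshill terrain-rasters <grid.asc> --outdir out --inner 400 --outer 1200`
computes terrain products for an existing bathymetry grid.

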