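# Demonstration pipeline configuration.
#
#   abysshill all --config examples/config.yaml --outdir runs/demo
#
# Generates a 6 x 6 km synthetic survey (100 m bathymetric cells, one 70 m
# Gaussian hill), renders seabed images with known POM ground truth,
# and runs terrain classification, segmentation, biomass estimation,
# statistics and the observed-vs-predicted report.

seed: 1
render_images: true
tile_group_size: 10

generator:
  plain_depth: 4850.0
  grid_shape: [60, 60]
  cell_size: 100.0
  hills:
    - {center_x: 3000.0, center_y: 3000.0, height: 70.0, radius: 900.0}
  track:
    line_spacing: 250.0
    line_length: 5000.0
    n_lines: 20
    image_spacing: 20.0
    altitude: 3.2
    footprint_area: 1.6
  render:
    size: [160, 160]
  class_total_cover: {Hill: 45.4, Slope: 44.7, Plain: 43.4}
  class_biomass: {Hill: 5.2, Slope: 3.4, Plain: 2.1}
  environment:
    n_turbidity: 4000

terrain:
  inner_radius_m: 200.0   # scaled to the demo hill; survey-scale default 400
  outer_radius_m: 1000.0  # survey-scale default 1200
  depth_band_min_n: 50

segmentation:
  k_light: 2.5
  k_dark: 2.5
  min_object_area: 9

thresholds:
  min_images: 50
  min_tiles: 5
  elevation_threshold_m: 4840.0

null_model:
  z_ref_m: 4850.0
  z_hill_m: 4780.0

# path to a morphotype LUT YAML; omit to use the generator's own table
lut: null
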