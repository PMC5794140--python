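# Full synthetic-pipeline configuration (all keys shown with defaults).
seed: 1
output_dir: sepmap_out

synthetic:
  layout:
    shape: [300, 300]        # pixels (30 m each -> 9 x 9 km study area)
    pixel_size: 30.0
    n_villages: 6
    # target landscape composition; the remainder is bare soil
    class_fractions:
      field: 0.50
      shrubland: 0.29
      depression: 0.06
      forest: 0.005
      homestead: 0.028
      water: 0.002
      urban: 0.005
  signatures:
    stds: 0.01               # per-band reflectance noise (set 0 for a noise-free control)
  transects:
    n_transects: 27
    length_m: 3000.0
    spacing_m: 100.0         # a GPS stop every 100 m
    gps_noise_m: 5.0
  calibration_pixels_per_class: 30

classifier:
  m_threshold: 1.0           # minimum M separability to accept a tree split
  # class_order: [water, forest, shrubland, field, bare_soil]
  # tree_file: my_tree.yaml  # skip derivation and use a hand-edited tree

benefits:
  n_zones: 5
  zone_width_m: 500.0
  w_near: 1.2
  w_far: 0.8
  shrub_breakpoints: [0.02, 0.10, 0.25, 0.40]
  shrub_weights: [0.8, 1.0, 1.2, 1.1, 0.9]
  # score_table: my_scores.yaml

accuracy:
  buffer_m: 15.0
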