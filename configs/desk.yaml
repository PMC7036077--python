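# Desk-scale profile: small rasters and networks so the full pipeline runs
# on one CPU in minutes. Same stages and loss functions as the full-scale
# profile; only the sizes differ.
profile: desk
phantom:
  n_cases: 12
  image_height_px: 320
  image_width_px: 160
  seed: 0
preprocess:
  output_spacing_mm: 8.0   # 2000 mm head-to-toe -> 250 px
  crop_width: 128
networks:
  skeleton:
    depth: 3
    base_channels: 4
    input_shape: [96, 48]
    use_dsv: true
  hotspot:
    depth: 2
    base_channels: 6
    input_shape: [64, 64]
    use_residual: true
training:
  skeleton:
    batch_size: 4
    max_iterations: 1100
    alpha_decay_iteration: 900
    eval_every: 100
    seed: 1
  hotspot:
    batch_size: 8
    max_iterations: 900
    eval_every: 100
    seed: 2
inference:
  target_sensitivity: 0.9
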