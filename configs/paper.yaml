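# Full-scale profile: the reference protocol's raster sizes and schedules
# (512x1024 inputs, batch 6 / 1620 iterations for skeleton segmentation
# with step decay at 1350, batch 256 / 50000 iterations for hot spots).
# Not exercised by the test suite; training at this scale needs GPU-class
# hardware.
profile: paper
phantom:
  n_cases: 246
  image_height_px: 1024
  image_width_px: 512
  seed: 0
preprocess:
  output_spacing_mm: 2.0   # 2000 mm head-to-toe -> 1000 px
  crop_width: 384
networks:
  skeleton:
    depth: 4
    base_channels: 32
    input_shape: [1024, 384]
    use_dsv: true
  hotspot:
    depth: 3
    base_channels: 32
    input_shape: [64, 64]
    use_residual: true
training:
  skeleton:
    batch_size: 6
    max_iterations: 1620
    alpha_decay_iteration: 1350
    eval_every: 30
    seed: 1
  hotspot:
    batch_size: 256
    max_iterations: 50000
    eval_every: 500
    seed: 2
inference:
  target_sensitivity: 0.9
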