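# Desk-scale pipeline run: small grid, small network, minutes on one CPU.
phantom:
  grid_shape: [32, 32, 16]
  voxel_size_mm: 2.0
  cortical_suvr_neg: 1.0
  cortical_suvr_pos: 1.6
  wm_suvr: 1.7
  noise_cv: 0.05
  between_subject_sd: 0.05
cohort:
  n_neg: 20
  n_pos: 12
  test_n_neg: 4
  test_n_pos: 3
cnn:
  conv_filters: [8, 8, 16, 16]
  kernel_size: 3
  dropout_rate: 0.6
  learning_rate: 1.0e-5
  lr_decay: 1.0e-6
  epochs: 150
  rng_seed: 0
cv:
  k: 5
seed: 0
suvr_window_min: [50, 70]
# augment:                  # off by default; enable for orientation jitter
#   max_rotation_deg: 10
#   max_shift_frac: 0.1
#   max_shear: 0.1
#   max_zoom_frac: 0.1
#   flip_lr: true
#   rng_seed: 0
render_cams: true
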