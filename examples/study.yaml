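# Desk-scale sparse-view restoration study (about 20 minutes on one CPU):
# 200 disk phantoms in a 256-element ring, keep 1/8 of the elements,
# train the noise estimator and restore the held-out test images.
n_phantoms: 200
phantom_kind: disks
grid_px: 32
spacing_mm: 0.6
mode: sparse          # or "limited" with param in radians
param: 32
geometry:
  radius_mm: 40.0
  n_elements: 256
  coverage_rad: 6.283185307179586
  start_angle_rad: 0.0
  speed_of_sound_m_s: 1500.0
  sampling_rate_mhz: 62.5
  n_samples: null
filter:
  order: 3
  band_mhz: [0.5, 10.0]
network:
  base_channels: 16
  blocks_per_level: [1, 1, 1, 1, 1]
  heads_per_level: [1, 2, 4, 8, 1]
  gcfn_expansion: 2.66
  time_embed_dim: 32
  input_channels: 2
training:
  max_steps: 5000
  batch_size: 2
  lr: 3.0e-05
  betas: [0.9, 0.99]
  T: 100
  lam: 50.0
  schedule_kind: constant
  seed: 0
  log_every: 250
  checkpoint_every: 0
fractions: [0.8, 0.1, 0.1]
sampling_steps: 0
sampling_stochastic: false
seed: 7
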