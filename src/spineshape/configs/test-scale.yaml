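# CI-sized settings: a 30-subject phantom cohort at ~1.3k surface points
# and 60 synthetic subjects.  Completes on one CPU in minutes while
# exercising every stage with the same statistical defaults as the full
# configuration (2 SD bounds, 1000 bootstrap iterations, 1024 coalitions).
phantom:
  t: 30
  p: 1300
  latent_dim: 4
  noise_sd: 0.05
  size_sd: 0.04
ssm:
  kaiser_factor: 0.7
  specificity_samples: 100
power:
  rho2: 0.15
  alpha: 0.05
  power: 0.95
  model: random
sampling:
  n_samples: 60
  sd_range: 2.0
  criterion: correlation_min
morphing:
  n_control_points: 200
  regularisation: 0.0
mechanics:
  total_force: 400.0
  min_scaled_jacobian: 0.05
uq:
  iterations: 1000
  level: 0.95
sensitivity:
  n_coalitions: 1024
  significance_level: 0.05
seed: 0
output_dir: pipeline_out
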