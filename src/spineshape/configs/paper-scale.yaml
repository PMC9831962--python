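# Full study-scale settings: 152 training subjects at ~14k surface points,
# 500 synthetic subjects bounded at +-2 SD, 1000 TPS control points,
# 1000 bootstrap iterations, 1024 SHAP coalitions, 400 N axial load.
# Runnable, but slow on a single CPU.
phantom:
  t: 152
  p: 14015
  latent_dim: 4
  noise_sd: 0.05
  size_sd: 0.04
ssm:
  kaiser_factor: 0.7
  specificity_samples: 500
power:
  rho2: 0.15
  alpha: 0.05
  power: 0.95
  model: random
sampling:
  n_samples: 500
  sd_range: 2.0
  criterion: correlation_min
morphing:
  n_control_points: 1000
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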