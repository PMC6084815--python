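seed: 1
output_dir: twinmeth_demo
simulation:
  n_mz: 100
  n_dz: 80
  n_sites: 200
  a_true: 0.25
  c_true: 0.15
  e_true: 0.60
  mu_beta: [0.1, 0.9]
  total_sd: [0.01, 0.07]
  scale_mode: linear-clip
  mqtl:
    fraction: 0.1
    maf: 0.2
    effect_per_allele: 0.05
  exposure:
    p_exposed: 0.3
    concordance: 1.0
    effect: -0.1
    n_affected_sites: 5
thresholds:
  variable: 0.05
  intermediate_low: 0.20
  intermediate_high: 0.80
  a_high: 0.8
  covariation_cutoff: 0.5
  dmp: 1.0e-7
ace:
  method: fiml
ewas:
  exposure: exposed
  adjustments: [sex]
profile:
  window_bp: 500
  step_bp: 100
  min_n: 5
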