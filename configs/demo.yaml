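# Demo study: two small RI panels, four treatments, planted effects.
# Runs end to end in well under a minute:
#   qtlact run --config configs/demo.yaml --out-dir runs/demo
seed: 11

simulation:
  n_strains: [20, 20]
  n_markers: [200, 200]
  n_expression_traits: 50
  n_cis: 10
  n_syntenic_trans: 4
  n_nonsyntenic_trans: 12
  n_snps: 2000
  breakpoint_rate: 0.02
  sigma: 1.0
  effect_sizes: [2.0, 3.0]

mapping:
  n_perm: 200
  fdr_target: 0.05
  # uncomment to replicate-style fix the panel thresholds instead of
  # recomputing them by permutation:
  # thresholds: {LXS: 24, BXD: 26}

conservation:
  window_mb: 50
  step_mb: 5

network:
  prefilter_lrs: 20
  include_r: 0.7
  edge_r: 0.8
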