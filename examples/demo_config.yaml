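# End-to-end demo on synthetic data with a planted 10-gene hotspot.
# Run:  expmods run-all --config examples/demo_config.yaml --out demo_run
seed: 7
output_dir: demo_run
synthetic:
  enabled: true
  expression:
    n_genes: 300
    n_case: 7
    n_control: 5
    effect_size: 4.0
    noise_sd: 1.0
  network:
    n_nodes: 300
    planted_module_size: 10
    planted_internal_density: 0.9
  validation:
    concordant_frac: 0.8
hotspot:
  n_seeds: 10
  gamma: 2.0        # resolution matched to the 10-gene planted scale
  n_perm: 400
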