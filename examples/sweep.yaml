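# Optimal-ratio search: smallest E/T controlling net growth over 18 h.
seed: 1
out_dir: results/sweep
simulation:
  line: melanoma
  duration_h: 18.0
  initial_targets: 1000
scenario:
  kind: sweep
  ratio_min: 0.5
  ratio_max: 1.0
  step: 0.005
  n_runs: 20
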