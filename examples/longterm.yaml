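# Multi-day trajectories at several E/T ratios (population cap guards runaway growth).
seed: 1
out_dir: results/longterm
simulation:
  line: melanoma
  duration_h: 360.0
  initial_targets: 200
  population_cap: 50000
scenario:
  kind: longterm
  et_ratios: [1.0, 4.0, 16.0]
  n_runs: 5
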