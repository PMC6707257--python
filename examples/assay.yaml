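# Killing assay over the calibration E/T grid, both measures recorded.
seed: 1
out_dir: results/assay
simulation:
  line: conventional
  duration_h: 18.0
  initial_targets: 500
scenario:
  kind: assay
  et_ratios: [0.01, 0.05, 0.1, 0.5, 1.0]
  n_runs: 10
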