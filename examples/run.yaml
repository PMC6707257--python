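# One 18 h melanoma co-culture at E/T 0.6, repo-default calibrated params.
seed: 7
out_dir: results/run
simulation:
  line: melanoma
  duration_h: 18.0
  initial_targets: 1000
  et_ratio: 0.6
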