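# Three equal CTL cohorts at 4 h spacing vs a single matched bolus.
seed: 1
out_dir: results/sequential
simulation:
  line: melanoma
  duration_h: 18.0
  initial_targets: 600
scenario:
  kind: sequential
  bolus_total: 240
  schedules:
    - [[0.0, 80], [4.0, 80], [8.0, 80]]
  n_runs: 20
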