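# ctlsim

Agent-based simulator of human cytotoxic T lymphocyte (CTL) / tumor target
cell co-cultures in a virtual 2-D culture well, with:

- off-lattice cell mechanics (mass-spring-damper adhesions, collisions,
  Brownian CTL motility, centrifugation-style initialization),
- the two agent state machines — target cells (G1/S–G2/M cycling, defense
  state, survival-duration depletion, division) and CTL (search, attack,
  permanent probabilistic inactivation near defending targets),
- per-capita killing analytics (k_ctl = n_kt / n_ctl), kill-count
  repartition histograms, temporal per-capita tracking, exact/approximate
  Wilcoxon rank-sum comparisons,
- scenario protocols: killing assays across E/T ratios, optimal-ratio
  sweeps, multi-day runs, sequential CTL-cohort addition vs a single bolus,
- calibration: cell-cycle fitting from growth counts and exhaustive
  (R_d, P_d) grid search against reference killing curves, plus a synthetic
  reference-fixture generator for end-to-end parameter-recovery tests.

Units: micrometres and minutes internally; hours at the config/CLI surface.

## CLI

All subcommands accept `--config <yaml>`, `--seed`, `--out`, `--runs`,
`--quiet/--verbose`:

```sh
ctlsim simulate   --config examples/run.yaml --seed 7 --out results/
ctlsim assay      --config examples/assay.yaml          # killing curve vs E/T
ctlsim sweep      --config examples/sweep.yaml          # optimal-ratio search
ctlsim longterm   --config examples/longterm.yaml       # multi-day trajectories
ctlsim sequential --config examples/sequential.yaml     # cohorts vs bolus + rank-sum
ctlsim calibrate  --reference ref.csv --growth growth.csv
ctlsim fixture    --seed 1 --out fixtures/              # synthetic reference data
```

Outputs are CSV/JSON(-lines) with a provenance header (software version,
parameter digest, seed). See `examples/` for annotated configs.

## Package layout

```
src/ctlsim/
  params.py       parameter records, validation, calibrated defaults
  mechanics.py    2-D overdamped mechanics, contacts, neighbor queries
  agents.py       per-agent reference semantics of both state machines
  engine.py       vectorized world state, main loop, cohort scheduling
  scenarios.py    assay / sweep / long-term / sequential protocols
  calibration.py  growth fitting and (R_d, P_d) grid search
  analysis.py     per-capita stats, repartition, rank-sum test
  config.py       YAML config round-tripping (hours at the interface)
  fixtures.py     synthetic reference killing curves & growth series
  cli.py          click CLI
```
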