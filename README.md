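# cohortcua

A Markov cohort cost-utility analysis pipeline for comparing an active
maintenance strategy against supportive care alone, built around:

- **Parametric survival extrapolation** (`cohortcua.survival`): exponential,
  Weibull, log-logistic, lognormal and Gompertz families; right-censored
  maximum-likelihood fitting of pseudo individual-patient data; AIC/BIC model
  selection; per-cycle event probabilities. The log-logistic law uses the
  scale-rate form `S(t) = 1 / (1 + lam * t**gam)` with time in 21-day cycles.
- **Four-state cohort engine** (`cohortcua.cohort`): progression-free with /
  without adverse events, progressed disease, death. State occupancy is read
  from the progression-free and overall survival curves (partitioned
  survival), with life-table background mortality, half-cycle correction and
  annual discounting.
- **Economics** (`cohortcua.economics`): drug-regimen costing with
  tablet/vial wastage, one-off adverse-event expectations, discounted
  cost/QALY/LY accrual, and incremental indices (ICUR, ICER, INMB, INHB).
- **Sensitivity analyses** (`cohortcua.sensitivity`): one-way ±20% tornado
  analysis, probabilistic Monte Carlo over Beta/Gamma parameter
  distributions, and cost-effectiveness acceptability curves.
- **Subgroups** (`cohortcua.subgroups`): hazard-ratio adjustment
  `S(t)**HR` of the treated arm's progression curve, with net-health-benefit
  ranges over the HR interval.
- **Synthetic inputs** (`cohortcua.synth`): inverse-CDF pseudo-IPD
  simulation with administrative and random censoring, Kaplan-Meier
  estimation, a Gompertz-Makeham life-table fixture, and the complete
  baseline configuration (all parameter values, ranges and distributions).

## Command-line usage

```bash
# emit the baseline config, life table and simulated pseudo-IPD
cohortcua simulate --out work/ --seed 1

# fit all five survival families to a pseudo-IPD CSV (time_cycles,event)
cohortcua fit --ipd work/ipd_bsc_pfs.csv --out work/

# base case: state traces, per-cycle ledgers, economics summary JSON
cohortcua run --config work/config.yaml --out work/

# tornado, probabilistic analysis + acceptability curve, subgroup table
cohortcua owsa --config work/config.yaml --out work/ --top 20
cohortcua psa  --config work/config.yaml --out work/ --draws 10000 --seed 20220801
cohortcua subgroups --config work/config.yaml --out work/
```

Each run writes a `manifest.json` (config hash, seed, version, emitted
files). Identical config and seed give byte-identical CSV/JSON outputs.

## Configuration

The configuration is one YAML/JSON mapping (see `cohortcua.synth.
baseline_fixture()` for the fully populated default). Uncertain parameters
are addressed by dot-paths (e.g. `drug_costs.capecitabine`); the
`distributions` list attaches Beta/Gamma sampling laws and the `owsa` list
attaches one-way bounds. At load time every distribution's analytic mean is
audited against its baseline; Gamma rates printed with too few decimals are
recalibrated to `shape / baseline` (disable with
`assumptions.recalibrate_distribution_rates: false`). Modelling defaults
that are not published values (unit sizes, imaging interval, subsequent-
therapy regimens and cap, life-table parameters) live under `assumptions.*`.

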