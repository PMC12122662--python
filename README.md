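# copdcea

Economic evaluation toolkit for a COPD early-warning self-management
intervention versus usual care, from the UK NHS perspective. It implements
two linked analyses:

- **Within-trial cost-utility / cost-effectiveness analysis** — trapezoidal
  QALY accrual from EQ-5D utilities, chained multiple imputation of missing
  follow-up data, seemingly-unrelated-regression (FGLS) adjusted incremental
  costs and effects, non-parametric bootstrap ICERs, CEACs, and cost per
  hospitalisation averted.
- **Five-year Markov cohort model** — monthly cycles over GOLD stages A–D
  (or the merged A/B/E variant), three-month post-discharge tunnel states
  with a utility decrement, death on admission, four treatment effects
  (improved 12-month starting states, beneficial-transition adjustment with
  an annually halving effect, exacerbation-rate reductions, bed-day savings
  per admission), 3.5% annual discounting, probabilistic sensitivity
  analysis and value-of-information analysis (EVPI / EVPPI, population
  scaling).

Because individual participant data are not shared, a synthetic trial
generator (`copdcea.synth`) produces patient-level tables with the same
structure, configurable arm effects, missingness and **closed-form ground
truth** for estimator-recovery testing.

## Layout

| Module | Contents |
| --- | --- |
| `copdcea.parameters` | Typed inputs: distribution specs, transition matrices, stage parameters; YAML/JSON config loading and validation |
| `copdcea.costing` | Bottom-up per-patient intervention costing (first / subsequent year) |
| `copdcea.effects` | Treatment-effect schedules and matrix adjustment |
| `copdcea.markov` | Cohort engine, tunnel states, microsimulation oracle, A/B/E merge |
| `copdcea.trial` | Within-trial CEA: QALY AUC, imputation, SUR, bootstrap, CEAC |
| `copdcea.psa` | PSA sampler, CEAC, EVPI, EVPPI (regression and nested MC), population VoI |
| `copdcea.synth` | Synthetic trial generator with closed-form truth |
| `copdcea.cli` | CLI orchestration, run manifest, figures |

The packaged default configuration (`src/copdcea/data/default.yaml`) encodes
the published parameter tables (costing items, 12-month starting states,
monthly transition probabilities, exacerbation rates, utilities, costs, PSA
distribution parameters). Keys marked `PLACEHOLDER` (per-admission death
probability, the usual-care transition matrix, year-1 accruals) are not
published in the main text; loaders fill documented defaults and log every
fill.

## CLI

```sh
copdcea run-model --arm both --structure abcd --out out/model
copdcea generate-trial --n-per-arm 45 --seed 1 --out trial.csv --truth truth.json
copdcea run-trial-cea --data trial.csv --horizon 6 --impute --reps 5000 --seed 1 --out out/cea
copdcea run-psa --iters 10000 --seed 1 --evppi utilities,costs --out out/psa
copdcea run-all --seed 1 --out out/full        # end-to-end with manifest
```

All commands accept `--config <file>` to override the packaged defaults;
`run-model` supports `--null-effects` for falsification runs and
`--structure ace` for the merged three-state variant. Exit codes distinguish
config (2), data (3) and numerical (4) failures.

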