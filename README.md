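# adhtraj

Medication-adherence trajectory analysis on pharmacy-claims-shaped tables:

- **adherence** — daily supply calendars with full carry-forward stockpiling,
  30-day-month proportion of days covered (PDC), dichotomized monthly
  adherence indicators (PDC ≥ 0.8), overall PDC.
- **gbtm** — group-based trajectory model: a finite mixture of logistic
  polynomial trajectories over month with multinomial-logit mixing weights,
  fitted by multi-start EM; BIC (`logL − (k/2)·ln N`, larger is better),
  observed-information standard errors, Wald tests on each group's
  highest-order term.
- **selection** — two-stage specification search: a 30-cell grid over group
  count (1–5) × common polynomial order (0–5) ranked by BIC, then stepwise
  per-group order reduction until every highest term is significant (with an
  order-0 floor) and a minimum-group-share check with a flagged G−1 fallback.
- **diagnostics** — average posterior probability of assignment (APP ≥ 0.7),
  odds of correct classification (OCC > 5), relative entropy (≥ 0.7), group
  shares, observed-vs-fitted trajectory tables, spaghetti-plot exports.
- **fmlogit** — fractional multinomial logit relating posterior membership
  probabilities to baseline covariates, with heteroskedasticity-robust
  sandwich standard errors and an adjusted-odds-ratio table.
- **cohort** — sequential inclusion/exclusion filters over claims tables
  (age, continuous enrollment, diagnosis rule with an inclusive 14-day
  outpatient gap, baseline antifibrotic use, excluded care settings,
  comorbid exclusions, overlapping alternative therapy, survival) with an
  attrition report.
- **synthetic** — a claims generator with latent five-group trajectory
  structure (registry scenarios `paper5`, `two_group_easy`,
  `one_group_null`) so the full pipeline runs without external data.

## CLI

```sh
adhtraj simulate --scenario paper5 --n-patients 1798 --outdir out --seed 1
adhtraj cohort    --outdir out
adhtraj adherence --outdir out
adhtraj select    --outdir out --seed 1
adhtraj diagnose  --outdir out
adhtraj regress   --outdir out
# or end-to-end, with per-stage options in a YAML config:
adhtraj run --config config.yaml --outdir out --seed 1
```

All artifacts are plain CSV/JSON (`fills.csv`, `panel.csv`, `grid.csv`,
`selection.json`, `posteriors.csv`, `diagnostics.json`, `aor_table.csv`,
`attrition.csv`, …); `run` writes a `manifest.json` with the seed, package
version, artifact hashes, and stage timings so a run can be reproduced
byte-identically.

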