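# lungsim

A population-level microsimulation of low-dose CT lung cancer screening in a
US-like, multi-birth-cohort population.

Most screening models follow a single birth cohort, which freezes smoking
behavior at the level of that generation. US smoking prevalence, intensity and
duration have all declined steadily across cohorts born since the 1930s, so a
single-cohort estimate captures screening's benefit at its historical maximum.
`lungsim` simulates every cohort aged 30–84 at any point in a 2016–2030
horizon, with cohort-specific smoking histories, and compares an annual CT
screening program under the CMS criteria — age 55–77, ≥30 pack-years, current
smoker or quit <15 years ago — against a no-screening counterfactual. It is
written for epidemiologists and health-policy modelers who need a transparent,
fully reproducible testbed for screening-program questions: adherence
sensitivity, overdiagnosis accounting, and the erosion of program benefit as
lower-risk cohorts replace higher-risk ones.

## Model

Each simulated person carries a birth year, sex, and a smoking career
(initiation age, constant cigarettes/day, cessation age) drawn from
cohort- and sex-specific parameters with declining generational trends.
On top of that:

* **Competing mortality** — Gompertz hazard `a·e^{b·age}` times a smoking-status
  hazard ratio (current > former > never), sampled exactly by piecewise
  inversion.
* **Natural history** — lung cancer onset with hazard
  `baseline(age) · exp(dose-response)`, the smoking excess decaying after
  cessation; five histologies; preclinical stages I→IV with exponential
  sojourns; stage-specific clinical-presentation hazards.
* **Survival** — per (stage, histology) cure fraction plus exponential
  residual, driven by one per-person quantile that maps *comonotonically*
  across stages: for a fixed quantile, an earlier stage at detection never
  yields an earlier lung-cancer death. Stage shift through this coupling is
  the only mechanism of screening benefit, which makes "screening never
  shortens a life" an exact per-person invariant rather than a statistical
  tendency.
* **Screening** — annual exams while eligible, fixed per-person adherence by
  thresholding a single uniform draw (so the adherent set at 25% is nested in
  the set at 45%, making adherence sweeps monotone on one population), and
  stage-dependent exam sensitivity.

Both scenarios of a pair read the *same* per-person random substreams
(common random numbers), so every scenario difference is attributable to
screening. Outcome metrics follow the standard definitions: mortality
reduction = (no-screening deaths − screening deaths)/no-screening deaths;
life-years gained truncated at the horizon; overdiagnosis both as
screen-detected diagnoses followed by other-cause death and as the
excess-diagnosis (screening-arm minus control-arm cases over screening-arm
diagnoses) rate.

## Worked example

```bash
python analysis/01_baseline_projection.py
```

runs 5 replications of 60,000 persons (a few minutes on one CPU) and prints:

```
headline metrics (mean [95% CI] across replications):
  mortality_reduction_pct                        4.11  [3.60, 4.62]
  screened_population_mr_pct                    20.50  [17.57, 23.43]
  deaths_avoided                                18.60  [16.58, 20.62]
  life_years_gained                             95.64  [82.12, 109.16]
  screen_detected                              100.00  [95.20, 104.80]
  overdiagnoses                                 56.20  [51.71, 60.69]
  eligible_fraction_first_year_pct               4.77  [4.69, 4.84]
  eligible_fraction_last_year_pct                1.25  [1.21, 1.28]
```

Read: at 45% adherence, screening averts ~4% of the population's lung cancer
deaths over 2016–2030 (about 31 per 100,000 simulated persons), and ~20%
among people actually screened at least once; the screening-eligible share of
the 30–84 population falls from ~4.8% to ~1.3% as lighter-smoking cohorts age
in — the generational dynamic at the heart of the model. Counts are per 60,000
simulated persons; scale by `person_weight` for national figures.

The other drivers follow the same pattern: `02_adherence_sweep.py` (deaths
avoided scale proportionally with adherence on a shared population),
`03_birth_cohorts.py` (cumulative 15-year mortality reduction declines from
the 1960 to the 1980 cohort), `04_metric_reference_checks.py` (below). The
same functionality is exposed as a CLI:
`lungsim simulate|sweep|cohort|check|write-config`.

All parameters live in one YAML file (`lungsim write-config --out cfg.yaml`
dumps every default); `docs/methods.md` documents each block and the
reasoning behind the defaults.

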