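# Methods

This note documents the model structure, the default parameterization and the
reasoning behind it, the numerical and design choices that were genuinely
open, and what the synthetic population does and does not capture.

## Population and smoking histories

The simulated population covers everyone aged 30–84 in at least one year of
the 2016–2030 horizon (birth cohorts 1932–2000). Birth years follow a
geometric cohort-size law (`cohort_growth_rate`, default 0 = uniform); sex is
Bernoulli (`sex_fraction_male`, default 0.49). Persons who reach age 30 after
2016 enter the study dynamically; all persons present at the start year are
conditioned on being alive then (their competing-mortality draw is truncated
at their age in 2016). One open choice: events occurring during the horizon to
cohort members who have aged past 84 are still counted, since the cohorts
themselves were selected by the age window, not the events.

A smoking career is (initiation age, constant cigarettes/day, cessation age):

| quantity | law | default |
|---|---|---|
| ever-smoking | Bernoulli, linear decline in birth year | 0.65 (M) / 0.50 (F) at the 1932 anchor, −0.006/birth-year, floor 0.05 |
| initiation age | truncated normal | mean 17, SD 3, range 10–35 |
| cigarettes/day | lognormal, median declining geometrically by cohort | median 28 (M) / 20 (F) at anchor, −1.8%/birth-year, σ = 0.45, cap 60 |
| cessation | annual quit probability, rising geometrically by cohort | 0.020 at anchor, +2.5%/birth-year, cap 0.25 |

The three cohort trends are the substantive core of the generator. Initiation
decline alone turns out to be insufficient for the phenomenon this package
studies: if later cohorts merely have *fewer* smokers with identical careers,
per-cohort mortality reduction is nearly flat, because deaths avoided and
total lung cancer deaths shrink together. The documented US reality — later
cohorts also smoke fewer cigarettes per day and quit earlier — is what pushes
later cohorts below the 30-pack-year / <15-quit-year eligibility thresholds
and makes screening progressively less productive. With the defaults the
screening-eligible share of the 30–84 population falls from ≈4.8% (2016) to
≈1.3% (2030), and cumulative 15-year mortality reduction falls roughly from
≈7% (1960 cohort) through ≈5% (1970) to ≈2% (1980). These defaults were fixed
once, at design time, against qualitative targets (eligible fraction near 6%
and declining; never smokers a small but strictly positive share of lung
cancer deaths; total lung cancer deaths near 1% of the population over the
horizon) and are not adjusted per run.

Not modeled: intensity tapering within a career, relapse after quitting,
race/socioeconomic strata, migration. Cigarettes/day is constant over the
career because pack-year eligibility only needs the integral.

## Competing mortality

Non-lung-cancer death has a Gompertz hazard `a·e^{b·t}` (a = 5.5e-5,
b = 0.09/yr — roughly US all-cause magnitudes: ≈0.2% at 40, ≈7% at 80)
multiplied by a status hazard ratio along the person's own trajectory
(never 1.0 → current 2.3 → former 1.4). Sampling inverts the piecewise
cumulative hazard in closed form, so the law is exact, left-truncation at
study entry is exact, and the test suite can compare against scipy's Gompertz
CDF directly. Death age is capped at `max_age` = 100.

## Natural history

Onset hazard: `base_rate·e^{slope·age} · exp(dose)`, with
`dose = dose_coef · min(cpd, saturation)` while smoking, decaying as
`e^{−decay·(age−cess)}` after quitting, and 0 for never smokers. Defaults
(base 8e-7, slope 0.085, coef 0.19, saturation 30 cpd, decay 0.03/yr) give a
never-smoker lifetime risk near 1%, a current-heavy-smoker relative risk in
the tens, and a slowly fading former-smoker excess. The hazard is integrated
on a one-year midpoint grid and inverted against a unit exponential;
integration starts at study entry (left truncation), which means there is no
prevalent undiagnosed pool at baseline — early-horizon incidence ramps up over
roughly one mean sojourn time. This is a deliberate simplification; it
understates first-round screening yield.

Histology is a categorical draw (adenocarcinoma 0.40, squamous 0.22, large
cell 0.08, small cell 0.15, other 0.15; never smokers get an
adenocarcinoma-heavier mixture). Preclinical stages I→IV have exponential
sojourns (means 2/1/1 years; small cell ×0.5) with stage-specific
clinical-presentation hazards (0.12/0.35/0.9/2.0 per year). These are
transparent stand-ins chosen for plausibility — not estimates calibrated to
trial data — and every one is a config field.

## Survival and the non-harm coupling

Post-diagnosis survival is a cure fraction plus exponential residual per
(stage, histology): cure 0.38/0.22/0.09/0.02 for stages I–IV (small cell
×0.5), residual death rates 0.25/0.40/0.70/1.40 per year (small cell ×1.5).
One uniform quantile `q` per person drives the outcome comonotonically:
quantiles above `1 − cure(stage)` are cured — cure regions are nested because
cure falls with stage — and otherwise the residual is the inverse exponential
CDF evaluated at `q/(1 − cure)`, which is non-decreasing as stage improves.

The residual clock is anchored at the tumor's *clinical-presentation age*
(the age the cancer would surface without screening), which is
scenario-invariant, rather than at the actual detection age. This is the one
place the implementation deliberately re-interprets the obvious bookkeeping:
anchoring at detection age would let a screen detection in the *same* stage
produce an earlier death than no screening purely through lead time,
contradicting the intended invariant that screening benefit flows exclusively
through stage shift. With the clinical anchor, "screen-scenario death age ≥
no-screen death age" holds exactly for every person, and the engine asserts
it. When a tumor path has no finite clinical-presentation age (possible only
if all detection hazards are zero), the detection age is used and the
assertion is skipped.

A consequence worth stating: the reported diagnosis age is the true (earlier)
detection age, but survival-time-since-diagnosis comparisons between scenarios
would be lead-time biased by construction; mortality and life-year metrics,
which is what this package reports, are not.

## Screening program

Eligibility at each annual exam date: age 55–77 inclusive, pack-years ≥ 30
(exactly 30 eligible), and current smoker or quit strictly fewer than 15
years ago (exactly 15 ineligible). Screening runs 2016–2030 (2015 excluded);
exams happen at the start of a calendar year, before that year's clinical
presentation or death — the within-year ordering is a convention fixed for
reproducibility. Adherence is a permanent per-person attribute
(`adherence_uniform < rate`), giving nested adherent sets across rates. Exam
sensitivity by preclinical stage is 0.80/0.85/0.92/0.95; specificity 0.90
labels false-positive exams but triggers no downstream pathway (the model's
only quantified harm is overdiagnosis). One exam per person-year; screening
stops at any diagnosis or death.

## Scenario engine and replication

Each person's stochastic course — competing death age, tumor path, survival
quantile, per-year detection uniforms — is drawn once from named substreams
(`SeedSequence(master_seed, (person_id, stream))`), and both scenarios are
deterministic readings of it. Follow-up for cause-of-death classification
runs to actual death (age cap 100) even past 2030; all year-indexed tables
stop at 2030. Life-years gained are truncated at the horizon end.
Replications draw fresh populations from seeds derived off one master seed;
across-run summaries report mean ± 1.96·SD/√R. The CI is a normal
approximation by design; its finite-R coverage (≈93.5% at R = 20, ≈94.8% at
R = 100) is what the coverage test checks at R = 100.

## Outcome metrics

All metrics are pure functions of raw counts. Percentages are rounded to two
decimals, half away from zero; counts to integers. Overdiagnosis
definition 1 counts *every* screen-detected diagnosis whose person eventually
dies of a non-lung-cancer cause, with no counterfactual requirement. Under
this model's cure fractions that is a large share of screen-detected cases
(roughly half, since cured patients all eventually die of something else) —
substantially larger than counterfactual-based overdiagnosis notions; the
excess-diagnosis rate (screening-arm minus control-arm cases over
screening-arm diagnoses, control = the no-screening scenario) is the
complementary, population-level measure and comes out near 6% at full
adherence. Smoker-type attribution uses status at death for deaths and status
at exam for screens; age-band attribution uses age at death for deaths and
age at diagnosis for overdiagnoses. The bundled
`data/reference_aggregates.json` holds raw national-scale aggregate counts
from a published projection with this same design, used solely to exercise
the metric arithmetic at realistic magnitudes; its printed period table
carries ±1 rounding inconsistencies in the smoker-type rows (independent
rounding of run means), which the checks allow for while requiring the totals
row to sum exactly.

## Problem sizes

Defaults chosen for the bundled analyses: 60k persons × 5 replications for
the baseline projection, 50k × 3 for the adherence sweep, 80–100k × 2 per
cohort for the single-cohort analyses, 30k for the shared test replication.
Monte Carlo error at these sizes is visible in rare-event counts (per-cohort
deaths avoided in particular); the analysis drivers print CIs so the noise is
explicit. Simulated quantities in `scripts/acceptance.py` use the same sizes.

## Known limitations

* One tumor per person; stages I–IV for all histologies (no limited/extensive
  small cell dichotomy); no nodule management, treatment choice or costs.
* The current/former smoker split of lung cancer deaths leans more toward
  current smokers than US projections do — a constant-intensity career with a
  single cessation probability understates the accumulated risk carried by
  long-quit heavy smokers.
* No baseline prevalent preclinical pool (left truncation at entry), so
  first-year screening yield is understated.
* Synthetic-population results validate structure and mechanism, not national
  absolute counts; scale-dependent numbers should be read per simulated
  person (or via `person_weight`), and calibrated parameters would be needed
  before any policy-grade absolute projection.
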