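# Methods

## The problem

Population surveys of cardiovascular risk factors (the WHO STEPS family)
record, per adult: demographics, three seated blood-pressure readings,
fasting glucose (whole-blood or plasma specimen), total cholesterol
(often only for a biochemical subsample), smoking history, medication
self-reports, and anthropometry — under a stratified multistage cluster
design with sampling, non-response and post-stratification weights.

Two ways of turning such data into treatment-need estimates compete:

* the **single risk factor** ("vertical") approach — count everyone past
  a diagnostic cutoff (hypertension: SBP ≥ 140 or DBP ≥ 90 mmHg or on
  antihypertensives; hypercholesterolemia: TC ≥ 6.2 mmol/l or on
  lipid-lowering drugs);
* the **total CVD risk** approach — score each person's 10-year risk of a
  fatal or non-fatal cardiovascular event with a chart that combines
  sex, age, smoking, diabetes, SBP and (optionally) total cholesterol,
  and target treatment at the high-risk tail.

The charts come with practice notes that adjust individual scores: BP
≥ 160/100 mmHg or cholesterol ≥ 8.0 mmol/l put a person in the high-risk
category regardless of the chart cell, and a further list of factors
(obesity, sedentariness, raised pulse, raised triglycerides, low HDL,
current antihypertensive therapy) marks risk as "higher than charted".
Applied at population level, the notes can multiply the apparent
high-risk prevalence several-fold relative to the bare chart, so the
package makes the inclusion criteria explicit and nested.

## Chart engine

A chart is a pure lookup table, shipped as data (CSV or JSON), never as
code. Keys are (sex, age band, smoker, diabetic, SBP band) plus a
cholesterol column 4–8 mmol/l in the with-cholesterol variant: 640 cells
with cholesterol, 128 without. The validator accepts a file iff the cell
set is exactly this cross-product with admissible band labels, and its
error message names every missing, duplicated or mislabelled key.

Numerical conventions (the chart literature prints bands, not rules, so
these are package choices, stated once here):

* age bands 40–49 / 50–59 / 60–69 / 70+; ages below 40 are a hard error
  (the instrument is defined for 40+), not a silent drop — scope
  filtering belongs to the pipeline;
* SBP band edges are lower-inclusive (140 → "140-159", 160 → "160-179",
  180 → "≥180"), matching the ≥-style of every diagnostic threshold in
  the domain;
* cholesterol maps to the nearest integer column, exact midpoints round
  up, clamped to [4, 8];
* a measured cholesterol selects the with-cholesterol chart; a missing
  one selects the fallback chart. A zero/negative value is an input
  error, never treated as missing.

## Derived variables and flags

* SBP and DBP are the mean of the **last two** of three seated readings
  (the first reading is typically elevated and is discarded). The rule
  is standard for SBP; applying it to DBP as well is a documented
  extension.
* Smoker = currently smoking, or quit less than a year before survey.
* Diabetes = fasting glucose ≥ 6.1 mmol/l (whole blood) / ≥ 7.0 mmol/l
  (plasma), or glucose-lowering medication.
* Elevating flags: BMI ≥ 30 kg/m²; < 600 MET-minutes/week; resting pulse
  > 90 bpm (strict); triglycerides > 2.00 mmol/l (strict); HDL < 1.0
  (men) / < 1.3 mmol/l (women); current antihypertensive treatment
  (taken verbatim from self-report, with no BP gating).

Every "≥"/"≤" is inclusive and every ">"/"<" strict, exactly as the
definitions read. Missing inputs never default to a negative flag: the
flag is undefined, excluded from "any elevating factor", and counted as
missing in tabulations — per-variable denominators therefore differ, as
they do in real surveys with biochemical subsampling.

## Reclassification cascade

Four nested inclusion-criteria scenarios:

| scenario | promoted to high if |
|---|---|
| `CHART_ONLY` | never (chart category as-is) |
| `CHART_BP` | SBP ≥ 160 **or** DBP ≥ 100 mmHg |
| `CHART_BP_CHOL` | … or total cholesterol ≥ 8.0 mmol/l |
| `CHART_BP_CHOL_MED` | … or on antihypertensive medication |

Promotion targets the high category and never demotes, so the high-risk
sets are nested by construction — the package's core monotonicity
invariant. Design choices: the 160/100 slash notation is read as OR
(the standard clinical reading; an AND switch is provided);
"persistent" blood pressure cannot be assessed from one survey visit,
so the survey-derived value is used and the single-visit overestimation
caveat documented; a missing cholesterol makes the ≥ 8.0 criterion a
logged no-op for that record rather than an error. The age filter is
40–64 inclusive.

## Survey estimation

Point estimates are ratio means Σwx/Σw. Variance is by Taylor
linearization with clusters as PSUs drawn with replacement within
strata:

Var(p̂) = Σ_h n_h/(n_h−1) Σ_c (e_hc − ē_h)², where e_hc = Σ_{i∈hc}
w_i (x_i − p̂)/Σw, with df = (#clusters − #strata). Any stratum with a
single cluster leaves the point estimate intact but marks the CI
undefined rather than guessing.

The 95% CI is computed on the logit scale and back-transformed, so it
respects [0, 1] even for the 1–2% prevalences typical of high-risk
cells; a Wald option (clamped) exists for comparability with analyses
that print symmetric intervals, which can produce nominal negative
bounds for rare outcomes. Degenerate estimates (p̂ ∈ {0, 1}) get a
degenerate interval. No finite-population correction is applied. A
single pre-multiplied weight column is expected (the usual STEPS
deliverable).

## Synthetic data generator

The generator is first-class, tested code: it is the only way to
exercise the full pipeline without survey microdata, which are not
distributable. It emulates:

* a two-stage design — default 2 strata × 10 sampled clusters (from a
  200-cluster frame) × 25 invited persons (from 500), per-cluster
  non-response ~ U(0, 0.15); weights = sampling weight × observed
  non-response adjustment, strictly positive;
* three BP readings per person around a person-level latent mean
  (between-person SD 14/9 mmHg, reading SD 6/5 mmHg), so the
  mean-of-last-two rule has real work to do;
* log-normal fasting glucose with a 50/50 whole-blood/plasma specimen
  mix (both cutoff branches exercised), assay noise, and treatment
  probability conditional on being above threshold;
* normal cholesterol with 25% missingness (forcing the fallback-chart
  path) and assay noise;
* age/sex-dependent smoking (45% of men, 10% of women, plus 4% recent
  quitters), and normal/log-normal models for BMI, MET-minutes, pulse,
  triglycerides and HDL chosen to put meaningful mass on both sides of
  every cutoff — levels typical of a middle-income Asian population.

Defaults give n ≈ 470 respondents; tests and the acceptance script also
run a 20-cluster × 125-person configuration (n ≈ 4,600) where sharper
estimates are needed. Correlations arise only through age and sex
effects (no copulas): enough to exercise every code path while keeping
ground truth computable.

**Ground truth.** `TruthRecord.prevalence` applies the definitions to
the realized *recorded* measurements through an independent vectorized
code path; a correct pipeline reproduces it exactly on each factor's
estimable domain, and with genuine (unbiased, vanishing) sampling error
where estimation runs on the cholesterol-observed subsample.
`prevalence_latent` applies the same definitions to the noise-free
latent values; the gap between the two is the measurement model's
threshold-misclassification effect (reading noise inflates hypertension
prevalence by roughly 2–4 points under the defaults because the SBP
density is falling at 140), which is a property of the data, not of the
estimator, and does not shrink with n. Recovery tests therefore compare
against the recorded-measurement truth, and use the closed-form
superpopulation rates (`GeneratorConfig.model_rates`, with thresholds
shifted by half the recording resolution) to demonstrate convergence as
n grows. Passing these tests shows the pipeline is a faithful,
consistent estimator of what the records contain; it does not validate
the chart values themselves (the fixture charts are synthetic) nor the
behaviour of the definitions under real-world correlated missingness.

Fixture charts for testing: `uniform` (every cell "<10"), `threshold`
(band index = age-band index + SBP-band index, capped — monotone and
enumerable), `adversarial` (exactly one deviant cell, for lookup
sensitivity).

## Numerical and degenerate-input choices

* Missingness is an empty CSV field ↔ `None`/NaN; numeric sentinels are
  rejected.
* Measurements are recorded at survey-realistic resolution (BP 0.1 mmHg,
  biochemistry 0.01 mmol/l, pulse 1 bpm, BMI 0.1, MET-minutes 1).
* Empty domains yield n = 0 estimates with undefined CIs, not errors.
* All outputs are deterministic given inputs; provenance records config
  and chart SHA-256 checksums, and no timestamps, so reruns are
  byte-identical.

## Known limitations

* The official published chart values are not redistributed; users
  supply their region's chart file in the documented schema. All shipped
  charts are synthetic fixtures.
* mmol/l only; no mg/dl conversion, no imputation of missing
  biochemistry, no age-standardisation, no finite-population correction.
* The qualitative practice points that are not measurable from STEPS
  variables (family history, premature menopause, socioeconomic
  deprivation, "approaching the next category") are out of scope; the
  package flags only the quantifiable factors and never reclassifies on
  proximity to a band edge.
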