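# cvdrisk

Total cardiovascular risk stratification for STEPS-like survey
microdata: a chart-based 10-year CVD risk engine, the standard
diagnostic threshold definitions, a nested practice-note
reclassification cascade, and design-based weighted prevalence
estimation — plus a synthetic survey generator with known ground truth
so the whole pipeline is testable without access to restricted survey
data.

## Who this is for

Epidemiologists and health planners comparing two ways of estimating
preventive treatment need from a national risk-factor survey:

* **single-factor ("vertical") prevalence** — e.g. hypertension as
  SBP ≥ 140 or DBP ≥ 90 mmHg or antihypertensive treatment;
* **total CVD risk** — each person's 10-year risk of a fatal or
  non-fatal cardiovascular event, read from a colour-chart lookup on
  (sex, age band, smoking, diabetes, SBP band, and optionally a total
  cholesterol column), reported as low (<10%), moderate (10–<20%) and
  high (≥20%).

The charts' accompanying practice notes promote individuals to high
risk when BP ≥ 160/100 mmHg or cholesterol ≥ 8.0 mmol/l, and flag
treatment status and metabolic factors as risk-elevating. Whether these
notes are applied changes population high-risk prevalence several-fold,
so the package exposes them as four explicitly nested scenarios:

    CHART_ONLY ⊆ CHART_BP ⊆ CHART_BP_CHOL ⊆ CHART_BP_CHOL_MED

with the guarantee (tested, not assumed) that the high-risk set only
grows along the chain.

Estimation is design-based throughout: weighted proportions Σwx/Σw with
Taylor-linearized variance over clusters within strata, and 95%
intervals on the logit scale so rare-outcome CIs stay inside [0, 1].

Charts are **data, not code**: the package validates and evaluates any
chart supplied in its documented CSV/JSON schema (one row per cell;
exhaustiveness is enforced — 640 cells with cholesterol, 128 without)
and does not redistribute official chart values.

## Worked example

```sh
cvdrisk simulate --seed 7 --out data            # synthetic survey + truth.json
cvdrisk make-chart --style threshold --out charts
cvdrisk analyze --records data/participants.csv \
    --chart charts/chart_with.csv \
    --chart-nochol charts/chart_without.csv --out results
cat results/summary.txt
```

which prints (abridged):

```
records in: 470  classified: 470  excluded: 0

Risk-category distribution by inclusion scenario (weighted %, 95% CI):
  CHART_ONLY         high_ge20  32.3 (28.9-36.0)
  CHART_BP           high_ge20  33.0 (29.4-36.8)
  CHART_BP_CHOL      high_ge20  33.4 (29.8-37.3)
  CHART_BP_CHOL_MED  high_ge20  37.3 (33.4-41.3)

Single risk-factor prevalence, ages 40-64 (weighted %):
  hypertension            42.6 (n=470)
  diabetes                 9.4 (n=470)
  hypercholesterolemia    19.5 (n=363)
  smoking                 30.1 (n=470)
```

Reading this: under the synthetic `threshold` fixture chart, 32.3% of
the weighted population is charted at high (≥20%) risk; adding the
BP ≥ 160/100 promotion, then cholesterol ≥ 8, then treated-hypertension
lifts that to 37.3% — the monotone cascade. Single-factor hypertension
(42.6%) exceeds even the widest total-risk criterion, illustrating why
the two approaches imply very different treatment loads. Note the
hypercholesterolemia denominator (n = 363): cholesterol is measured on
a subsample, and per-variable Ns follow the data, never imputation.

The same is available as a library:

```python
from cvdrisk import GeneratorConfig, generate, make_fixture_chart, run_analysis

records, truth = generate(GeneratorConfig(seed=7))
bundle = run_analysis(records,
                      make_fixture_chart("threshold", "with_cholesterol"),
                      make_fixture_chart("threshold", "without_cholesterol"))
print(bundle.scenario_distribution)
```

`docs/methods.md` documents the model, every threshold, the variance
estimator, the generator's assumptions and the package's limitations.

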