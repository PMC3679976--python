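"""STEPS-like synthetic survey microdata with known ground truth.

The generator emulates the structure of a national stepwise NCD
risk-factor survey: a stratified two-stage cluster sample (clusters
drawn within strata, persons within clusters), per-cluster non-response,
design weights (sampling × non-response adjustment), three seated blood
pressure readings per person drawn around a person-level latent mean,
specimen-dependent glucose cutoffs (whole blood vs plasma), and
cholesterol missing for a configurable fraction of records (so the
no-cholesterol chart fallback is exercised).

Alongside the records it returns a :class:`TruthRecord` with two
prevalence sets, both weighted on the *realized sample*:

* ``prevalence`` — the factor definitions applied to the realized,
  recorded measurements through an independent vectorized code path.
  A correct pipeline recovers these exactly except where it must
  estimate on a subsample (cholesterol missingness), where the error is
  pure, unbiased sampling noise that vanishes as n grows.
* ``prevalence_latent`` — the same definitions on the latent, noise-free
  person values.  The gap between the two quantifies what measurement
  noise does to threshold classification (reading noise inflates
  hypertension prevalence because more people sit just below 140 than
  just above); it is a property of the measurement model, not an
  estimator defect, and it does not shrink with n.

Correlations between variables arise only through the age and sex
effects; there are no residual correlations, which keeps the truth
computable while still exercising every code path.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .chart import (
    AGE_BANDS,
    RISK_BANDS,
    SBP_BANDS,
    ChartSpec,
    to_age_band,
    to_sbp_band,
    _expected_keys,
)
from .definitions import (
    BMI_OBESITY_THRESHOLD,
    CHOL_HIGH_THRESHOLD,
    DBP_HTN_THRESHOLD,
    GLUCOSE_THRESHOLD_PLASMA,
    GLUCOSE_THRESHOLD_WHOLE_BLOOD,
    HDL_LOW_THRESHOLD_FEMALE,
    HDL_LOW_THRESHOLD_MALE,
    MET_SEDENTARY_THRESHOLD,
    PULSE_HIGH_THRESHOLD,
    SBP_HTN_THRESHOLD,
    TG_HIGH_THRESHOLD,
    ParticipantRecord,
)
from .errors import ConfigError


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic survey; the seed fully determines output.

    Defaults describe a mid-sized national survey of adults aged 40-64
    with risk-factor levels typical of a middle-income Asian population:
    roughly half of men and a tenth of women smoke, mean SBP in the 120s
    rising with age, a few percent diabetic, and a quarter of records
    lacking a cholesterol measurement (biochemical subsampling).
    """

    # design
    n_strata: int = 2
    clusters_per_stratum: int = 10
    persons_per_cluster: int = 25          # invited per sampled cluster
    seed: int = 0
    pop_clusters_per_stratum: int = 200    # cluster frame size per stratum
    pop_persons_per_cluster: int = 500     # person frame size per cluster
    max_nonresponse_rate: float = 0.15     # per-cluster rate ~ U(0, max)
    # demographics
    age_range: tuple = (40, 64)
    sex_ratio: float = 0.5                 # P(male)
    # smoking
    smoking_prob_male: float = 0.45
    smoking_prob_female: float = 0.10
    quit_lt_1yr_prob: float = 0.04         # among current non-smokers
    # blood pressure (mmHg)
    sbp_baseline: float = 122.0            # latent mean at age 40
    sbp_age_slope: float = 0.9             # per year of age
    sbp_between_sd: float = 14.0           # person-level SD
    sbp_within_sd: float = 6.0             # reading-level SD (3 readings)
    dbp_baseline: float = 76.0
    dbp_age_slope: float = 0.3
    dbp_between_sd: float = 9.0
    dbp_within_sd: float = 5.0
    # fasting glucose (mmol/l), lognormal latent + assay noise
    glucose_log_mean: float = float(np.log(5.1))
    glucose_log_sd: float = 0.16
    glucose_assay_sd: float = 0.15
    whole_blood_fraction: float = 0.5
    dm_medication_prob_if_high: float = 0.25
    dm_medication_prob_background: float = 0.01
    # total cholesterol (mmol/l)
    chol_mean: float = 5.1
    chol_sd: float = 1.05
    chol_assay_sd: float = 0.10
    chol_missing_prob: float = 0.25
    chol_medication_prob_if_high: float = 0.15
    chol_medication_prob_background: float = 0.01
    # elevating-factor models
    tg_log_mean: float = float(np.log(1.5))
    tg_log_sd: float = 0.40
    hdl_mean_male: float = 1.15
    hdl_mean_female: float = 1.45
    hdl_sd: float = 0.30
    bmi_mean: float = 24.5
    bmi_sd: float = 4.2
    met_log_mean: float = float(np.log(900.0))
    met_log_sd: float = 1.0
    pulse_mean: float = 76.0
    pulse_sd: float = 11.0
    # hypertension treatment
    ht_medication_prob_if_hypertensive: float = 0.30
    ht_medication_prob_background: float = 0.02

    def validate(self) -> None:
        problems = []
        for name in ("n_strata", "clusters_per_stratum", "persons_per_cluster",
                     "pop_clusters_per_stratum", "pop_persons_per_cluster"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.clusters_per_stratum > self.pop_clusters_per_stratum:
            problems.append("cannot sample more clusters than the frame holds")
        if self.persons_per_cluster > self.pop_persons_per_cluster:
            problems.append("cannot sample more persons than the cluster holds")
        probs = ("sex_ratio", "smoking_prob_male", "smoking_prob_female",
                 "quit_lt_1yr_prob", "whole_blood_fraction",
                 "dm_medication_prob_if_high", "dm_medication_prob_background",
                 "chol_missing_prob", "chol_medication_prob_if_high",
                 "chol_medication_prob_background", "max_nonresponse_rate",
                 "ht_medication_prob_if_hypertensive",
                 "ht_medication_prob_background")
        for name in probs:
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must be a probability in [0, 1]")
        sds = ("sbp_between_sd", "sbp_within_sd", "dbp_between_sd",
               "dbp_within_sd", "glucose_log_sd", "glucose_assay_sd",
               "chol_sd", "chol_assay_sd", "tg_log_sd", "hdl_sd", "bmi_sd",
               "met_log_sd", "pulse_sd")
        for name in sds:
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        lo, hi = self.age_range
        if not (40 <= lo <= hi):
            problems.append("age_range must lie within the 40+ chart scope")
        if problems:
            raise ConfigError("invalid generator config: " + "; ".join(problems))

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "age_range" in d:
            d = {**d, "age_range": tuple(d["age_range"])}
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        with open(Path(path), encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        return d

    def model_rates(self) -> dict:
        """Closed-form superpopulation rates of the directly observed factors.

        Thresholds are shifted by half the recording resolution (pulse is
        recorded to the bpm, BMI to 0.1, etc.), so these are the rates of
        the *recorded* flags.  Floor-clipping of the latent distributions
        (e.g. HDL at 0.4) does not move any flag across its cutoff and is
        ignored.  Factors needing derived or subsampled inputs (blood
        pressure, glucose, cholesterol) have no closed form here; their
        truth is the finite-sample :class:`TruthRecord`.
        """
        from scipy import stats

        male, female = self.sex_ratio, 1.0 - self.sex_ratio

        def smoke(p):
            return p + (1.0 - p) * self.quit_lt_1yr_prob

        norm, lognorm = stats.norm, stats.lognorm
        return {
            "smoking": male * smoke(self.smoking_prob_male)
            + female * smoke(self.smoking_prob_female),
            "obesity": norm.sf(BMI_OBESITY_THRESHOLD - 0.05,
                               self.bmi_mean, self.bmi_sd),
            "low_physical_activity": lognorm.cdf(
                MET_SEDENTARY_THRESHOLD - 0.5, self.met_log_sd,
                scale=np.exp(self.met_log_mean)),
            "high_pulse": norm.sf(PULSE_HIGH_THRESHOLD + 0.5,
                                  self.pulse_mean, self.pulse_sd),
            "high_triglycerides": lognorm.sf(
                TG_HIGH_THRESHOLD + 0.005, self.tg_log_sd,
                scale=np.exp(self.tg_log_mean)),
            "low_hdl": male * norm.cdf(HDL_LOW_THRESHOLD_MALE - 0.005,
                                       self.hdl_mean_male, self.hdl_sd)
            + female * norm.cdf(HDL_LOW_THRESHOLD_FEMALE - 0.005,
                                self.hdl_mean_female, self.hdl_sd),
        }


TRUTH_FACTORS = ("hypertension", "diabetes", "hypercholesterolemia", "smoking",
                 "obesity", "low_physical_activity", "high_pulse",
                 "on_ht_medication", "high_triglycerides", "low_hdl")


@dataclass
class TruthRecord:
    """Weighted finite-sample truth for every planted factor.

    ``prevalence`` applies the definitions to the realized recorded
    measurements (what a perfect analysis of these records would find);
    ``prevalence_latent`` applies them to the latent noise-free values;
    ``observed_flags``/``latent_flags`` hold the per-record indicator
    arrays; ``chart_band_distribution`` is the weighted band distribution
    under the deterministic threshold fixture chart.
    """

    n: int
    prevalence: dict
    prevalence_latent: dict = field(default_factory=dict)
    observed_flags: dict = field(repr=False, default_factory=dict)
    latent_flags: dict = field(repr=False, default_factory=dict)
    chart_band_distribution: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = {"n": self.n, "prevalence": self.prevalence,
               "prevalence_latent": self.prevalence_latent,
               "chart_band_distribution": self.chart_band_distribution}
        with open(Path(path), "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# fixture charts

FIXTURE_STYLES = ("uniform", "threshold", "adversarial")

# the single deviant key of the adversarial fixtures
ADVERSARIAL_KEY_WITH = ("male", "60-69", True, True, ">=180", 8)
ADVERSARIAL_KEY_WITHOUT = ("male", "60-69", True, True, ">=180", None)


def threshold_band_rule(age_band: str, sbp_band: str) -> str:
    """Deterministic band for the threshold fixture: index = age + SBP.

    The band index is ``min(4, age_band_index + sbp_band_index)``, so risk
    rises monotonically with both age and SBP and every cohort with
    SBP >= 180 lands outside the low band.  Smoking, diabetes and
    cholesterol are deliberately ignored so expected category
    distributions are computable from (age, SBP) alone.
    """
    idx = AGE_BANDS.index(age_band) + SBP_BANDS.index(sbp_band)
    return RISK_BANDS[min(len(RISK_BANDS) - 1, idx)]


def make_fixture_chart(style: str,
                       variant: str = "with_cholesterol") -> ChartSpec:
    """Fully populated test chart: uniform, threshold or adversarial."""
    if style not in FIXTURE_STYLES:
        raise ConfigError(f"style must be one of {FIXTURE_STYLES}, got {style!r}")
    cells = {}
    for key in _expected_keys(variant):
        sex, age_band, smoker, diabetic, sbp_band, chol_band = key
        if style == "uniform":
            band = "<10"
        elif style == "threshold":
            band = threshold_band_rule(age_band, sbp_band)
        else:
            deviant = (ADVERSARIAL_KEY_WITH if variant == "with_cholesterol"
                       else ADVERSARIAL_KEY_WITHOUT)
            band = ">=40" if key == deviant else "<10"
        cells[key] = band
    spec = ChartSpec(region_id=f"FIXTURE-{style.upper()}", variant=variant,
                     cells=cells)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# generation

def _bernoulli(rng, p, size=None):
    return rng.random(size) < p


def generate(config: GeneratorConfig,
             rng: Optional[np.random.Generator] = None):
    """Draw one synthetic survey; returns ``(records, truth)``.

    Output is fully reproducible from ``config.seed`` (an explicit ``rng``
    overrides the seed, for replicate studies driven by a parent stream).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    # --- design: sample clusters within strata, persons within clusters,
    # then per-cluster non-response among the invited persons.
    rows = []
    for s in range(config.n_strata):
        stratum_id = f"S{s + 1}"
        cluster_ids = rng.choice(config.pop_clusters_per_stratum,
                                 size=config.clusters_per_stratum,
                                 replace=False)
        base_weight = ((config.pop_clusters_per_stratum
                        / config.clusters_per_stratum)
                       * (config.pop_persons_per_cluster
                          / config.persons_per_cluster))
        for c in np.sort(cluster_ids):
            nr_rate = rng.uniform(0.0, config.max_nonresponse_rate)
            responded = _bernoulli(rng, 1.0 - nr_rate,
                                   config.persons_per_cluster)
            n_resp = int(responded.sum())
            if n_resp == 0:
                continue
            # observed non-response adjustment: invited / responded
            weight = base_weight * config.persons_per_cluster / n_resp
            for _ in range(n_resp):
                rows.append((stratum_id, f"C{c + 1:03d}", weight))
    n = len(rows)
    stratum = np.array([r[0] for r in rows])
    cluster = np.array([r[1] for r in rows])
    weight = np.array([r[2] for r in rows])

    # --- demographics
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n)
    male = _bernoulli(rng, config.sex_ratio, n)
    sex = np.where(male, "male", "female")

    # --- smoking (directly observed; latent == observed)
    p_smoke = np.where(male, config.smoking_prob_male,
                       config.smoking_prob_female)
    current_smoker = rng.random(n) < p_smoke
    quit_lt_1yr = (~current_smoker) & _bernoulli(rng, config.quit_lt_1yr_prob, n)

    # --- blood pressure: latent person mean + three noisy readings
    sbp_latent = (config.sbp_baseline + config.sbp_age_slope * (age - lo)
                  + rng.normal(0, config.sbp_between_sd, n))
    dbp_latent = (config.dbp_baseline + config.dbp_age_slope * (age - lo)
                  + rng.normal(0, config.dbp_between_sd, n))
    sbp_readings = sbp_latent[:, None] + rng.normal(
        0, config.sbp_within_sd, (n, 3))
    dbp_readings = dbp_latent[:, None] + rng.normal(
        0, config.dbp_within_sd, (n, 3))
    sbp_readings = np.maximum(sbp_readings, 60.0)
    dbp_readings = np.maximum(dbp_readings, 35.0)

    # --- glucose
    glucose_latent = rng.lognormal(config.glucose_log_mean,
                                   config.glucose_log_sd, n)
    glucose_obs = np.maximum(
        glucose_latent + rng.normal(0, config.glucose_assay_sd, n), 0.5)
    whole_blood = _bernoulli(rng, config.whole_blood_fraction, n)
    specimen = np.where(whole_blood, "whole_blood", "plasma")
    glucose_cut = np.where(whole_blood, GLUCOSE_THRESHOLD_WHOLE_BLOOD,
                           GLUCOSE_THRESHOLD_PLASMA)
    glucose_high_latent = glucose_latent >= glucose_cut
    p_dm_med = np.where(glucose_high_latent,
                        config.dm_medication_prob_if_high,
                        config.dm_medication_prob_background)
    on_dm_medication = rng.random(n) < p_dm_med

    # --- cholesterol
    chol_latent = np.maximum(
        rng.normal(config.chol_mean, config.chol_sd, n), 2.5)
    chol_obs = np.maximum(
        chol_latent + rng.normal(0, config.chol_assay_sd, n), 2.0)
    chol_missing = _bernoulli(rng, config.chol_missing_prob, n)
    chol_high_latent = chol_latent >= CHOL_HIGH_THRESHOLD
    p_chol_med = np.where(chol_high_latent,
                          config.chol_medication_prob_if_high,
                          config.chol_medication_prob_background)
    on_chol_medication = rng.random(n) < p_chol_med

    # --- elevating factors (directly observed)
    triglycerides = rng.lognormal(config.tg_log_mean, config.tg_log_sd, n)
    hdl = np.maximum(rng.normal(
        np.where(male, config.hdl_mean_male, config.hdl_mean_female),
        config.hdl_sd, n), 0.4)
    bmi = np.maximum(rng.normal(config.bmi_mean, config.bmi_sd, n), 14.0)
    met_minutes = rng.lognormal(config.met_log_mean, config.met_log_sd, n)
    pulse = np.maximum(rng.normal(config.pulse_mean, config.pulse_sd, n), 40.0)

    # --- hypertension treatment, conditional on latent hypertensive status
    hypertensive_latent = ((sbp_latent >= SBP_HTN_THRESHOLD)
                           | (dbp_latent >= DBP_HTN_THRESHOLD))
    p_ht_med = np.where(hypertensive_latent,
                        config.ht_medication_prob_if_hypertensive,
                        config.ht_medication_prob_background)
    on_ht_medication = rng.random(n) < p_ht_med

    # --- recorded (rounded) measurements; records and observed truth are
    # computed from the same arrays so the two stay consistent by
    # construction
    sbp_rec = np.round(sbp_readings, 1)
    dbp_rec = np.round(dbp_readings, 1)
    glucose_rec = np.round(glucose_obs, 2)
    chol_rec = np.round(chol_obs, 2)
    bmi_rec = np.round(bmi, 1)
    met_rec = np.round(met_minutes, 0)
    pulse_rec = np.round(pulse, 0)
    tg_rec = np.round(triglycerides, 2)
    hdl_rec = np.round(hdl, 2)

    records = []
    for i in range(n):
        records.append(ParticipantRecord(
            participant_id=f"P{i + 1:06d}",
            stratum_id=str(stratum[i]),
            cluster_id=str(cluster[i]),
            weight=float(weight[i]),
            sex=str(sex[i]),
            age=int(age[i]),
            sbp1=float(sbp_rec[i, 0]),
            sbp2=float(sbp_rec[i, 1]),
            sbp3=float(sbp_rec[i, 2]),
            dbp1=float(dbp_rec[i, 0]),
            dbp2=float(dbp_rec[i, 1]),
            dbp3=float(dbp_rec[i, 2]),
            current_smoker=bool(current_smoker[i]),
            quit_lt_1yr=bool(quit_lt_1yr[i]),
            fasting_glucose=float(glucose_rec[i]),
            glucose_specimen=str(specimen[i]),
            on_dm_medication=bool(on_dm_medication[i]),
            total_cholesterol=(None if chol_missing[i]
                               else float(chol_rec[i])),
            on_chol_medication=bool(on_chol_medication[i]),
            on_ht_medication=bool(on_ht_medication[i]),
            bmi=float(bmi_rec[i]),
            met_minutes=float(met_rec[i]),
            pulse=float(pulse_rec[i]),
            triglycerides=float(tg_rec[i]),
            hdl=float(hdl_rec[i]),
        ))

    # --- finite-sample truth on the recorded measurements (independent
    # vectorized restatement of the definitions).  Cholesterol truth uses
    # the pre-masking measurement of every record, so the pipeline's
    # estimate on the observed subsample carries genuine sampling error.
    sbp_derived = (sbp_rec[:, 1] + sbp_rec[:, 2]) / 2.0
    dbp_derived = (dbp_rec[:, 1] + dbp_rec[:, 2]) / 2.0
    observed_flags = {
        "hypertension": (sbp_derived >= SBP_HTN_THRESHOLD)
        | (dbp_derived >= DBP_HTN_THRESHOLD) | on_ht_medication,
        "diabetes": (glucose_rec >= glucose_cut) | on_dm_medication,
        "hypercholesterolemia": (chol_rec >= CHOL_HIGH_THRESHOLD)
        | on_chol_medication,
        "smoking": current_smoker | quit_lt_1yr,
        "obesity": bmi_rec >= BMI_OBESITY_THRESHOLD,
        "low_physical_activity": met_rec < MET_SEDENTARY_THRESHOLD,
        "high_pulse": pulse_rec > PULSE_HIGH_THRESHOLD,
        "on_ht_medication": on_ht_medication,
        "high_triglycerides": tg_rec > TG_HIGH_THRESHOLD,
        "low_hdl": np.where(male, hdl_rec < HDL_LOW_THRESHOLD_MALE,
                            hdl_rec < HDL_LOW_THRESHOLD_FEMALE).astype(bool),
    }
    latent_flags = {
        "hypertension": hypertensive_latent | on_ht_medication,
        "diabetes": glucose_high_latent | on_dm_medication,
        "hypercholesterolemia": chol_high_latent | on_chol_medication,
        "smoking": current_smoker | quit_lt_1yr,
        "obesity": bmi >= BMI_OBESITY_THRESHOLD,
        "low_physical_activity": met_minutes < MET_SEDENTARY_THRESHOLD,
        "high_pulse": pulse > PULSE_HIGH_THRESHOLD,
        "on_ht_medication": on_ht_medication,
        "high_triglycerides": triglycerides > TG_HIGH_THRESHOLD,
        "low_hdl": np.where(male, hdl < HDL_LOW_THRESHOLD_MALE,
                            hdl < HDL_LOW_THRESHOLD_FEMALE).astype(bool),
    }
    total_w = weight.sum()
    prevalence = {name: float((weight * flags).sum() / total_w)
                  for name, flags in observed_flags.items()}
    prevalence_latent = {name: float((weight * flags).sum() / total_w)
                         for name, flags in latent_flags.items()}

    # band distribution under the threshold fixture chart, from the
    # derived (mean of last two recorded readings) SBP
    band_w: dict = {b: 0.0 for b in RISK_BANDS}
    for i in range(n):
        band = threshold_band_rule(to_age_band(float(age[i])),
                                   to_sbp_band(float(sbp_derived[i])))
        band_w[band] += float(weight[i])
    chart_dist = {b: v / total_w for b, v in band_w.items()}

    truth = TruthRecord(n=n, prevalence=prevalence,
                        prevalence_latent=prevalence_latent,
                        observed_flags=observed_flags,
                        latent_flags=latent_flags,
                        chart_band_distribution=chart_dist)
    return records, truth
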