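"""Derivation of chart inputs and risk-factor flags from raw survey records.

The thresholds here are the conventional clinical cutoffs used with the
WHO/ISH instrument and STEPS surveys:

* hypertension: SBP >= 140 mmHg or DBP >= 90 mmHg, or antihypertensive
  medication regardless of measured pressure;
* hypercholesterolemia: total cholesterol >= 6.2 mmol/l or lipid-lowering
  medication;
* diabetes: fasting glucose >= 6.1 mmol/l for whole-blood specimens,
  >= 7.0 mmol/l for plasma, or glucose-lowering medication;
* smoker: current smoking, or quitting less than one year before the survey;
* risk-elevating flags: obesity (BMI >= 30 kg/m2), sedentary lifestyle
  (< 600 MET-minutes/week), raised resting pulse (> 90 bpm), raised
  triglycerides (> 2.00 mmol/l), low HDL (< 1.0 mmol/l in men,
  < 1.3 mmol/l in women) and current antihypertensive treatment.

Inclusive versus strict comparisons follow the definitions exactly:
">=" cutoffs include the threshold value, ">"/"<" cutoffs are strict.
Missing inputs never silently become negative flags — they propagate as
``None`` and are reported as missing in downstream tabulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .chart import RiskProfile
from .errors import InputError, MissingInputError

GLUCOSE_SPECIMENS = ("whole_blood", "plasma")

# Diagnostic thresholds (mmol/l unless noted)
SBP_HTN_THRESHOLD = 140.0          # mmHg, inclusive
DBP_HTN_THRESHOLD = 90.0           # mmHg, inclusive
GLUCOSE_THRESHOLD_WHOLE_BLOOD = 6.1  # inclusive
GLUCOSE_THRESHOLD_PLASMA = 7.0       # inclusive
CHOL_HIGH_THRESHOLD = 6.2            # inclusive
BMI_OBESITY_THRESHOLD = 30.0         # kg/m2, inclusive
MET_SEDENTARY_THRESHOLD = 600.0      # MET-min/week, strict <
PULSE_HIGH_THRESHOLD = 90.0          # bpm, strict >
TG_HIGH_THRESHOLD = 2.00             # strict >
HDL_LOW_THRESHOLD_MALE = 1.0         # strict <
HDL_LOW_THRESHOLD_FEMALE = 1.3       # strict <


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def derive_sbp(sbp1, sbp2, sbp3) -> float:
    """Mean of the last two of three seated readings.

    The first reading is discarded by protocol (it is typically elevated);
    readings 2 and 3 are required.  Records lacking them are excluded
    downstream rather than imputed.
    """
    if _missing(sbp2) or _missing(sbp3):
        raise MissingInputError("blood pressure readings 2 and 3 are required")
    for v in (sbp1, sbp2, sbp3):
        if not _missing(v) and v <= 0:
            raise InputError(f"blood pressure reading must be positive, got {v}")
    return (sbp2 + sbp3) / 2.0


# DBP follows the same mean-of-last-two rule.
derive_dbp = derive_sbp


def is_smoker(current_smoker, quit_lt_1yr) -> bool:
    """Current smoker, or quit less than one year before the survey."""
    if _missing(current_smoker) or _missing(quit_lt_1yr):
        raise MissingInputError("smoking status requires both indicator fields")
    return bool(current_smoker) or bool(quit_lt_1yr)


def is_diabetic(fasting_glucose, glucose_specimen, on_dm_medication) -> bool:
    """Fasting glucose at/above the specimen-specific cutoff, or on treatment.

    Whole-blood and plasma glucose have different diagnostic cutoffs
    (6.1 vs 7.0 mmol/l); medication (insulin or oral hypoglycemics)
    classifies as diabetic even with glucose below threshold.
    """
    if on_dm_medication:
        return True
    if _missing(fasting_glucose):
        raise MissingInputError(
            "diabetes status requires fasting glucose or a medication flag"
        )
    if _missing(glucose_specimen):
        raise MissingInputError("glucose specimen type is required")
    if glucose_specimen not in GLUCOSE_SPECIMENS:
        raise InputError(f"unknown glucose specimen {glucose_specimen!r}")
    threshold = (GLUCOSE_THRESHOLD_WHOLE_BLOOD
                 if glucose_specimen == "whole_blood"
                 else GLUCOSE_THRESHOLD_PLASMA)
    return fasting_glucose >= threshold


def has_hypertension(sbp, dbp, on_ht_medication) -> bool:
    """SBP >= 140 or DBP >= 90 mmHg, or antihypertensive medication."""
    return (sbp >= SBP_HTN_THRESHOLD or dbp >= DBP_HTN_THRESHOLD
            or bool(on_ht_medication))


def has_hypercholesterolemia(total_cholesterol, on_chol_medication) -> bool:
    """Total cholesterol >= 6.2 mmol/l, or lipid-lowering medication."""
    if on_chol_medication:
        return True
    if _missing(total_cholesterol):
        raise MissingInputError(
            "hypercholesterolemia requires a cholesterol measurement or a "
            "medication flag"
        )
    return total_cholesterol >= CHOL_HIGH_THRESHOLD


@dataclass(frozen=True)
class FlagSet:
    """Risk-factor flags for one participant; ``None`` marks missing inputs."""

    hypertension_single: Optional[bool] = None
    hypercholesterolemia_single: Optional[bool] = None
    obesity: Optional[bool] = None
    low_physical_activity: Optional[bool] = None
    high_pulse: Optional[bool] = None
    on_ht_medication: Optional[bool] = None
    high_triglycerides: Optional[bool] = None
    low_hdl: Optional[bool] = None

    # the six chart practice-note factors that define "any elevating factor"
    ELEVATING = ("obesity", "low_physical_activity", "high_pulse",
                 "on_ht_medication", "high_triglycerides", "low_hdl")

    @property
    def any_elevating(self) -> Optional[bool]:
        """OR over the defined (non-missing) elevating flags.

        ``None`` only when every elevating flag is undefined.
        """
        defined = [getattr(self, name) for name in self.ELEVATING
                   if getattr(self, name) is not None]
        if not defined:
            return None
        return any(defined)


def elevating_flags(profile: RiskProfile) -> FlagSet:
    """All single-factor and risk-elevating flags for a derived profile."""
    def tc_flag():
        if profile.on_chol_medication:
            return True
        if _missing(profile.total_cholesterol):
            return None
        return profile.total_cholesterol >= CHOL_HIGH_THRESHOLD

    hdl_cut = (HDL_LOW_THRESHOLD_MALE if profile.sex == "male"
               else HDL_LOW_THRESHOLD_FEMALE)
    return FlagSet(
        hypertension_single=has_hypertension(
            profile.sbp, profile.dbp, profile.on_ht_medication),
        hypercholesterolemia_single=tc_flag(),
        obesity=None if _missing(profile.bmi)
        else profile.bmi >= BMI_OBESITY_THRESHOLD,
        low_physical_activity=None if _missing(profile.met_minutes)
        else profile.met_minutes < MET_SEDENTARY_THRESHOLD,
        high_pulse=None if _missing(profile.pulse)
        else profile.pulse > PULSE_HIGH_THRESHOLD,
        on_ht_medication=bool(profile.on_ht_medication),
        high_triglycerides=None if _missing(profile.triglycerides)
        else profile.triglycerides > TG_HIGH_THRESHOLD,
        low_hdl=None if _missing(profile.hdl) else profile.hdl < hdl_cut,
    )


# ---------------------------------------------------------------------------
# Participant records and CSV ingest

@dataclass
class ParticipantRecord:
    """One raw survey row; ``None`` marks a missing value."""

    participant_id: str
    stratum_id: str
    cluster_id: str
    weight: float
    sex: str
    age: float
    sbp1: Optional[float] = None
    sbp2: Optional[float] = None
    sbp3: Optional[float] = None
    dbp1: Optional[float] = None
    dbp2: Optional[float] = None
    dbp3: Optional[float] = None
    current_smoker: Optional[bool] = None
    quit_lt_1yr: Optional[bool] = None
    fasting_glucose: Optional[float] = None
    glucose_specimen: Optional[str] = None
    on_dm_medication: bool = False
    total_cholesterol: Optional[float] = None
    on_chol_medication: bool = False
    on_ht_medication: bool = False
    bmi: Optional[float] = None
    met_minutes: Optional[float] = None
    pulse: Optional[float] = None
    triglycerides: Optional[float] = None
    hdl: Optional[float] = None


PARTICIPANT_COLUMNS = tuple(f.name for f in dc_fields(ParticipantRecord))

_BOOL_COLUMNS = ("current_smoker", "quit_lt_1yr", "on_dm_medication",
                 "on_chol_medication", "on_ht_medication")
_FLOAT_COLUMNS = ("weight", "age", "sbp1", "sbp2", "sbp3", "dbp1", "dbp2",
                  "dbp3", "fasting_glucose", "total_cholesterol", "bmi",
                  "met_minutes", "pulse", "triglycerides", "hdl")


def validate_participant_frame(frame: pd.DataFrame) -> None:
    """Schema validation for a participant table; raises :class:`InputError`."""
    problems = []
    missing_cols = set(PARTICIPANT_COLUMNS) - set(frame.columns)
    if missing_cols:
        problems.append(f"missing columns: {sorted(missing_cols)}")
    else:
        dup = frame["participant_id"][frame["participant_id"].duplicated()]
        if len(dup):
            problems.append(
                f"duplicate participant_id values: {sorted(set(dup.astype(str)))[:10]}"
            )
        if frame["weight"].isna().any() or (frame["weight"] <= 0).any():
            problems.append("weights must be present and strictly positive")
        bad_sex = set(frame["sex"].dropna()) - {"male", "female"}
        if bad_sex:
            problems.append(f"unknown sex values: {sorted(bad_sex)}")
        spec = frame["glucose_specimen"].dropna()
        bad_spec = set(spec) - set(GLUCOSE_SPECIMENS)
        if bad_spec:
            problems.append(f"unknown glucose_specimen values: {sorted(bad_spec)}")
        for col in _BOOL_COLUMNS:
            vals = set(pd.unique(frame[col].dropna()))
            if not vals <= {0, 1, 0.0, 1.0, True, False}:
                problems.append(f"column {col} must be 0/1, got {sorted(map(str, vals))[:5]}")
    if problems:
        raise InputError("participant table invalid: " + "; ".join(problems))


def load_participants(path) -> list[ParticipantRecord]:
    """Read the participant CSV (empty field = missing, booleans as 0/1)."""
    frame = pd.read_csv(Path(path), dtype={"participant_id": str,
                                           "stratum_id": str,
                                           "cluster_id": str})
    validate_participant_frame(frame)
    return records_from_frame(frame)


def records_from_frame(frame: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for row in frame.itertuples(index=False):
        kwargs = {}
        for name in PARTICIPANT_COLUMNS:
            v = getattr(row, name)
            if isinstance(v, float) and math.isnan(v):
                v = None
            if v is not None and name in _BOOL_COLUMNS:
                v = bool(v)
            kwargs[name] = v
        for name in ("on_dm_medication", "on_chol_medication", "on_ht_medication"):
            kwargs[name] = bool(kwargs[name]) if kwargs[name] is not None else False
        records.append(ParticipantRecord(**kwargs))
    return records


def frame_from_records(records) -> pd.DataFrame:
    frame = pd.DataFrame(
        [{name: getattr(r, name) for name in PARTICIPANT_COLUMNS}
         for r in records],
        columns=list(PARTICIPANT_COLUMNS),
    )
    for col in _BOOL_COLUMNS:
        frame[col] = frame[col].map(
            lambda v: np.nan if v is None else int(v))
    return frame


def save_participants(records, path) -> None:
    """Write records to the participant CSV schema (empty = missing)."""
    frame = frame_from_records(records)
    # integers render without trailing .0 so re-reading is byte-stable
    frame.to_csv(Path(path), index=False, float_format="%.6g")


def derive_profile(record: ParticipantRecord) -> RiskProfile:
    """Build the chart-input profile from a raw record.

    Raises :class:`MissingInputError` (with the reason in the message) when a
    required chart input cannot be derived, and :class:`OutOfScopeError` for
    ages below 40.
    """
    try:
        sbp = derive_sbp(record.sbp1, record.sbp2, record.sbp3)
        dbp = derive_dbp(record.dbp1, record.dbp2, record.dbp3)
    except MissingInputError:
        raise MissingInputError("missing_bp_readings")
    try:
        smoker = is_smoker(record.current_smoker, record.quit_lt_1yr)
    except MissingInputError:
        raise MissingInputError("missing_smoking_status")
    try:
        diabetic = is_diabetic(record.fasting_glucose, record.glucose_specimen,
                               record.on_dm_medication)
    except MissingInputError:
        raise MissingInputError("missing_diabetes_status")
    return RiskProfile(
        sex=record.sex,
        age=record.age,
        smoker=smoker,
        diabetic=diabetic,
        sbp=sbp,
        dbp=dbp,
        total_cholesterol=record.total_cholesterol,
        on_ht_medication=bool(record.on_ht_medication),
        on_dm_medication=bool(record.on_dm_medication),
        on_chol_medication=bool(record.on_chol_medication),
        bmi=record.bmi,
        met_minutes=record.met_minutes,
        pulse=record.pulse,
        triglycerides=record.triglycerides,
        hdl=record.hdl,
    )
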