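"""Derived variables, threshold flags, and the participant CSV schema."""

import numpy as np
import pytest

from cvdrisk import (
    FlagSet,
    RiskProfile,
    derive_dbp,
    derive_profile,
    derive_sbp,
    elevating_flags,
    has_hypercholesterolemia,
    has_hypertension,
    is_diabetic,
    is_smoker,
    load_participants,
    save_participants,
)
from cvdrisk.definitions import (
    ParticipantRecord,
    frame_from_records,
    records_from_frame,
    validate_participant_frame,
)
from cvdrisk.errors import InputError, MissingInputError


def make_profile(**kw):
    base = dict(sex="male", age=55, smoker=False, diabetic=False,
                sbp=130.0, dbp=80.0)
    base.update(kw)
    return RiskProfile(**base)


class TestDeriveBloodPressure:
    def test_mean_of_last_two(self):
        assert derive_sbp(150, 142, 138) == 140.0

    def test_identical_readings(self):
        assert derive_sbp(120, 120, 120) == 120.0

    def test_first_reading_ignored_and_optional(self):
        assert derive_sbp(None, 130, 134) == 132.0
        assert derive_sbp(999, 130, 134) == 132.0

    @pytest.mark.parametrize("readings", [
        (130, 128, None), (130, None, 128), (130, np.nan, 128),
    ])
    def test_missing_required_reading_raises(self, readings):
        with pytest.raises(MissingInputError):
            derive_sbp(*readings)

    def test_dbp_uses_same_rule(self):
        assert derive_dbp(90, 84, 80) == 82.0

    def test_nonpositive_reading_rejected(self):
        with pytest.raises(InputError):
            derive_sbp(120, -5, 120)


class TestSmokerDefinition:
    @pytest.mark.parametrize("current,quit,expected", [
        (True, False, True),
        (False, True, True),   # quit <1 year ago still counts
        (True, True, True),
        (False, False, False),
    ])
    def test_truth_table(self, current, quit, expected):
        assert is_smoker(current, quit) is expected

    def test_missing_status_raises(self):
        with pytest.raises(MissingInputError):
            is_smoker(None, False)


class TestDiabetesDefinition:
    @pytest.mark.parametrize("glucose,specimen,med,expected", [
        (6.1, "whole_blood", False, True),    # inclusive whole-blood cutoff
        (6.09, "whole_blood", False, False),
        (6.9, "plasma", False, False),        # plasma cutoff is higher
        (7.0, "plasma", False, True),
        (5.0, "plasma", True, True),          # medication overrides
        (None, "plasma", True, True),
    ])
    def test_specimen_specific_thresholds(self, glucose, specimen, med, expected):
        assert is_diabetic(glucose, specimen, med) is expected

    def test_no_glucose_and_no_medication_raises(self):
        with pytest.raises(MissingInputError):
            is_diabetic(None, "plasma", False)

    def test_unknown_specimen_rejected(self):
        with pytest.raises(InputError):
            is_diabetic(6.5, "serum", False)


class TestSingleFactorDefinitions:
    @pytest.mark.parametrize("sbp,dbp,med,expected", [
        (139.9, 89.9, False, False),
        (140.0, 80.0, False, True),
        (120.0, 92.0, False, True),
        (118.0, 76.0, True, True),
    ])
    def test_hypertension(self, sbp, dbp, med, expected):
        assert has_hypertension(sbp, dbp, med) is expected

    @pytest.mark.parametrize("tc,med,expected", [
        (6.2, False, True), (6.19, False, False), (4.0, True, True),
    ])
    def test_hypercholesterolemia(self, tc, med, expected):
        assert has_hypercholesterolemia(tc, med) is expected

    def test_hypercholesterolemia_needs_measurement_or_medication(self):
        with pytest.raises(MissingInputError):
            has_hypercholesterolemia(None, False)


class TestElevatingFlags:
    def test_obesity_cutoff_inclusive(self):
        assert elevating_flags(make_profile(bmi=30.0)).obesity is True
        assert elevating_flags(make_profile(bmi=29.9)).obesity is False

    def test_pulse_cutoff_strict(self):
        assert elevating_flags(make_profile(pulse=90.0)).high_pulse is False
        assert elevating_flags(make_profile(pulse=90.5)).high_pulse is True

    def test_hdl_cutoff_is_sex_specific(self):
        female = make_profile(sex="female", hdl=1.25)
        male = make_profile(sex="male", hdl=1.25)
        assert elevating_flags(female).low_hdl is True
        assert elevating_flags(male).low_hdl is False

    def test_triglycerides_strict_and_met_strict(self):
        assert elevating_flags(make_profile(triglycerides=2.00)) \
            .high_triglycerides is False
        assert elevating_flags(make_profile(met_minutes=600.0)) \
            .low_physical_activity is False
        assert elevating_flags(make_profile(met_minutes=599.9)) \
            .low_physical_activity is True

    def test_missing_inputs_leave_flags_undefined(self):
        flags = elevating_flags(make_profile())  # no bmi/met/pulse/tg/hdl
        assert flags.obesity is None
        assert flags.low_physical_activity is None
        assert flags.high_pulse is None
        assert flags.high_triglycerides is None
        assert flags.low_hdl is None

    def test_any_elevating_skips_undefined_flags(self):
        assert FlagSet(on_ht_medication=False).any_elevating is False
        assert FlagSet(on_ht_medication=False, obesity=True).any_elevating is True
        assert FlagSet().any_elevating is None


class TestThresholdGridOracle:
    def test_randomized_grid_agrees_with_brute_force(self, rng):
        """Independent re-statement of every threshold on values near it."""
        for _ in range(300):
            eps = float(rng.choice([-0.05, -0.01, 0.0, 0.01, 0.05]))
            sbp = 140 + eps
            dbp = 90 + float(rng.choice([-0.05, 0.0, 0.05]))
            med = bool(rng.random() < 0.3)
            assert has_hypertension(sbp, dbp, med) == (
                (sbp >= 140) or (dbp >= 90) or med)
            tc = 6.2 + eps
            assert has_hypercholesterolemia(tc, med) == ((tc >= 6.2) or med)
            glu = float(rng.choice([6.1, 7.0])) + eps
            for spec, cut in (("whole_blood", 6.1), ("plasma", 7.0)):
                assert is_diabetic(glu, spec, med) == ((glu >= cut) or med)
            p = make_profile(bmi=30 + eps, met_minutes=600 + eps * 100,
                             pulse=90 + eps, triglycerides=2.0 + eps,
                             hdl=1.0 + eps,
                             sex=str(rng.choice(["male", "female"])))
            flags = elevating_flags(p)
            assert flags.obesity == (p.bmi >= 30)
            assert flags.low_physical_activity == (p.met_minutes < 600)
            assert flags.high_pulse == (p.pulse > 90)
            assert flags.high_triglycerides == (p.triglycerides > 2.00)
            cut = 1.0 if p.sex == "male" else 1.3
            assert flags.low_hdl == (p.hdl < cut)


def make_record(**kw):
    base = dict(participant_id="P1", stratum_id="S1", cluster_id="C1",
                weight=2.0, sex="male", age=50, sbp1=130, sbp2=128, sbp3=126,
                dbp1=85, dbp2=82, dbp3=80, current_smoker=False,
                quit_lt_1yr=False, fasting_glucose=5.2,
                glucose_specimen="plasma")
    base.update(kw)
    return ParticipantRecord(**base)


class TestParticipantIO:
    def test_round_trip_preserves_values_and_missingness(self, tmp_path):
        records = [
            make_record(),
            make_record(participant_id="P2", sex="female",
                        total_cholesterol=None, bmi=27.5, hdl=1.21),
        ]
        path = tmp_path / "p.csv"
        save_participants(records, path)
        loaded = load_participants(path)
        assert [r.participant_id for r in loaded] == ["P1", "P2"]
        assert loaded[1].total_cholesterol is None
        assert loaded[1].bmi == 27.5
        assert loaded[0].current_smoker is False

    def test_duplicate_ids_rejected(self):
        frame = frame_from_records([make_record(), make_record()])
        with pytest.raises(InputError, match="duplicate participant_id"):
            validate_participant_frame(frame)

    def test_nonpositive_weight_rejected(self):
        frame = frame_from_records([make_record(weight=0.0)])
        with pytest.raises(InputError, match="strictly positive"):
            validate_participant_frame(frame)

    def test_unknown_specimen_rejected(self):
        frame = frame_from_records([make_record()])
        frame.loc[0, "glucose_specimen"] = "serum"
        with pytest.raises(InputError, match="glucose_specimen"):
            validate_participant_frame(frame)

    def test_frame_round_trip(self):
        records = [make_record(), make_record(participant_id="P2", pulse=77)]
        assert records_from_frame(frame_from_records(records)) == records


class TestDeriveProfile:
    def test_reason_codes_for_missing_inputs(self):
        with pytest.raises(MissingInputError, match="missing_bp_readings"):
            derive_profile(make_record(sbp2=None))
        with pytest.raises(MissingInputError, match="missing_smoking_status"):
            derive_profile(make_record(current_smoker=None))
        with pytest.raises(MissingInputError, match="missing_diabetes_status"):
            derive_profile(make_record(fasting_glucose=None))

    def test_complete_record_derives_chart_inputs(self):
        profile = derive_profile(make_record())
        assert profile.sbp == 127.0
        assert profile.dbp == 81.0
        assert profile.smoker is False
        assert profile.diabetic is False
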