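"""Scenario reclassification cascade and flag attribution."""

import dataclasses

import pytest

from cvdrisk import (
    RiskCategory,
    RiskProfile,
    Scenario,
    apply_scenario,
    classify_all,
    flags_by_category,
)
from cvdrisk.cascade import classified_to_frame, exclusion_summary
from cvdrisk.errors import InputError
from conftest import random_profiles
from test_definitions import make_record


def make_profile(**kw):
    base = dict(sex="male", age=55, smoker=False, diabetic=False,
                sbp=130.0, dbp=80.0)
    base.update(kw)
    return RiskProfile(**base)


class TestApplyScenario:
    def test_chart_only_never_changes_category(self):
        p = make_profile(sbp=190.0, dbp=110.0, on_ht_medication=True,
                         total_cholesterol=9.0)
        for cat in RiskCategory:
            assert apply_scenario(cat, p, Scenario.CHART_ONLY) is cat

    @pytest.mark.parametrize("sbp,dbp,promoted", [
        (165.0, 80.0, True),    # SBP alone crosses 160
        (150.0, 102.0, True),   # DBP alone crosses 100
        (160.0, 100.0, True),
        (159.9, 99.9, False),
    ])
    def test_bp_promotion_or_rule(self, sbp, dbp, promoted):
        p = make_profile(sbp=sbp, dbp=dbp)
        got = apply_scenario(RiskCategory.low, p, Scenario.CHART_BP)
        assert got is (RiskCategory.high if promoted else RiskCategory.low)

    def test_bp_promotion_and_rule_requires_both(self):
        p = make_profile(sbp=165.0, dbp=80.0)
        assert apply_scenario(RiskCategory.low, p, Scenario.CHART_BP,
                              bp_rule="and") is RiskCategory.low
        both = make_profile(sbp=165.0, dbp=105.0)
        assert apply_scenario(RiskCategory.low, both, Scenario.CHART_BP,
                              bp_rule="and") is RiskCategory.high

    def test_cholesterol_promotion_inclusive_at_8(self):
        p = make_profile(total_cholesterol=8.0)
        assert apply_scenario(RiskCategory.low, p,
                              Scenario.CHART_BP_CHOL) is RiskCategory.high
        p = make_profile(total_cholesterol=7.99)
        assert apply_scenario(RiskCategory.low, p,
                              Scenario.CHART_BP_CHOL) is RiskCategory.low

    def test_missing_cholesterol_is_a_noop_not_an_error(self):
        p = make_profile()  # tc missing
        assert apply_scenario(RiskCategory.low, p,
                              Scenario.CHART_BP_CHOL) is RiskCategory.low

    def test_medication_promotion_only_in_final_scenario(self):
        p = make_profile(on_ht_medication=True)
        assert apply_scenario(RiskCategory.moderate, p,
                              Scenario.CHART_ONLY) is RiskCategory.moderate
        assert apply_scenario(RiskCategory.moderate, p,
                              Scenario.CHART_BP_CHOL) is RiskCategory.moderate
        assert apply_scenario(RiskCategory.moderate, p,
                              Scenario.CHART_BP_CHOL_MED) is RiskCategory.high

    def test_promotion_never_demotes(self, rng):
        for p in random_profiles(100, rng):
            for scenario in Scenario:
                for cat in RiskCategory:
                    assert apply_scenario(cat, p, scenario).value >= cat.value
        # very-high stays very-high under promotion
        p = make_profile(sbp=200.0, on_ht_medication=True)
        assert apply_scenario(RiskCategory.very_high, p,
                              Scenario.CHART_BP_CHOL_MED) is RiskCategory.very_high

    def test_idempotent(self, rng):
        for p in random_profiles(100, rng):
            for scenario in Scenario:
                once = apply_scenario(RiskCategory.low, p, scenario)
                assert apply_scenario(once, p, scenario) is once

    def test_depends_only_on_promotion_inputs(self, rng):
        """Perturbing fields outside (sbp, dbp, tc, ht-med) changes nothing."""
        for p in random_profiles(50, rng):
            for scenario in Scenario:
                base = apply_scenario(RiskCategory.moderate, p, scenario)
                perturbed = dataclasses.replace(
                    p, bmi=50.0, pulse=120.0, met_minutes=0.0,
                    triglycerides=9.0, hdl=0.5, smoker=not p.smoker)
                assert apply_scenario(RiskCategory.moderate, perturbed,
                                      scenario) is base

    def test_high_sets_nested_across_scenarios(self, rng):
        for p in random_profiles(200, rng):
            cats = [apply_scenario(RiskCategory.low, p, s) for s in Scenario]
            highs = [c.reporting_label == "high_ge20" for c in cats]
            # once promoted, stays promoted in every more inclusive scenario
            assert highs == sorted(highs)


class TestClassifyAll:
    def test_filter_and_exclusion_reasons(self, uniform_charts):
        records = [
            make_record(participant_id="A", age=39),
            make_record(participant_id="B", age=50),
            make_record(participant_id="C", age=55, fasting_glucose=None,
                        on_dm_medication=False),
        ]
        out = classify_all(records, *uniform_charts)
        assert len(out) == 3
        by_id = {c.participant_id: c for c in out}
        assert by_id["A"].excluded and \
            by_id["A"].exclusion_reason == "age_out_of_scope"
        assert not by_id["B"].excluded
        assert by_id["C"].excluded and \
            by_id["C"].exclusion_reason == "missing_diabetes_status"
        tally = exclusion_summary(out)
        assert tally["n"].sum() == 3

    def test_age_bounds_inclusive_40_to_64(self, uniform_charts):
        records = [make_record(participant_id=f"P{a}", age=a)
                   for a in (39, 40, 64, 65)]
        out = {c.participant_id: c for c in
               classify_all(records, *uniform_charts)}
        assert out["P39"].excluded and out["P65"].excluded
        assert not out["P40"].excluded and not out["P64"].excluded

    def test_missing_cholesterol_uses_fallback_chart(self, uniform_charts):
        records = [make_record(participant_id="A", total_cholesterol=5.0),
                   make_record(participant_id="B", total_cholesterol=None)]
        out = {c.participant_id: c for c in
               classify_all(records, *uniform_charts)}
        assert out["A"].variant_used == "with_cholesterol"
        assert out["B"].variant_used == "without_cholesterol"

    def test_empty_input(self, uniform_charts):
        assert classify_all([], *uniform_charts) == []

    def test_duplicate_id_rejected(self, uniform_charts):
        records = [make_record(), make_record()]
        with pytest.raises(InputError, match="duplicate participant_id"):
            classify_all(records, *uniform_charts)

    def test_wrong_variant_order_rejected(self, uniform_charts):
        chart_with, chart_without = uniform_charts
        with pytest.raises(InputError):
            classify_all([], chart_without, chart_with)

    def test_output_frame_has_one_row_per_record(self, uniform_charts):
        records = [make_record(participant_id="A", age=39),
                   make_record(participant_id="B")]
        frame = classified_to_frame(classify_all(records, *uniform_charts))
        assert len(frame) == 2
        assert set(frame.columns) >= {
            "participant_id", "chart_band", "category_CHART_ONLY",
            "category_CHART_BP_CHOL_MED", "excluded", "exclusion_reason"}


class TestFlagsByCategory:
    def test_no_flags_means_zero_prevalence(self, uniform_charts):
        records = [make_record(participant_id=f"P{i}", bmi=22.0,
                               met_minutes=1000.0, pulse=70.0,
                               triglycerides=1.0, hdl=1.6)
                   for i in range(4)]
        out = classify_all(records, *uniform_charts)
        table = flags_by_category(out, Scenario.CHART_ONLY)
        low = table[table.category == "low"]
        assert (low.prevalence_weighted.fillna(0) == 0).all()

    def test_single_moderate_obese_participant(self, uniform_charts, threshold_charts):
        # threshold chart puts a 40-49yo with SBP 145 into the moderate band
        record = make_record(age=45, sbp1=150, sbp2=145, sbp3=145, bmi=33.0)
        out = classify_all([record], *threshold_charts)
        assert out[0].categories[Scenario.CHART_ONLY] is RiskCategory.moderate
        table = flags_by_category(out, Scenario.CHART_ONLY)
        mod = table[table.category == "moderate"].set_index("flag")
        assert mod.loc["obesity", "prevalence_weighted"] == 1.0
        assert mod.loc["any_elevating", "prevalence_weighted"] == 1.0

    def test_missingness_counted_per_flag(self, uniform_charts):
        records = [make_record(participant_id="A", bmi=None),
                   make_record(participant_id="B", bmi=35.0)]
        table = flags_by_category(classify_all(records, *uniform_charts),
                                  Scenario.CHART_ONLY)
        obesity_low = table[(table.category == "low")
                            & (table.flag == "obesity")].iloc[0]
        assert obesity_low.n_missing == 1
        assert obesity_low.prevalence_unweighted == 1.0
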