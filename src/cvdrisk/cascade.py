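"""Scenario-based reclassification and flag attribution.

Charts alone understate population treatment need: the practice notes that
accompany the charts promote individuals to the high-risk category when
blood pressure is at or above 160/100 mmHg or total cholesterol is at or
above 8.0 mmol/l, and current antihypertensive treatment marks risk as
higher than charted.  This module applies four nested inclusion-criteria
scenarios to chart-derived categories:

* ``CHART_ONLY``       — the chart category unchanged;
* ``CHART_BP``         — promote to high if BP >= 160/100;
* ``CHART_BP_CHOL``    — additionally promote if cholesterol >= 8.0 mmol/l;
* ``CHART_BP_CHOL_MED``— additionally promote if on antihypertensive drugs.

Promotion never demotes, so the high-risk sets are nested across scenarios
by construction, which is the qualitative signature this analysis exists
to quantify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

from .chart import (
    ChartSpec,
    RiskCategory,
    RiskProfile,
    band_to_category,
    select_variant,
)
from .definitions import FlagSet, derive_profile, elevating_flags
from .errors import InputError, MissingInputError, OutOfScopeError

logger = logging.getLogger(__name__)

# Promotion thresholds from the chart practice notes
SBP_PROMOTION_THRESHOLD = 160.0   # mmHg, inclusive
DBP_PROMOTION_THRESHOLD = 100.0   # mmHg, inclusive
CHOL_PROMOTION_THRESHOLD = 8.0    # mmol/l, inclusive


class Scenario(Enum):
    """The four inclusion-criteria scenarios, ordered by inclusiveness."""

    CHART_ONLY = 0
    CHART_BP = 1
    CHART_BP_CHOL = 2
    CHART_BP_CHOL_MED = 3

    @property
    def description(self) -> str:
        return {
            Scenario.CHART_ONLY: "simple application of the chart",
            Scenario.CHART_BP: "chart + BP >= 160/100 promoted to high",
            Scenario.CHART_BP_CHOL:
                "chart + BP 160/100 + cholesterol >= 8.0 mmol/l",
            Scenario.CHART_BP_CHOL_MED:
                "chart + BP 160/100 + cholesterol 8.0 + on HT medication",
        }[self]


def _bp_promotes(profile: RiskProfile, bp_rule: str) -> bool:
    high_sbp = profile.sbp >= SBP_PROMOTION_THRESHOLD
    high_dbp = profile.dbp >= DBP_PROMOTION_THRESHOLD
    if bp_rule == "or":
        return high_sbp or high_dbp
    if bp_rule == "and":
        return high_sbp and high_dbp
    raise InputError(f"bp_rule must be 'or' or 'and', got {bp_rule!r}")


def apply_scenario(chart_category: RiskCategory, profile: RiskProfile,
                   scenario: Scenario, bp_rule: str = "or") -> RiskCategory:
    """Promote a chart category per the scenario's inclusion criteria.

    The 160/100 slash notation is read as SBP >= 160 OR DBP >= 100 by
    default (``bp_rule="or"``); ``bp_rule="and"`` requires both.  Promotion
    targets the high category and never demotes: an individual already
    charted very-high stays very-high.  When the scenario needs cholesterol
    but it is missing, the cholesterol criterion is skipped with a logged
    notice (the record keeps its BP-based promotion, if any).
    """
    promote = False
    if scenario.value >= Scenario.CHART_BP.value:
        promote = promote or _bp_promotes(profile, bp_rule)
    if scenario.value >= Scenario.CHART_BP_CHOL.value:
        if profile.total_cholesterol is None:
            logger.debug(
                "cholesterol missing; scenario %s cholesterol criterion "
                "skipped for this record", scenario.name,
            )
        elif profile.total_cholesterol >= CHOL_PROMOTION_THRESHOLD:
            promote = True
    if scenario.value >= Scenario.CHART_BP_CHOL_MED.value:
        promote = promote or bool(profile.on_ht_medication)
    if promote:
        return max(chart_category, RiskCategory.high,
                   key=lambda c: c.value)
    return chart_category


@dataclass
class ClassifiedParticipant:
    """Per-person classification outputs behind the population tables."""

    participant_id: str
    stratum_id: str = ""
    cluster_id: str = ""
    weight: float = 1.0
    sex: str = ""
    age: Optional[float] = None
    variant_used: Optional[str] = None
    chart_band: Optional[str] = None
    categories: dict = field(default_factory=dict)  # Scenario -> RiskCategory
    flags: Optional[FlagSet] = None
    profile: Optional[RiskProfile] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None


DEFAULT_AGE_RANGE = (40, 64)


def classify_all(records, chart_with: ChartSpec, chart_without: ChartSpec,
                 *, age_range=DEFAULT_AGE_RANGE,
                 bp_rule: str = "or") -> list[ClassifiedParticipant]:
    """Classify every record, excluding (with reasons) those out of scope.

    Scope is ages ``age_range`` inclusive (default 40-64).  Records missing
    a required chart input after the cholesterol-variant fallback are
    excluded, never imputed.  Returns one entry per input record, with
    ``excluded`` set on the dropped ones so denominators reconcile.
    """
    seen = set()
    for r in records:
        if r.participant_id in seen:
            raise InputError(f"duplicate participant_id {r.participant_id!r}")
        seen.add(r.participant_id)
    if chart_with.variant != "with_cholesterol":
        raise InputError("chart_with must be the with_cholesterol variant")
    if chart_without.variant != "without_cholesterol":
        raise InputError("chart_without must be the without_cholesterol variant")

    lo, hi = age_range
    out = []
    for record in records:
        base = dict(participant_id=record.participant_id,
                    stratum_id=record.stratum_id,
                    cluster_id=record.cluster_id,
                    weight=record.weight, sex=record.sex, age=record.age)
        if record.age is None or not (lo <= record.age <= hi):
            out.append(ClassifiedParticipant(
                **base, excluded=True, exclusion_reason="age_out_of_scope"))
            continue
        try:
            profile = derive_profile(record)
        except (MissingInputError, OutOfScopeError, InputError) as exc:
            out.append(ClassifiedParticipant(
                **base, excluded=True, exclusion_reason=str(exc)))
            continue
        variant = select_variant(profile)
        chart = chart_with if variant == "with_cholesterol" else chart_without
        band = chart.lookup(profile)
        chart_category = band_to_category(band)
        categories = {
            scenario: apply_scenario(chart_category, profile, scenario,
                                     bp_rule=bp_rule)
            for scenario in Scenario
        }
        out.append(ClassifiedParticipant(
            **base, variant_used=variant, chart_band=band,
            categories=categories, flags=elevating_flags(profile),
            profile=profile))
    n_excl = sum(c.excluded for c in out)
    logger.info("classified %d records, excluded %d", len(out) - n_excl, n_excl)
    return out


def exclusion_summary(classified) -> pd.DataFrame:
    """Tally of exclusion reasons (one row per reason, plus the retained count)."""
    rows = [{"status": "classified" if not c.excluded else "excluded",
             "reason": c.exclusion_reason or ""} for c in classified]
    frame = pd.DataFrame(rows, columns=["status", "reason"])
    tally = (frame.groupby(["status", "reason"]).size()
             .rename("n").reset_index()
             .sort_values(["status", "reason"], kind="stable")
             .reset_index(drop=True))
    return tally


FLAG_NAMES = FlagSet.ELEVATING + ("any_elevating",)


def flags_by_category(classified, scenario: Scenario) -> pd.DataFrame:
    """Cross-tabulate elevating flags against reporting risk category.

    For each category (low / moderate / high_ge20) and flag, reports the
    unweighted count, the number with the flag's inputs missing, and the
    weighted and unweighted prevalence among those with the flag defined.
    """
    rows = []
    kept = [c for c in classified if not c.excluded]
    for label in ("low", "moderate", "high_ge20"):
        members = [c for c in kept
                   if c.categories[scenario].reporting_label == label]
        for flag in FLAG_NAMES:
            vals = [(getattr(c.flags, flag) if flag != "any_elevating"
                     else c.flags.any_elevating, c.weight) for c in members]
            defined = [(v, w) for v, w in vals if v is not None]
            n_missing = len(vals) - len(defined)
            sw = sum(w for _, w in defined)
            rows.append({
                "category": label,
                "flag": flag,
                "n": len(members),
                "n_defined": len(defined),
                "n_missing": n_missing,
                "prevalence_unweighted": (
                    sum(bool(v) for v, _ in defined) / len(defined)
                    if defined else float("nan")),
                "prevalence_weighted": (
                    sum(w for v, w in defined if v) / sw
                    if sw > 0 else float("nan")),
            })
    return pd.DataFrame(rows)


def classified_to_frame(classified) -> pd.DataFrame:
    """Per-participant classification output in the documented CSV layout."""
    rows = []
    for c in classified:
        row = {
            "participant_id": c.participant_id,
            "variant_used": c.variant_used or "",
            "chart_band": c.chart_band or "",
            "excluded": int(c.excluded),
            "exclusion_reason": c.exclusion_reason or "",
        }
        for scenario in Scenario:
            row[f"category_{scenario.name}"] = (
                c.categories[scenario].reporting_label if c.categories else "")
        for flag in FLAG_NAMES:
            if c.flags is None:
                row[f"flag_{flag}"] = ""
            else:
                v = (getattr(c.flags, flag) if flag != "any_elevating"
                     else c.flags.any_elevating)
                row[f"flag_{flag}"] = "" if v is None else int(v)
        rows.append(row)
    return pd.DataFrame(rows)
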