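"""End-to-end analysis: ingest → derivation → classification → estimation.

Produces the four canonical population tables of a total-CVD-risk survey
report:

* single risk-factor prevalence (hypertension, diabetes,
  hypercholesterolemia, smoking) by sex × age group;
* chart risk-category distribution (low / moderate / high >=20%) by
  sex × age group;
* low / moderate / high proportions under each of the four inclusion
  scenarios;
* elevating-flag prevalence within each risk category.

Every table row carries its unweighted denominator, proportions within a
partition sum to one, and an exclusion report reconciles the input count
with the analysed count.  Output is deterministic given inputs and
configuration; the provenance block records config and chart checksums so
runs can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cascade import (
    Scenario,
    classified_to_frame,
    classify_all,
    exclusion_summary,
    flags_by_category,
)
from .chart import ChartSpec, load_chart
from .errors import ConfigError
from .survey import SurveyDesign, grouped_estimates, weighted_proportion

logger = logging.getLogger(__name__)

SINGLE_FACTORS = ("hypertension", "diabetes", "hypercholesterolemia", "smoking")


@dataclass
class AnalysisConfig:
    """Pipeline switches; defaults reproduce the standard analysis."""

    bp_rule: str = "or"            # 160/100 promotion: SBP>=160 OR/AND DBP>=100
    ci_method: str = "logit"
    age_range: tuple = (40, 64)
    flag_scenario: str = "CHART_ONLY"  # scenario for the flags-by-category table

    def validate(self) -> None:
        if self.bp_rule not in ("or", "and"):
            raise ConfigError(f"bp_rule must be 'or' or 'and', got {self.bp_rule!r}")
        if self.ci_method not in ("logit", "wald"):
            raise ConfigError(f"ci_method must be 'logit' or 'wald'")
        if self.flag_scenario not in Scenario.__members__:
            raise ConfigError(f"unknown scenario {self.flag_scenario!r}")
        lo, hi = self.age_range
        if not 40 <= lo <= hi:
            raise ConfigError("age_range must lie within the 40+ chart scope")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        return d


@dataclass
class ResultBundle:
    """All pipeline outputs for one run."""

    single_factor_prevalence: pd.DataFrame     # by sex × age group
    category_distribution: pd.DataFrame        # chart-only, by sex × age group
    scenario_distribution: pd.DataFrame        # low/mod/high × scenario
    flags_by_category: pd.DataFrame
    exclusions: pd.DataFrame
    classified_frame: pd.DataFrame = field(repr=False)
    provenance: dict = field(default_factory=dict)


def _chart_checksum(chart: ChartSpec) -> str:
    payload = json.dumps(
        {"region_id": chart.region_id, "variant": chart.variant,
         "cells": sorted((str(k), v) for k, v in chart.cells.items())},
        sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def _single_factor_indicator(c, factor) -> Optional[bool]:
    flags = c.flags
    if factor == "hypertension":
        return flags.hypertension_single
    if factor == "diabetes":
        return c.profile.diabetic
    if factor == "hypercholesterolemia":
        return flags.hypercholesterolemia_single
    return c.profile.smoker


def run_analysis(records, chart_with: ChartSpec, chart_without: ChartSpec,
                 config: Optional[AnalysisConfig] = None) -> ResultBundle:
    """Run the full analysis on raw records against the two chart variants."""
    config = config or AnalysisConfig()
    config.validate()
    classified = classify_all(records, chart_with, chart_without,
                              age_range=config.age_range,
                              bp_rule=config.bp_rule)
    kept = [c for c in classified if not c.excluded]
    design = SurveyDesign.from_classified(kept) if kept else SurveyDesign(
        np.array([]), np.array([]), np.array([], dtype=float))

    frame = pd.DataFrame({
        "sex": [c.sex for c in kept],
        "age": [c.age for c in kept],
    })
    for factor in SINGLE_FACTORS:
        frame[factor] = [
            np.nan if (v := _single_factor_indicator(c, factor)) is None
            else float(v) for c in kept]
    table2 = grouped_estimates(frame, SINGLE_FACTORS, design,
                               method=config.ci_method)

    for label in ("low", "moderate", "high_ge20"):
        frame[f"cat_{label}"] = [
            float(c.categories[Scenario.CHART_ONLY].reporting_label == label)
            for c in kept]
    table3 = grouped_estimates(
        frame, [f"cat_{label}" for label in ("low", "moderate", "high_ge20")],
        design, method=config.ci_method)
    table3["outcome"] = table3["outcome"].str.removeprefix("cat_")

    rows = []
    for scenario in Scenario:
        for label in ("low", "moderate", "high_ge20"):
            x = [float(c.categories[scenario].reporting_label == label)
                 for c in kept]
            est = weighted_proportion(x, design, method=config.ci_method)
            rows.append({
                "scenario": scenario.name, "category": label,
                "n_unweighted": est.n_unweighted,
                "proportion": est.proportion,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "method": est.method,
            })
    table4 = pd.DataFrame(rows)

    table5 = flags_by_category(classified, Scenario[config.flag_scenario])

    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "chart_with_sha256": _chart_checksum(chart_with),
        "chart_without_sha256": _chart_checksum(chart_without),
        "n_input": len(classified),
        "n_classified": len(kept),
        "n_excluded": len(classified) - len(kept),
    }
    return ResultBundle(
        single_factor_prevalence=table2,
        category_distribution=table3,
        scenario_distribution=table4,
        flags_by_category=table5,
        exclusions=exclusion_summary(classified),
        classified_frame=classified_to_frame(classified),
        provenance=provenance,
    )


def _pct(v) -> str:
    return "" if v is None or (isinstance(v, float) and np.isnan(v)) \
        else f"{100 * v:.1f}"


def summary_text(bundle: ResultBundle) -> str:
    """Human-readable summary with percentages to one decimal."""
    lines = ["Total CVD risk analysis summary", "=" * 31, ""]
    p = bundle.provenance
    lines.append(f"records in: {p['n_input']}  classified: {p['n_classified']}"
                 f"  excluded: {p['n_excluded']}")
    lines.append("")
    lines.append("Risk-category distribution by inclusion scenario "
                 "(weighted %, 95% CI):")
    for _, row in bundle.scenario_distribution.iterrows():
        ci = (f" ({_pct(row.ci_low)}-{_pct(row.ci_high)})"
              if row.ci_low is not None else "")
        lines.append(f"  {row.scenario:<18} {row.category:<9} "
                     f"{_pct(row.proportion):>5}{ci}")
    lines.append("")
    lines.append("Single risk-factor prevalence, ages 40-64 (weighted %):")
    t2 = bundle.single_factor_prevalence
    total = t2[(t2.sex == "total") & (t2.age_group == "40-64")]
    for _, row in total.iterrows():
        lines.append(f"  {row.outcome:<22} {_pct(row.proportion):>5} "
                     f"(n={row.n_unweighted})")
    return "\n".join(lines) + "\n"


def write_bundle(bundle: ResultBundle, outdir) -> None:
    """Write all tables, the per-participant CSV and the provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.single_factor_prevalence.to_csv(
        outdir / "single_factor_prevalence.csv", index=False)
    bundle.category_distribution.to_csv(
        outdir / "category_distribution.csv", index=False)
    bundle.scenario_distribution.to_csv(
        outdir / "scenario_distribution.csv", index=False)
    bundle.flags_by_category.to_csv(
        outdir / "flags_by_category.csv", index=False)
    bundle.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    bundle.classified_frame.to_csv(outdir / "classified.csv", index=False)
    with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(summary_text(bundle))
    logger.info("analysis outputs written to %s", outdir)


def run_from_files(records_path, chart_with_path, chart_without_path,
                   config: Optional[AnalysisConfig] = None) -> ResultBundle:
    from .definitions import load_participants

    chart_with = load_chart(chart_with_path)
    chart_without = load_chart(chart_without_path)
    return run_analysis(load_participants(records_path), chart_with,
                        chart_without, config)
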