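"""Risk-chart encoding, validation and lookup.

WHO/ISH-style charts are colour-coded lookup tables giving the 10-year
probability band of a fatal or non-fatal cardiovascular event from sex,
age band, smoking status, diabetes status and systolic blood pressure
band, optionally stratified by a total-cholesterol column.  The chart is
*data*, not a formula: this module loads a chart definition file (CSV or
JSON), validates that it covers the full cross-product of inputs, and
evaluates it on derived individual profiles.

Two chart variants exist: ``with_cholesterol`` (640 cells: 2 sexes x
4 age bands x 2 smoking x 2 diabetes x 4 SBP bands x 5 cholesterol
columns) and ``without_cholesterol`` (128 cells).  Individuals with a cholesterol
measurement are scored on the former; individuals with missing
cholesterol fall back to the latter.
"""

from __future__ import annotations

import csv
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from .errors import (
    ChartValidationError,
    InputError,
    OutOfScopeError,
    VariantMismatchError,
)

logger = logging.getLogger(__name__)

# Admissible band labels, in increasing risk order.
RISK_BANDS = ("<10", "10-<20", "20-<30", "30-<40", ">=40")
RISK_BAND_ORDER = {b: i for i, b in enumerate(RISK_BANDS)}

AGE_BANDS = ("40-49", "50-59", "60-69", "70+")
SBP_BANDS = ("<140", "140-159", "160-179", ">=180")
CHOL_BANDS = (4, 5, 6, 7, 8)
SEXES = ("male", "female")
VARIANTS = ("with_cholesterol", "without_cholesterol")


class RiskCategory(Enum):
    """Clinical risk category derived from a chart band.

    ``low`` is <10% 10-year risk, ``moderate`` 10-<20%, ``high`` 20-<30%
    and ``very_high`` >=30%.  For population reporting, ``high`` and
    ``very_high`` collapse into a single "high (>=20%)" column.
    """

    low = 0
    moderate = 1
    high = 2
    very_high = 3

    @property
    def reporting_label(self) -> str:
        if self in (RiskCategory.high, RiskCategory.very_high):
            return "high_ge20"
        return self.name

    def __lt__(self, other):
        if isinstance(other, RiskCategory):
            return self.value < other.value
        return NotImplemented

    def __le__(self, other):
        if isinstance(other, RiskCategory):
            return self.value <= other.value
        return NotImplemented


REPORTING_CATEGORIES = ("low", "moderate", "high_ge20")


def band_to_category(band: str) -> RiskCategory:
    """Map a chart risk band to its clinical category.

    The two top bands (30-<40 and >=40) both mean "very high"; charts may
    distinguish them but the categorisation does not.
    """
    if band not in RISK_BAND_ORDER:
        raise InputError(f"unknown risk band label: {band!r}")
    return {
        "<10": RiskCategory.low,
        "10-<20": RiskCategory.moderate,
        "20-<30": RiskCategory.high,
        "30-<40": RiskCategory.very_high,
        ">=40": RiskCategory.very_high,
    }[band]


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


@dataclass(frozen=True)
class RiskProfile:
    """Derived chart inputs plus the ancillary threshold inputs.

    Continuous measurements use ``None`` for missing; numeric sentinels
    (zero or negative readings) are rejected at construction.
    """

    sex: str
    age: float
    smoker: bool
    diabetic: bool
    sbp: float
    dbp: float
    total_cholesterol: Optional[float] = None
    on_ht_medication: bool = False
    on_dm_medication: bool = False
    on_chol_medication: bool = False
    bmi: Optional[float] = None
    met_minutes: Optional[float] = None
    pulse: Optional[float] = None
    triglycerides: Optional[float] = None
    hdl: Optional[float] = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise InputError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age < 40:
            raise OutOfScopeError(
                f"age {self.age} is below 40; the risk charts cover ages 40 and over"
            )
        if _is_missing(self.sbp) or _is_missing(self.dbp):
            raise InputError("sbp and dbp are required chart inputs")
        if self.sbp <= 0 or self.dbp <= 0:
            raise InputError(
                f"blood pressure must be positive (sbp={self.sbp}, dbp={self.dbp})"
            )
        if not _is_missing(self.total_cholesterol) and self.total_cholesterol <= 0:
            raise InputError(
                f"total cholesterol must be positive when present, got "
                f"{self.total_cholesterol}; use an empty value for missing"
            )


def to_age_band(age: float) -> str:
    """Decade band used by the chart rows; ages below 40 are out of scope."""
    if age < 40:
        raise OutOfScopeError(f"age {age} is below the chart's 40+ scope")
    if age < 50:
        return "40-49"
    if age < 60:
        return "50-59"
    if age < 70:
        return "60-69"
    return "70+"


def to_sbp_band(sbp: float) -> str:
    """SBP chart row; band edges are lower-inclusive (140 -> "140-159")."""
    if sbp <= 0:
        raise InputError(f"sbp must be positive, got {sbp}")
    if sbp < 140:
        return "<140"
    if sbp < 160:
        return "140-159"
    if sbp < 180:
        return "160-179"
    return ">=180"


def to_chol_band(tc: float) -> int:
    """Nearest integer cholesterol column 4-8 (mmol/l), midpoints round up."""
    if tc <= 0:
        raise InputError(f"total cholesterol must be positive, got {tc}")
    # floor(x + 0.5) rounds exact midpoints up, unlike banker's round()
    nearest = math.floor(tc + 0.5)
    return int(min(8, max(4, nearest)))


def select_variant(profile: RiskProfile) -> str:
    """Chart variant for a profile: cholesterol chart iff cholesterol measured."""
    if _is_missing(profile.total_cholesterol):
        return "without_cholesterol"
    return "with_cholesterol"


@dataclass(frozen=True)
class ChartCell:
    sex: str
    age_band: str
    smoker: bool
    diabetic: bool
    sbp_band: str
    chol_band: Optional[int]
    risk_band: str

    @property
    def key(self):
        return (self.sex, self.age_band, self.smoker, self.diabetic,
                self.sbp_band, self.chol_band)


def _expected_keys(variant: str):
    chol = CHOL_BANDS if variant == "with_cholesterol" else (None,)
    return itertools.product(
        SEXES, AGE_BANDS, (False, True), (False, True), SBP_BANDS, chol
    )


def _fmt_key(key) -> str:
    sex, age_band, smoker, diabetic, sbp_band, chol_band = key
    parts = [sex, age_band, f"smoker={int(smoker)}", f"diabetic={int(diabetic)}",
             f"sbp={sbp_band}"]
    if chol_band is not None:
        parts.append(f"chol={chol_band}")
    return "(" + ", ".join(parts) + ")"


@dataclass
class ChartSpec:
    """A complete, validated risk chart for one region and variant."""

    region_id: str
    variant: str
    cells: dict = field(repr=False)  # key tuple -> risk band label

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def validate(self) -> None:
        """Check exhaustiveness and label admissibility; list every problem."""
        problems = []
        if self.variant not in VARIANTS:
            raise ChartValidationError([f"unknown variant {self.variant!r}"])
        expected = set(_expected_keys(self.variant))
        present = set(self.cells)
        for key in sorted(present - expected, key=str):
            problems.append(f"unexpected cell key {_fmt_key(key)}")
        for key in sorted(expected - present, key=str):
            problems.append(f"missing cell {_fmt_key(key)}")
        for key, band in sorted(self.cells.items(), key=str):
            if band not in RISK_BAND_ORDER:
                problems.append(
                    f"unknown risk band label {band!r} at {_fmt_key(key)}"
                )
        if problems:
            for p in problems:
                logger.error("chart %s: %s", self.region_id, p)
            raise ChartValidationError(problems)
        logger.info(
            "chart %s (%s): %d cells validated", self.region_id, self.variant,
            self.n_cells,
        )

    def lookup(self, profile: RiskProfile) -> str:
        """Risk band for a profile; the chart variant must match the profile."""
        variant = select_variant(profile)
        if variant != self.variant:
            raise VariantMismatchError(
                f"profile requires the {variant} chart but this chart is "
                f"{self.variant}"
            )
        chol_band = (
            to_chol_band(profile.total_cholesterol)
            if variant == "with_cholesterol" else None
        )
        key = (profile.sex, to_age_band(profile.age), bool(profile.smoker),
               bool(profile.diabetic), to_sbp_band(profile.sbp), chol_band)
        return self.cells[key]


def chart_lookup(chart: ChartSpec, profile: RiskProfile) -> str:
    """Functional form of :meth:`ChartSpec.lookup`."""
    return chart.lookup(profile)


# ---------------------------------------------------------------------------
# Chart file I/O

CHART_CSV_COLUMNS = ("region_id", "variant", "sex", "age_band", "smoker",
                     "diabetic", "sbp_band", "chol_band", "risk_band")


def _parse_bool(raw: str, what: str, problems: list) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    problems.append(f"{what} must be 0 or 1, got {raw!r}")
    return False


def _rows_to_spec(rows) -> ChartSpec:
    problems: list[str] = []
    region_ids, variants = set(), set()
    cells: dict = {}
    for i, row in enumerate(rows, start=1):
        region_ids.add(row["region_id"])
        variant = row["variant"]
        variants.add(variant)
        smoker = _parse_bool(str(row["smoker"]), f"row {i}: smoker", problems)
        diabetic = _parse_bool(str(row["diabetic"]), f"row {i}: diabetic", problems)
        chol_raw = row.get("chol_band")
        if chol_raw in (None, ""):
            chol_band = None
        else:
            try:
                chol_band = int(chol_raw)
            except (TypeError, ValueError):
                problems.append(f"row {i}: chol_band must be an integer, got {chol_raw!r}")
                chol_band = None
        if variant == "with_cholesterol" and chol_band is None:
            problems.append(f"row {i}: with_cholesterol row lacks chol_band")
        if variant == "without_cholesterol" and chol_band is not None:
            problems.append(f"row {i}: without_cholesterol row carries chol_band")
        key = (row["sex"], row["age_band"], smoker, diabetic, row["sbp_band"],
               chol_band)
        if key in cells:
            problems.append(f"duplicate cell key {_fmt_key(key)}")
        cells[key] = row["risk_band"]
    if len(region_ids) > 1:
        problems.append(f"mixed region_id values: {sorted(region_ids)}")
    if len(variants) > 1:
        problems.append(f"mixed variant values: {sorted(variants)}")
    if problems:
        for p in problems:
            logger.error("chart file: %s", p)
        raise ChartValidationError(problems)
    spec = ChartSpec(region_id=region_ids.pop() if region_ids else "",
                     variant=variants.pop() if variants else "",
                     cells=cells)
    spec.validate()
    return spec


def load_chart(path) -> ChartSpec:
    """Load and validate a chart definition file (CSV or JSON by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        rows = [
            {"region_id": doc["region_id"], "variant": doc["variant"], **cell}
            for cell in doc["cells"]
        ]
        return _rows_to_spec(rows)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(CHART_CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing_cols:
            raise ChartValidationError(
                [f"missing column {c!r} in chart CSV header" for c in sorted(missing_cols)]
            )
        return _rows_to_spec(list(reader))


def save_chart(spec: ChartSpec, path) -> None:
    """Write a chart to CSV or JSON (by extension), one cell per row."""
    path = Path(path)
    items = sorted(spec.cells.items(), key=str)
    if path.suffix.lower() == ".json":
        doc = {
            "region_id": spec.region_id,
            "variant": spec.variant,
            "cells": [
                {"sex": k[0], "age_band": k[1], "smoker": int(k[2]),
                 "diabetic": int(k[3]), "sbp_band": k[4],
                 "chol_band": k[5], "risk_band": band}
                for k, band in items
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CHART_CSV_COLUMNS)
        for k, band in items:
            sex, age_band, smoker, diabetic, sbp_band, chol_band = k
            writer.writerow([
                spec.region_id, spec.variant, sex, age_band, int(smoker),
                int(diabetic), sbp_band, "" if chol_band is None else chol_band,
                band,
            ])
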