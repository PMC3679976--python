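"""Design-based prevalence estimation for stratified cluster samples.

Point estimates are ratio means Σwx / Σw under the survey weights
(sample × non-response × post-stratification, pre-multiplied into one
column).  Variance is estimated by Taylor linearization treating clusters
as primary sampling units drawn with replacement within strata — the
standard with-replacement approximation used by survey software — with
degrees of freedom (number of clusters − number of strata).

Confidence intervals default to the logit scale, back-transformed and
therefore respecting [0, 1]; a Wald interval (clamped) is available for
comparability with analyses that report symmetric intervals, which can
produce nominal bounds below zero for rare outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

CI_METHODS = ("logit", "wald")


@dataclass
class SurveyDesign:
    """Per-record design variables: stratum, cluster (PSU) and weight."""

    stratum: np.ndarray
    cluster: np.ndarray
    weight: np.ndarray

    def __post_init__(self):
        self.stratum = np.asarray(self.stratum)
        self.cluster = np.asarray(self.cluster)
        self.weight = np.asarray(self.weight, dtype=float)
        n = len(self.weight)
        if not (len(self.stratum) == len(self.cluster) == n):
            raise InputError("design arrays must have equal length")
        if n and (~np.isfinite(self.weight) | (self.weight <= 0)).any():
            raise InputError("weights must be finite and strictly positive")

    def __len__(self):
        return len(self.weight)

    def subset(self, mask) -> "SurveyDesign":
        return SurveyDesign(self.stratum[mask], self.cluster[mask],
                            self.weight[mask])

    @classmethod
    def from_classified(cls, classified) -> "SurveyDesign":
        return cls(
            stratum=np.array([c.stratum_id for c in classified]),
            cluster=np.array([f"{c.stratum_id}|{c.cluster_id}" for c in classified]),
            weight=np.array([c.weight for c in classified], dtype=float),
        )


@dataclass
class PrevalenceEstimate:
    """Weighted proportion with design-based 95% CI.

    ``ci_low``/``ci_high`` are ``None`` when the variance is unavailable
    (a stratum with fewer than two clusters, or an empty domain).
    """

    proportion: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    n_unweighted: int
    sum_weights: float
    method: str

    def __post_init__(self):
        if self.ci_low is not None and self.ci_high is not None:
            assert self.ci_low - 1e-12 <= self.proportion <= self.ci_high + 1e-12


def _taylor_variance(x: np.ndarray, design: SurveyDesign, p: float):
    """Linearized variance of the ratio mean, and its degrees of freedom.

    Returns ``(None, None)`` when any stratum holds fewer than two
    clusters (between-PSU variance is then undefined).
    """
    w = design.weight
    total_w = w.sum()
    # score residuals of the ratio estimator
    z = w * (x - p) / total_w
    frame = pd.DataFrame({"stratum": design.stratum, "cluster": design.cluster,
                          "z": z})
    by_cluster = frame.groupby(["stratum", "cluster"], sort=False)["z"].sum()
    clusters_per_stratum = by_cluster.groupby(level="stratum").size()
    if (clusters_per_stratum < 2).any():
        return None, None
    var = 0.0
    for _, e in by_cluster.groupby(level="stratum"):
        n_h = len(e)
        var += n_h / (n_h - 1) * ((e - e.mean()) ** 2).sum()
    df = int(clusters_per_stratum.sum() - len(clusters_per_stratum))
    return float(var), df


def weighted_proportion(indicator, design: SurveyDesign,
                        method: str = "logit") -> PrevalenceEstimate:
    """Design-based weighted prevalence of a boolean indicator.

    Missing indicator values (``None``/NaN) are excluded from both
    numerator and denominator; the design is subset accordingly.
    """
    if method not in CI_METHODS:
        raise InputError(f"CI method must be one of {CI_METHODS}, got {method!r}")
    x = np.asarray(
        [np.nan if v is None else float(v) for v in indicator], dtype=float)
    if len(x) != len(design):
        raise InputError("indicator and design must have equal length")
    keep = ~np.isnan(x)
    x, design = x[keep], design.subset(keep)
    if len(x) == 0:
        return PrevalenceEstimate(float("nan"), None, None, 0, 0.0, method)

    w = design.weight
    p = float((w * x).sum() / w.sum())
    var, df = _taylor_variance(x, design, p)
    if var is None or df < 1:
        return PrevalenceEstimate(p, None, None, len(x), float(w.sum()),
                                  method + " (CI undefined)")
    se = np.sqrt(var)
    if se == 0.0:
        return PrevalenceEstimate(p, p, p, len(x), float(w.sum()), method)
    t = float(stats.t.ppf(0.975, df))
    if method == "wald":
        lo = max(0.0, p - t * se)
        hi = min(1.0, p + t * se)
    else:
        if p <= 0.0 or p >= 1.0:
            # logit undefined at the boundary; degenerate interval
            lo = hi = p
        else:
            logit = np.log(p / (1 - p))
            se_logit = se / (p * (1 - p))
            lo = float(1 / (1 + np.exp(-(logit - t * se_logit))))
            hi = float(1 / (1 + np.exp(-(logit + t * se_logit))))
    return PrevalenceEstimate(p, lo, hi, len(x), float(w.sum()), method)


AGE_GROUPS = (("40-49", 40, 49), ("50-59", 50, 59), ("60-64", 60, 64))


def age_group_label(age: float) -> Optional[str]:
    for label, lo, hi in AGE_GROUPS:
        if lo <= age <= hi:
            return label
    return None


def grouped_estimates(frame: pd.DataFrame, outcome_cols, design: SurveyDesign,
                      method: str = "logit") -> pd.DataFrame:
    """Prevalence of each outcome by sex × age group, with margins.

    ``frame`` must carry ``sex`` and ``age`` columns aligned with
    ``design``; outcomes are boolean columns (NaN = missing).  Groups are
    the cross of {male, female, total} × {40-49, 50-59, 60-64, 40-64},
    the canonical survey-report layout.
    """
    age_labels = frame["age"].map(age_group_label)
    rows = []
    sex_groups = [("male",), ("female",), ("male", "female")]
    age_groups = [lab for lab, _, _ in AGE_GROUPS] + ["40-64"]
    for sexes in sex_groups:
        sex_label = sexes[0] if len(sexes) == 1 else "total"
        sex_mask = frame["sex"].isin(sexes).to_numpy()
        for age_label in age_groups:
            if age_label == "40-64":
                age_mask = age_labels.notna().to_numpy()
            else:
                age_mask = (age_labels == age_label).to_numpy()
            mask = sex_mask & age_mask
            for outcome in outcome_cols:
                est = weighted_proportion(
                    frame.loc[mask, outcome], design.subset(mask), method)
                rows.append({
                    "sex": sex_label, "age_group": age_label,
                    "outcome": outcome, "n_unweighted": est.n_unweighted,
                    "proportion": est.proportion,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "method": est.method,
                })
    return pd.DataFrame(rows)
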