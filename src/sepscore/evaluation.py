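"""Validation statistics for risk stratification scores.

Everything a score-validation table needs: 2x2 confusion counts,
sensitivity/specificity with exact Clopper-Pearson 95% intervals,
Mann-Whitney AUC with a DeLong variance-based interval, the paired DeLong
test for comparing two scores on the same patients, Woolf (logit-scale)
confidence intervals for odds ratios against 30-day mortality, and the
Pearson chi-square test for comparing proportions (no continuity
correction anywhere, matching the conventions of published early-warning
score validations).

The DeLong computation follows the fast midrank formulation: with m cases
and n controls, the AUC is the Mann-Whitney statistic (ties count 1/2) and
its variance is ``var(V10)/m + var(V01)/n`` where V10/V01 are the per-case
and per-control structural components.  For two paired scores the same
components give the covariance of the two AUCs, hence a z-test for the
difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "MetricWithCI",
    "ComparisonResult",
    "confusion",
    "sensitivity_specificity",
    "auc",
    "delong_test",
    "odds_ratio",
    "chi2_test",
    "evaluate_scores",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 screen-vs-outcome counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for f in ("tp", "fp", "fn", "tn"):
            if getattr(self, f) < 0:
                raise ValueError(f"count {f} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n: int

    def rounded(self, ndigits: int = 0):
        """The (estimate, low, high) triple rounded half-up."""
        def r(v):
            out = np.floor(v * 10**ndigits + 0.5) / 10**ndigits
            return int(out) if ndigits == 0 else float(out)
        return r(self.estimate), r(self.ci_low), r(self.ci_high)

    def as_percent(self):
        """The triple on the integer percent scale (as validation tables print)."""
        scaled = MetricWithCI(
            self.estimate * 100, self.ci_low * 100, self.ci_high * 100, self.method, self.n
        )
        return scaled.rounded(0)


@dataclass(frozen=True)
class ComparisonResult:
    auc_a: float
    auc_b: float
    difference: float
    p_value: float
    method: str = "DeLong paired"


def confusion(predicted: Sequence, outcome: Sequence) -> ConfusionTable:
    """2x2 counts from boolean screen-positive and outcome vectors."""
    p = np.asarray(predicted, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("predicted and outcome vectors differ in length")
    return ConfusionTable(
        tp=int(np.sum(p & y)),
        fp=int(np.sum(p & ~y)),
        fn=int(np.sum(~p & y)),
        tn=int(np.sum(~p & ~y)),
    )


def _proportion_ci(k: int, n: int, method_name: str) -> MetricWithCI:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return MetricWithCI(k / n, float(lo), float(hi), method_name, n)


def sensitivity_specificity(ct: ConfusionTable) -> tuple[MetricWithCI, MetricWithCI]:
    """Sensitivity and specificity with exact (Clopper-Pearson) 95% CIs."""
    if ct.tp + ct.fn == 0 or ct.tn + ct.fp == 0:
        raise ValueError("undefined metric: empty outcome margin")
    sens = _proportion_ci(ct.tp, ct.tp + ct.fn, "sensitivity (Clopper-Pearson)")
    spec = _proportion_ci(ct.tn, ct.tn + ct.fp, "specificity (Clopper-Pearson)")
    return sens, spec


# ---------------------------------------------------------------------------
# AUC / DeLong
# ---------------------------------------------------------------------------

def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components (V10 per case, V01 per control) and the AUC."""
    cases = scores[y]
    controls = scores[~y]
    m, n = cases.size, controls.size
    all_ranks = rankdata(scores)
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    # midrank identities: V10_i = (R_i - r_i)/n ; V01_j = 1 - (R_j - r_j)/m
    v10 = (all_ranks[y] - case_ranks) / n
    v01 = 1.0 - (all_ranks[~y] - control_ranks) / m
    a = v10.mean()
    return v10, v01, a


def _check_two_classes(y: np.ndarray):
    if y.all() or not y.any():
        raise ValueError("AUC needs both outcome classes present")


def auc(scores: Sequence, outcome: Sequence) -> MetricWithCI:
    """Mann-Whitney AUC (ties count 1/2) with a DeLong-variance 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and outcome vectors differ in length")
    _check_two_classes(y)
    v10, v01, a = _delong_components(s, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return MetricWithCI(
        float(a), float(max(a - half, 0.0)), float(min(a + half, 1.0)), "AUC (DeLong CI)", y.size
    )


def delong_test(
    scores_a: Sequence, scores_b: Sequence, outcome: Sequence, paired: bool = True
) -> ComparisonResult:
    """Two-sided DeLong test for the difference of two AUCs.

    ``paired=True`` (default) assumes both scores are computed on the same
    patients and uses the covariance of the structural components;
    ``paired=False`` treats them as independent.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if sa.shape != y.shape or sb.shape != y.shape:
        raise ValueError("paired DeLong test needs equal-length score and outcome vectors")
    _check_two_classes(y)
    v10a, v01a, aa = _delong_components(sa, y)
    v10b, v01b, ab = _delong_components(sb, y)
    m, n = v10a.size, v01a.size
    var_a = v10a.var(ddof=1) / m + v01a.var(ddof=1) / n
    var_b = v10b.var(ddof=1) / m + v01b.var(ddof=1) / n
    if paired:
        cov = (
            np.cov(v10a, v10b, ddof=1)[0, 1] / m + np.cov(v01a, v01b, ddof=1)[0, 1] / n
        )
    else:
        cov = 0.0
    var_diff = var_a + var_b - 2.0 * cov
    diff = aa - ab
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * norm.sf(abs(z)))
    return ComparisonResult(float(aa), float(ab), float(diff), p,
                            "DeLong paired" if paired else "DeLong unpaired")


# ---------------------------------------------------------------------------
# Odds ratios and chi-square
# ---------------------------------------------------------------------------

def odds_ratio(
    exposed_events: int,
    exposed_nonevents: int,
    unexposed_events: int,
    unexposed_nonevents: int,
    correction: float = 0.0,
) -> MetricWithCI:
    """Odds ratio with the Woolf logit-scale 95% interval.

    A zero cell is an error unless a continuity ``correction`` (e.g. 0.5)
    is supplied explicitly; none is applied by default.
    """
    a, b, c, d = exposed_events, exposed_nonevents, unexposed_events, unexposed_nonevents
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0 and correction == 0.0:
        raise ValueError("zero cell in 2x2 table; pass correction=0.5 to add a continuity correction")
    a, b, c, d = (v + correction for v in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.975)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    n = int(round(a + b + c + d - 4 * correction))
    return MetricWithCI(float(or_), float(lo), float(hi), "odds ratio (Woolf CI)", n)


def chi2_test(table: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Pearson chi-square p-value for a 2x2 table, 1 df, no continuity correction."""
    t = np.asarray(table, dtype=float).reshape(2, 2)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(rows, cols) / t.sum()
    stat = ((t - expected) ** 2 / expected).sum()
    return float(_chi2_dist.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Table-shaped reporting
# ---------------------------------------------------------------------------

def evaluate_scores(
    scored: pd.DataFrame,
    score_names: Sequence[str],
    outcome_col: str = "sepsis",
    reference: str | None = None,
    mortality_col: str | None = "mortality_30d",
    subgroups: Mapping[str, Sequence[bool]] | None = None,
) -> dict:
    """Validation report for a scored cohort.

    ``scored`` must carry, per score name, a ``<name>_total`` column (or
    ``<name>_level`` for triage) and a ``<name>_positive`` column.  The
    report holds, per group and score: the 2x2 counts against the outcome,
    sensitivity and specificity with CIs, AUC with CI, the paired DeLong
    comparison against ``reference``, and the odds ratio of screen
    positivity for 30-day mortality.  ``subgroups`` maps group names to
    boolean row filters (e.g. infected-only validation).
    """
    groups: dict[str, np.ndarray] = {"all": np.ones(len(scored), dtype=bool)}
    for name, mask in (subgroups or {}).items():
        groups[name] = np.asarray(mask, dtype=bool)

    def _numeric_score(df: pd.DataFrame, name: str) -> np.ndarray:
        if f"{name}_total" in df.columns:
            return df[f"{name}_total"].to_numpy(dtype=float)
        if f"{name}_level" in df.columns:  # triage: ordinal green..red
            order = {"green": 0, "yellow": 1, "orange": 2, "red": 3}
            return df[f"{name}_level"].map(order).to_numpy(dtype=float)
        raise KeyError(f"no total/level column for score {name!r}")

    report: dict = {}
    for gname, mask in groups.items():
        sub = scored.loc[mask]
        entry: dict = {"n": int(len(sub))}
        if len(sub) == 0 or sub[outcome_col].astype(bool).nunique() < 2:
            entry["empty"] = True
            report[gname] = entry
            continue
        y = sub[outcome_col].to_numpy(dtype=bool)
        ref_scores = _numeric_score(sub, reference) if reference else None
        for name in score_names:
            s = _numeric_score(sub, name)
            pos = sub[f"{name}_positive"].to_numpy(dtype=bool)
            ct = confusion(pos, y)
            sens, spec = sensitivity_specificity(ct)
            row = {
                "counts": {"tp": ct.tp, "fn": ct.fn, "fp": ct.fp, "tn": ct.tn},
                "sensitivity": sens,
                "specificity": spec,
                "auc": auc(s, y),
            }
            if ref_scores is not None:
                row["vs_reference"] = delong_test(s, ref_scores, y)
            if mortality_col and mortality_col in sub.columns:
                mort = sub[mortality_col].to_numpy(dtype=bool)
                cells = (
                    int(np.sum(pos & mort)),
                    int(np.sum(pos & ~mort)),
                    int(np.sum(~pos & mort)),
                    int(np.sum(~pos & ~mort)),
                )
                try:
                    row["mortality_or"] = odds_ratio(*cells)
                except ValueError:
                    warnings.warn(
                        f"zero cell in 30-day-mortality table for {name!r}; OR omitted",
                        stacklevel=2,
                    )
            entry[name] = row
        report[gname] = entry
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten an :func:`evaluate_scores` report into a tidy frame (percent scale)."""
    rows = []
    for group, entry in report.items():
        if entry.get("empty"):
            continue
        for score, cell in entry.items():
            if score in ("n", "empty"):
                continue
            sens: MetricWithCI = cell["sensitivity"]
            spec: MetricWithCI = cell["specificity"]
            a: MetricWithCI = cell["auc"]
            row = {
                "group": group,
                "score": score,
                **{k: v for k, v in cell["counts"].items()},
                "sensitivity_pct": sens.as_percent()[0],
                "sensitivity_ci": "{}-{}".format(*sens.as_percent()[1:]),
                "specificity_pct": spec.as_percent()[0],
                "specificity_ci": "{}-{}".format(*spec.as_percent()[1:]),
                "auc": round(a.estimate, 2),
                "auc_ci": "{:.2f}-{:.2f}".format(a.ci_low, a.ci_high),
            }
            if "vs_reference" in cell:
                row["p_vs_reference"] = round(cell["vs_reference"].p_value, 4)
            if "mortality_or" in cell:
                orr: MetricWithCI = cell["mortality_or"]
                row["mortality_or"] = round(orr.estimate, 1)
                row["mortality_or_ci"] = "{:.1f}-{:.1f}".format(orr.ci_low, orr.ci_high)
            rows.append(row)
    return pd.DataFrame(rows)
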