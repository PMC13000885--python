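"""Cohort-level agreement, paired comparisons, and diagnostic accuracy.

Everything here reduces to counts and exact binomial inference:

* ``exact_binomial_ci`` — Clopper–Pearson 95% interval (beta-quantile form),
  the interval behind every reported proportion;
* ``agreement_summary`` — share of participants whose estimated-GFR slope
  agrees with the measured-GFR slope (no large error) under either the
  ±3 mL/min/1.73 m²/yr or the ±5%/yr criterion;
* ``mcnemar_paired`` — paired comparison of two equations' agreement flags
  (exact binomial test on discordant pairs, chi-square for larger counts);
* ``diagnostic_metrics`` — sensitivity/specificity/PPV/NPV of progression
  detection against measured-GFR progression as the reference;
* ``p30`` — share of estimates within 30% of the paired measured GFR;
* ``median_bias`` / ``change_summary`` — median estimated-minus-measured
  differences and median (IQR) longitudinal changes.

No multiple-testing adjustment is applied anywhere, deliberately: the
equations under comparison are strongly dependent, sharing biomarkers and
participants. Report tables round half-up to 1 decimal; full-precision
values are always kept in the machine-readable output.
"""
from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .slopes import SlopeError

__all__ = [
    "ProportionCI", "ConfusionMatrix", "DiagnosticMetrics", "McNemarResult",
    "PairedDifference", "AccuracyReport", "exact_binomial_ci",
    "agreement_summary", "mcnemar_paired", "paired_difference",
    "diagnostic_metrics", "p30", "median_bias", "change_summary",
    "median_iqr", "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, as printed report tables use."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its exact (Clopper–Pearson) 95% CI."""

    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion

    def formatted(self) -> str:
        """``"73.1 (70.1 to 76.1)"`` — percent with CI, half-up to 1 dp."""
        return (f"{round_half_up(self.percent):.1f} "
                f"({round_half_up(100 * self.ci_low):.1f} to "
                f"{round_half_up(100 * self.ci_high):.1f})")


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Clopper–Pearson exact binomial confidence interval for k successes of n."""
    if n <= 0 or k < 0 or k > n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(numerator=int(k), denominator=int(n),
                        proportion=k / n, ci_low=low, ci_high=high)


def agreement_summary(errors: Sequence[SlopeError],
                      criterion: str = "abs3") -> ProportionCI:
    """Share of participants without a large slope error under one criterion.

    ``criterion`` is ``"abs3"`` (±3 mL/min/1.73 m²/yr, inclusive) or
    ``"pct5"`` (±5%/yr, exclusive).
    """
    if criterion not in ("abs3", "pct5"):
        raise ValueError(f"unknown criterion {criterion!r}")
    errors = list(errors)
    if not errors:
        raise ValueError("no slope errors supplied")
    flag = [e.large_abs if criterion == "abs3" else e.large_pct for e in errors]
    return exact_binomial_ci(sum(1 for f in flag if not f), len(flag))


@dataclass(frozen=True)
class McNemarResult:
    """Paired comparison of two binary flag vectors on discordant pairs."""

    b: int                 # a-only positives
    c: int                 # b-only positives
    p_exact: float
    p_chi2: float
    statistic: float       # chi-square statistic, no continuity correction
    p_value: float         # primary p: exact when b + c <= 25, else chi-square


def mcnemar_paired(flags_a: Sequence[bool], flags_b: Sequence[bool]) -> McNemarResult:
    """McNemar's test for paired binary outcomes.

    The exact two-sided binomial p-value on the discordant pairs is primary
    when there are ≤ 25 discordant pairs; the asymptotic chi-square test
    (no continuity correction) is primary otherwise. Both are reported.
    With zero discordant pairs p = 1 by convention.
    """
    a = np.asarray(flags_a, dtype=bool)
    b_arr = np.asarray(flags_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ValueError("flag vectors differ in length")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(b=0, c=0, p_exact=1.0, p_chi2=1.0,
                             statistic=0.0, p_value=1.0)
    p_exact = min(1.0, float(stats.binomtest(b, n_disc, 0.5).pvalue))
    statistic = (b - c) ** 2 / n_disc
    p_chi2 = float(stats.chi2.sf(statistic, df=1))
    primary = p_exact if n_disc <= 25 else p_chi2
    return McNemarResult(b=b, c=c, p_exact=p_exact, p_chi2=p_chi2,
                         statistic=statistic, p_value=primary)


@dataclass(frozen=True)
class PairedDifference:
    """Difference in agreement percentage between two paired flag vectors."""

    difference_pct: float
    ci_low_pct: float
    ci_high_pct: float
    method: str = "wald-paired"


def paired_difference(flags_a: Sequence[bool], flags_b: Sequence[bool],
                      level: float = 0.95) -> PairedDifference:
    """Percentage-point difference in agreement, b minus a, with a Wald CI.

    The CI uses the Wald paired-proportion form on the discordant counts.
    The method behind any externally reported interval for this quantity
    may differ; the point difference is the comparable statistic.
    """
    a = np.asarray(flags_a, dtype=bool)
    b_arr = np.asarray(flags_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ValueError("flag vectors differ in length")
    n = a.size
    if n == 0:
        raise ValueError("empty flag vectors")
    n10 = int(np.sum(a & ~b_arr))
    n01 = int(np.sum(~a & b_arr))
    d = (n01 - n10) / n
    se = np.sqrt(max(n01 + n10 - (n01 - n10) ** 2 / n, 0.0)) / n
    z = float(stats.norm.ppf(0.5 + level / 2))
    return PairedDifference(difference_pct=100.0 * d,
                            ci_low_pct=100.0 * (d - z * se),
                            ci_high_pct=100.0 * (d + z * se))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Progression detection counts: reference = measured GFR, index = equation."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_calls(cls, reference: Sequence[bool], index: Sequence[bool]) -> "ConfusionMatrix":
        r = np.asarray(reference, dtype=bool)
        i = np.asarray(index, dtype=bool)
        if r.shape != i.shape:
            raise ValueError("reference and index flags differ in length")
        return cls(tp=int(np.sum(r & i)), fn=int(np.sum(r & ~i)),
                   fp=int(np.sum(~r & i)), tn=int(np.sum(~r & ~i)))

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV with exact binomial CIs.

    A metric whose denominator is zero is undefined and reported as None.
    """

    sensitivity: Optional[ProportionCI]
    specificity: Optional[ProportionCI]
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Diagnostic accuracy of progression detection from a confusion matrix."""
    def _metric(k, n):
        return exact_binomial_ci(k, n) if n > 0 else None

    return DiagnosticMetrics(
        sensitivity=_metric(cm.tp, cm.tp + cm.fn),
        specificity=_metric(cm.tn, cm.fp + cm.tn),
        ppv=_metric(cm.tp, cm.tp + cm.fp),
        npv=_metric(cm.tn, cm.fn + cm.tn))


def p30(estimated, measured) -> ProportionCI:
    """Share of estimates within ±30% (inclusive) of the paired measured GFR."""
    est = np.asarray(estimated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.shape != meas.shape or est.size == 0:
        raise ValueError("estimated/measured arrays must be non-empty and aligned")
    if np.any(meas <= 0):
        raise ValueError("measured GFR must be positive")
    inside = np.abs(est - meas) / meas <= 0.30
    return exact_binomial_ci(int(inside.sum()), inside.size)


def median_iqr(x) -> tuple:
    """(median, 25th, 75th percentile) of a non-empty array."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return (float(np.median(x)), float(np.percentile(x, 25)),
            float(np.percentile(x, 75)))


def median_bias(estimated, measured) -> float:
    """Median of (estimated − measured) GFR at one timepoint."""
    est = np.asarray(estimated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.shape != meas.shape or est.size == 0:
        raise ValueError("estimated/measured arrays must be non-empty and aligned")
    return float(np.median(est - meas))


def change_summary(baseline, followup) -> dict:
    """Median (IQR) of within-person change, follow-up − baseline."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape or b.size == 0:
        raise ValueError("baseline/follow-up arrays must be non-empty and aligned")
    med, q1, q3 = median_iqr(f - b)
    return {"median": med, "q1": q1, "q3": q3, "n": int(b.size)}


@dataclass
class AccuracyReport:
    """Machine twin of the study's report tables.

    ``agreement``: per equation × criterion, n agree / n and CI.
    ``paired``: paired comparisons of each equation against the reference.
    ``diagnostics``: per-equation confusion counts with sens/spec/PPV/NPV.
    ``p30``: per equation × timepoint.
    ``bias``: per equation × timepoint × progression group, plus median
    (IQR) change rows for measured and estimated GFR.
    ``strata``: optional nested reports keyed by stratum (e.g. sex).
    """

    agreement: pd.DataFrame
    paired: pd.DataFrame
    diagnostics: pd.DataFrame
    p30: pd.DataFrame
    bias: pd.DataFrame
    n_evaluable: int
    strata: Optional[dict] = None
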