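"""Annualized GFR slopes and large-error classification.

Three slope estimators are provided, mirroring a monitoring study design
with baseline and 36-month visits plus interim measurements:

* ``two_point_slope`` — (follow-up − baseline) / elapsed years, the
  primary statistic;
* ``ols_slope`` — per-individual ordinary least squares over all visits;
* ``mixed_model_slopes`` — one linear mixed-effects model over the whole
  cohort (random intercept + random slope per participant, unstructured
  covariance, ML fit) whose per-participant slopes are the BLUPs
  (population slope + predicted random slope).

An estimated slope is compared with the measured-GFR slope by
``classify_error``: a discrepancy of ≥ ±3 mL/min/1.73 m²/yr (inclusive)
is a large absolute error; a discrepancy in percent-per-year terms
strictly beyond ±5%/yr is a large percent error. Percent slopes divide
the slope by the observed baseline value of the same source. Elapsed
time uses actual calendar dates with a 365.25-day year.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .equations import EquationId

__all__ = [
    "VisitRecord", "SlopeEstimate", "SlopeError", "MixedModelResult",
    "elapsed_years", "two_point_slope", "ols_slope", "mixed_model_slopes",
    "classify_error",
]

DAYS_PER_YEAR = 365.25
LARGE_ABS_THRESHOLD = 3.0   # mL/min/1.73 m²/yr, inclusive
LARGE_PCT_THRESHOLD = 5.0   # %/yr, exclusive

Source = Union[str, EquationId]  # "measured" or an equation id


@dataclass
class VisitRecord:
    """One dated visit: measured GFR and/or per-equation estimates."""

    participant_id: str
    visit_date: pd.Timestamp
    measured_gfr: Optional[float] = None
    estimates: Dict[EquationId, float] = field(default_factory=dict)

    def __post_init__(self):
        self.visit_date = pd.Timestamp(self.visit_date)
        if self.measured_gfr is None and not self.estimates:
            raise ValueError("visit carries neither measured nor estimated GFR")

    def value(self, source: Source) -> Optional[float]:
        if source == "measured":
            return self.measured_gfr
        return self.estimates.get(EquationId(source))


@dataclass(frozen=True)
class SlopeEstimate:
    """Annualized rate of change of one GFR source for one participant."""

    participant_id: str
    source: Source
    slope: float                    # mL/min/1.73 m²/yr
    percent_slope: float            # %/yr relative to observed baseline
    method: str                     # two_point | ols | mixed_model
    baseline_value: float
    n_visits: int = 2


@dataclass(frozen=True)
class SlopeError:
    """Estimated-minus-measured slope discrepancy and its large-error flags."""

    participant_id: str
    equation: EquationId
    error: float
    percent_error: float
    large_abs: bool
    large_pct: bool


@dataclass
class MixedModelResult:
    """Cohort mixed-model fit: per-participant BLUP slopes plus fit metadata."""

    slopes: Dict[str, SlopeEstimate]
    population_slope: float
    population_slope_se: float
    converged: bool
    used_ols_fallback: bool = False


def elapsed_years(date_a, date_b) -> float:
    """Calendar time from ``date_a`` to ``date_b`` in 365.25-day years."""
    a, b = pd.Timestamp(date_a), pd.Timestamp(date_b)
    if b < a:
        raise ValueError(f"dates out of order: {a.date()} > {b.date()}")
    return (b - a) / pd.Timedelta(days=1) / DAYS_PER_YEAR


def _require_value(visit: VisitRecord, source: Source) -> float:
    v = visit.value(source)
    if v is None or not np.isfinite(v):
        raise ValueError(
            f"visit {visit.participant_id}@{visit.visit_date.date()} lacks {source}")
    return float(v)


def two_point_slope(baseline: VisitRecord, followup: VisitRecord,
                    source: Source = "measured") -> SlopeEstimate:
    """Slope from two visits: (follow-up − baseline) / years between them."""
    if baseline.participant_id != followup.participant_id:
        raise ValueError("visits belong to different participants")
    dt = elapsed_years(baseline.visit_date, followup.visit_date)
    if dt == 0:
        raise ValueError("baseline and follow-up visits are on the same date")
    b = _require_value(baseline, source)
    f = _require_value(followup, source)
    slope = (f - b) / dt
    return SlopeEstimate(participant_id=baseline.participant_id, source=source,
                         slope=slope, percent_slope=100.0 * slope / b,
                         method="two_point", baseline_value=b, n_visits=2)


def ols_slope(visits: Sequence[VisitRecord], source: Source = "measured") -> SlopeEstimate:
    """Per-individual OLS slope of the source value on years since baseline."""
    usable = [v for v in visits if v.value(source) is not None]
    if len(usable) < 2:
        raise ValueError("need at least two visits with the requested value")
    usable.sort(key=lambda v: v.visit_date)
    pid = usable[0].participant_id
    if any(v.participant_id != pid for v in usable):
        raise ValueError("visits belong to different participants")
    t0 = usable[0].visit_date
    t = np.array([elapsed_years(t0, v.visit_date) for v in usable])
    if np.ptp(t) == 0:
        raise ValueError("all visits share one date; slope undefined")
    y = np.array([float(v.value(source)) for v in usable])
    slope = np.polyfit(t, y, 1)[0]
    b = y[0]
    return SlopeEstimate(participant_id=pid, source=source, slope=float(slope),
                         percent_slope=100.0 * float(slope) / b,
                         method="ols", baseline_value=b, n_visits=len(usable))


def _ols_fallback(groups: Dict[str, List[VisitRecord]], source: Source,
                  pooled_slope: float) -> Dict[str, SlopeEstimate]:
    out = {}
    for pid, visits in groups.items():
        try:
            est = ols_slope(visits, source)
        except ValueError:
            b = _require_value(visits[0], source)
            est = SlopeEstimate(pid, source, pooled_slope,
                                100.0 * pooled_slope / b, "mixed_model", b,
                                n_visits=len(visits))
        out[pid] = est
    return out


def mixed_model_slopes(visits: Iterable[VisitRecord],
                       source: Source = "measured") -> MixedModelResult:
    """Per-participant slopes from one cohort-level mixed-effects model.

    Fits value ~ years with a random intercept and random slope per
    participant (unstructured 2×2 covariance) by maximum likelihood.
    Each participant's slope is the population slope plus their predicted
    random slope; participants with a single visit receive essentially the
    population slope. If the optimizer fails to converge, per-individual
    OLS slopes are returned instead with ``used_ols_fallback`` set.
    """
    groups: Dict[str, List[VisitRecord]] = {}
    for v in visits:
        if v.value(source) is not None:
            groups.setdefault(v.participant_id, []).append(v)
    if len(groups) < 2:
        raise ValueError("mixed model needs at least two participants")
    rows = []
    for pid, vs in groups.items():
        vs.sort(key=lambda v: v.visit_date)
        t0 = vs[0].visit_date
        for v in vs:
            rows.append((pid, elapsed_years(t0, v.visit_date),
                         float(v.value(source))))
    df = pd.DataFrame(rows, columns=["pid", "years", "value"])

    # Degenerate noise-free limit: if every trajectory is exactly linear the
    # residual variance is zero, the likelihood is unbounded and optimizers
    # return garbage; the BLUPs then coincide with per-individual OLS.
    ss_resid, dof = 0.0, 0
    for _, sub in df.groupby("pid"):
        if len(sub) > 2 and sub["years"].nunique() > 1:
            r = np.polyfit(sub["years"], sub["value"], 1, full=True)[1]
            ss_resid += float(r[0]) if r.size else 0.0
            dof += len(sub) - 2
    if dof > 0 and ss_resid / dof < 1e-10 * max(float(df["value"].var()), 1.0):
        pooled = float(np.polyfit(df["years"], df["value"], 1)[0])
        slopes = _ols_fallback(groups, source, pooled)
        return MixedModelResult(slopes=slopes, population_slope=pooled,
                                population_slope_se=0.0, converged=True,
                                used_ols_fallback=True)

    exog = sm.add_constant(df[["years"]])
    model = MixedLM(df["value"], exog, groups=df["pid"],
                    exog_re=exog)  # random intercept + slope, unstructured
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res, converged = None, False
        for method in (["lbfgs", "bfgs", "cg"], "powell"):
            try:
                res = model.fit(reml=False, method=method, maxiter=2000)
                converged = bool(res.converged)
            except Exception:
                res, converged = None, False
            if converged:
                break

    if res is None or not converged:
        pooled = float(np.polyfit(df["years"], df["value"], 1)[0])
        slopes = _ols_fallback(groups, source, pooled)
        return MixedModelResult(slopes=slopes, population_slope=pooled,
                                population_slope_se=float("nan"),
                                converged=False, used_ols_fallback=True)

    pop_slope = float(res.fe_params["years"])
    pop_se = float(res.bse_fe["years"])
    re = res.random_effects
    slopes = {}
    for pid, vs in groups.items():
        b = float(vs[0].value(source))
        rand = re.get(pid)
        rand_slope = float(rand.get("years", 0.0)) if rand is not None else 0.0
        s = pop_slope + rand_slope
        slopes[pid] = SlopeEstimate(pid, source, s, 100.0 * s / b,
                                    "mixed_model", b, n_visits=len(vs))
    return MixedModelResult(slopes=slopes, population_slope=pop_slope,
                            population_slope_se=pop_se, converged=True)


def classify_error(est: SlopeEstimate, meas: SlopeEstimate,
                   abs_threshold: float = LARGE_ABS_THRESHOLD,
                   pct_threshold: float = LARGE_PCT_THRESHOLD) -> SlopeError:
    """Estimated − measured slope discrepancy with both large-error flags."""
    if est.participant_id != meas.participant_id:
        raise ValueError("slope estimates belong to different participants")
    if meas.source != "measured":
        raise ValueError("reference slope must come from measured GFR")
    if est.source == "measured":
        raise ValueError("index slope must come from an estimating equation")
    error = est.slope - meas.slope
    pct_error = est.percent_slope - meas.percent_slope
    return SlopeError(
        participant_id=est.participant_id, equation=EquationId(est.source),
        error=error, percent_error=pct_error,
        large_abs=abs(error) >= abs_threshold,
        large_pct=abs(pct_error) > pct_threshold)
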