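"""End-to-end analysis pipeline: cohort I/O, configuration, orchestration.

``read_cohort`` validates a long-format per-visit CSV (one row per
participant-visit: id, ISO date, demographics, serum creatinine in
µmol/L, cystatin C in mg/L, optional measured GFR). ``run_analysis``
estimates GFR with every configured equation at every visit, selects the
evaluable (complete-case) cohort, computes slopes and large-error flags,
and assembles the agreement / paired-comparison / progression-accuracy /
P30 / bias report. ``write_report`` renders the report to CSV and JSON
deterministically.

The headline analysis uses the intersection cohort: participants with
measured GFR and every equation's estimate available at both baseline
and follow-up, so all tables share one denominator. Counts at each
filtering step are recorded for accountability.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accuracy as acc
from .equations import EquationId, estimate_gfr_vector
from .slopes import (SlopeError, VisitRecord, classify_error,
                     mixed_model_slopes, ols_slope, two_point_slope)
from .staging import progressed_vector

__all__ = ["RunConfig", "CohortValidationError", "read_cohort",
           "add_estimates", "run_analysis", "write_report"]

logger = logging.getLogger("gfrmon")

REQUIRED_COLUMNS = ("participant_id", "visit_date", "age_at_baseline", "sex",
                    "serum_creatinine", "serum_cystatin_c")
ALL_EQUATIONS = tuple(EquationId)


class CohortValidationError(ValueError):
    """Raised when the cohort table fails validation; carries row numbers."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__("cohort validation failed:\n  " + "\n  ".join(problems))


@dataclass
class RunConfig:
    """Analysis configuration.

    The reference equation for paired comparisons defaults to the 2009
    CKD-EPI creatinine equation, the one recommended for routine clinical
    use in England. ``slope_method`` selects how slopes are computed:
    ``two_point`` (primary analysis), ``ols`` (per-individual regression
    over all estimated-GFR visits, measured slope still two-point), or
    ``mixed_model`` (per-individual OLS for estimates, one cohort-level
    mixed-effects model for measured GFR).
    """

    equations: Sequence[EquationId] = ALL_EQUATIONS
    abs_threshold: float = 3.0          # mL/min/1.73 m²/yr, inclusive
    pct_threshold: float = 5.0          # %/yr, exclusive
    reference_equation: EquationId = EquationId.CKDEPI_CR_2009
    slope_method: str = "two_point"
    min_followup_years: float = 2.0     # a visit this late counts as follow-up
    stratify: Optional[Sequence[str]] = None
    apply_race_term: bool = False
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        self.equations = tuple(EquationId(e) for e in self.equations)
        self.reference_equation = EquationId(self.reference_equation)
        if self.abs_threshold <= 0 or self.pct_threshold <= 0:
            raise ValueError("large-error thresholds must be positive")
        if self.slope_method not in ("two_point", "ols", "mixed_model"):
            raise ValueError(f"unknown slope method {self.slope_method!r}")
        if self.reference_equation not in self.equations:
            raise ValueError("reference equation must be among the evaluated ones")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = {k: (list(map(str, v)) if isinstance(v, (tuple, list)) else str(v))
                   for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def read_cohort(path, creatinine_unit: str = "umol/L") -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    A ``serum_creatinine_mgdl`` column is accepted in place of
    ``serum_creatinine`` and converted to µmol/L on read (logged), as is
    ``creatinine_unit="mg/dL"`` for a plain ``serum_creatinine`` column.
    Rows failing validation are reported with their line numbers; unit or
    sign problems are errors, not warnings.
    """
    df = pd.read_csv(path)
    if "serum_creatinine_mgdl" in df.columns and "serum_creatinine" not in df.columns:
        logger.info("converting serum_creatinine_mgdl column to µmol/L")
        df["serum_creatinine"] = df.pop("serum_creatinine_mgdl") * 88.4
    elif creatinine_unit == "mg/dL":
        logger.info("creatinine declared in mg/dL; converting to µmol/L")
        df["serum_creatinine"] = df["serum_creatinine"] * 88.4
    elif creatinine_unit != "umol/L":
        raise CohortValidationError([f"unknown creatinine unit {creatinine_unit!r}"])

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing required columns: {missing}"])
    if "measured_gfr" not in df.columns:
        df["measured_gfr"] = np.nan

    problems: List[str] = []
    dates = pd.to_datetime(df["visit_date"], format="ISO8601", errors="coerce")
    for i in np.flatnonzero(dates.isna()):
        problems.append(f"row {i + 2}: unparseable visit_date {df['visit_date'].iloc[i]!r}")
    df["visit_date"] = dates

    for col in ("serum_creatinine", "serum_cystatin_c"):
        bad = df[col].notna() & (df[col] <= 0)
        for i in np.flatnonzero(bad):
            problems.append(f"row {i + 2}: non-positive {col} {df[col].iloc[i]!r}")
    bad = df["measured_gfr"].notna() & (df["measured_gfr"] <= 0)
    for i in np.flatnonzero(bad):
        problems.append(f"row {i + 2}: non-positive measured_gfr {df['measured_gfr'].iloc[i]!r}")
    bad = ~df["sex"].isin(["male", "female"])
    for i in np.flatnonzero(bad):
        problems.append(f"row {i + 2}: sex must be male/female, got {df['sex'].iloc[i]!r}")
    bad = df["age_at_baseline"] < 18
    for i in np.flatnonzero(bad):
        problems.append(f"row {i + 2}: age_at_baseline below 18")
    dup = df.duplicated(subset=["participant_id", "visit_date"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["participant_id", "visit_date"]].drop_duplicates()
        for _, r in pairs.iterrows():
            problems.append(f"duplicate visit: {r['participant_id']} on {r['visit_date']}")
    if problems:
        raise CohortValidationError(problems)
    return df.sort_values(["participant_id", "visit_date"]).reset_index(drop=True)


def add_estimates(df: pd.DataFrame, config: Optional[RunConfig] = None) -> pd.DataFrame:
    """Append one eGFR column per configured equation (``egfr_<ID>``)."""
    config = config or RunConfig()
    out = df.copy()
    black = out["black_ethnicity"] if "black_ethnicity" in out.columns else None
    for eq in config.equations:
        out[f"egfr_{eq.value}"] = estimate_gfr_vector(
            eq, out["serum_creatinine"], out["serum_cystatin_c"],
            out["age_at_baseline"], out["sex"], black,
            config.apply_race_term)
    return out


def _visit_records(df: pd.DataFrame, equations) -> Dict[str, List[VisitRecord]]:
    groups: Dict[str, List[VisitRecord]] = {}
    for row in df.itertuples(index=False):
        mg = getattr(row, "measured_gfr")
        estimates = {}
        for eq in equations:
            v = getattr(row, f"egfr_{eq.value}")
            if np.isfinite(v):
                estimates[eq] = float(v)
        if not estimates and not np.isfinite(mg):
            continue
        rec = VisitRecord(
            participant_id=row.participant_id, visit_date=row.visit_date,
            measured_gfr=float(mg) if np.isfinite(mg) else None,
            estimates=estimates)
        groups.setdefault(row.participant_id, []).append(rec)
    for visits in groups.values():
        visits.sort(key=lambda v: v.visit_date)
    return groups


def _estimated_slope(visits, eq, method):
    if method == "two_point":
        first = next(v for v in visits if v.value(eq) is not None)
        last = next(v for v in reversed(visits) if v.value(eq) is not None)
        return two_point_slope(first, last, eq)
    return ols_slope(visits, eq)  # ols and mixed_model both use per-person OLS


def run_analysis(df: pd.DataFrame, config: Optional[RunConfig] = None) -> acc.AccuracyReport:
    """Run the full monitoring analysis on a validated cohort table."""
    config = config or RunConfig()
    if not any(c.startswith("egfr_") for c in df.columns):
        df = add_estimates(df, config)

    counts = {"rows": int(len(df)),
              "participants": int(df["participant_id"].nunique())}
    groups = _visit_records(df, config.equations)

    # evaluable (intersection) cohort: measured GFR and every equation's
    # estimate at baseline and at a follow-up >= min_followup_years later
    evaluable: Dict[str, dict] = {}
    n_base, n_follow = 0, 0
    for pid, visits in groups.items():
        base = visits[0]
        follow = visits[-1]
        has_base = base.measured_gfr is not None and all(
            base.value(eq) is not None for eq in config.equations)
        if has_base:
            n_base += 1
        span = (follow.visit_date - base.visit_date).days / 365.25
        has_follow = (follow.measured_gfr is not None
                      and all(follow.value(eq) is not None for eq in config.equations)
                      and span >= config.min_followup_years)
        if has_follow:
            n_follow += 1
        if has_base and has_follow:
            evaluable[pid] = {"visits": visits, "baseline": base, "followup": follow}
    counts["with_complete_baseline"] = n_base
    counts["with_complete_followup"] = n_follow
    counts["evaluable"] = len(evaluable)
    if len(evaluable) < 2:
        raise ValueError("fewer than two evaluable participants")
    pids = sorted(evaluable)

    # measured slopes
    if config.slope_method == "mixed_model":
        all_meas_visits = [v for pid in pids for v in evaluable[pid]["visits"]
                           if v.measured_gfr is not None]
        mm = mixed_model_slopes(all_meas_visits, "measured")
        meas_slopes = {pid: mm.slopes[pid] for pid in pids}
    else:
        meas_slopes = {pid: two_point_slope(evaluable[pid]["baseline"],
                                            evaluable[pid]["followup"], "measured")
                       for pid in pids}

    # per-equation slope errors and agreement flags
    errors: Dict[EquationId, List[SlopeError]] = {}
    for eq in config.equations:
        errs = []
        for pid in pids:
            est = _estimated_slope(evaluable[pid]["visits"], eq, config.slope_method)
            errs.append(classify_error(est, meas_slopes[pid],
                                       abs_threshold=config.abs_threshold,
                                       pct_threshold=config.pct_threshold))
        errors[eq] = errs

    agreement_rows = []
    for eq in config.equations:
        for crit in ("abs3", "pct5"):
            ci = acc.agreement_summary(errors[eq], crit)
            agreement_rows.append({
                "equation": eq.value, "criterion": crit,
                "n_agree": ci.numerator, "n": ci.denominator,
                "percent": ci.percent, "ci_low_pct": 100 * ci.ci_low,
                "ci_high_pct": 100 * ci.ci_high, "formatted": ci.formatted()})
    agreement = pd.DataFrame(agreement_rows)

    # paired comparisons against the reference equation
    ref = config.reference_equation
    paired_rows = []
    for eq in config.equations:
        if eq == ref:
            continue
        for crit in ("abs3", "pct5"):
            attr = "large_abs" if crit == "abs3" else "large_pct"
            ok_ref = [not getattr(e, attr) for e in errors[ref]]
            ok_eq = [not getattr(e, attr) for e in errors[eq]]
            mc = acc.mcnemar_paired(ok_ref, ok_eq)
            pdiff = acc.paired_difference(ok_ref, ok_eq)
            paired_rows.append({
                "equation": eq.value, "reference": ref.value, "criterion": crit,
                "difference_pct": pdiff.difference_pct,
                "ci_low_pct": pdiff.ci_low_pct, "ci_high_pct": pdiff.ci_high_pct,
                "p_value": mc.p_value, "p_exact": mc.p_exact,
                "p_chi2": mc.p_chi2, "discordant_b": mc.b, "discordant_c": mc.c})
    paired = pd.DataFrame(paired_rows)

    # progression accuracy (two-point baseline/follow-up values)
    base_meas = np.array([evaluable[p]["baseline"].measured_gfr for p in pids])
    fol_meas = np.array([evaluable[p]["followup"].measured_gfr for p in pids])
    ref_prog = progressed_vector(base_meas, fol_meas)
    diag_rows = []
    for eq in config.equations:
        be = np.array([evaluable[p]["baseline"].value(eq) for p in pids])
        fe = np.array([evaluable[p]["followup"].value(eq) for p in pids])
        cm = acc.ConfusionMatrix.from_calls(ref_prog, progressed_vector(be, fe))
        dm = acc.diagnostic_metrics(cm)
        row = {"equation": eq.value, "tp": cm.tp, "fn": cm.fn,
               "fp": cm.fp, "tn": cm.tn}
        for name, m in (("sensitivity", dm.sensitivity), ("specificity", dm.specificity),
                        ("ppv", dm.ppv), ("npv", dm.npv)):
            row[f"{name}_pct"] = m.percent if m else np.nan
            row[f"{name}_ci_low_pct"] = 100 * m.ci_low if m else np.nan
            row[f"{name}_ci_high_pct"] = 100 * m.ci_high if m else np.nan
        diag_rows.append(row)
    diagnostics = pd.DataFrame(diag_rows)

    # P30 and bias by timepoint / progression group
    p30_rows, bias_rows = [], []
    group_masks = {"all": np.ones(len(pids), bool),
                   "progression": ref_prog, "no_progression": ~ref_prog}
    ch = acc.change_summary(base_meas, fol_meas)
    for g, mask in group_masks.items():
        if mask.any():
            c = acc.change_summary(base_meas[mask], fol_meas[mask])
            bias_rows.append({"equation": "measured", "group": g, "n": c["n"],
                              "bias_baseline": 0.0, "bias_followup": 0.0,
                              "change_median": c["median"], "change_q1": c["q1"],
                              "change_q3": c["q3"]})
    for eq in config.equations:
        be = np.array([evaluable[p]["baseline"].value(eq) for p in pids])
        fe = np.array([evaluable[p]["followup"].value(eq) for p in pids])
        for tp_name, est, meas in (("baseline", be, base_meas),
                                   ("followup", fe, fol_meas)):
            ci = acc.p30(est, meas)
            p30_rows.append({"equation": eq.value, "timepoint": tp_name,
                             "n_within": ci.numerator, "n": ci.denominator,
                             "percent": ci.percent, "ci_low_pct": 100 * ci.ci_low,
                             "ci_high_pct": 100 * ci.ci_high})
        for g, mask in group_masks.items():
            if not mask.any():
                logger.warning("empty progression group %s omitted from bias table", g)
                continue
            c = acc.change_summary(be[mask], fe[mask])
            bias_rows.append({
                "equation": eq.value, "group": g, "n": c["n"],
                "bias_baseline": acc.median_bias(be[mask], base_meas[mask]),
                "bias_followup": acc.median_bias(fe[mask], fol_meas[mask]),
                "change_median": c["median"], "change_q1": c["q1"],
                "change_q3": c["q3"]})
    p30_table = pd.DataFrame(p30_rows)
    bias = pd.DataFrame(bias_rows)

    strata = None
    if config.stratify:
        strata = {}
        sub_cfg = dataclasses.replace(config, stratify=None)
        for key in config.stratify:
            for value, sub in df.groupby(key):
                sub_ids = set(sub["participant_id"])
                if sum(1 for p in pids if p in sub_ids) < 2:
                    continue
                strata[f"{key}={value}"] = run_analysis(sub, sub_cfg)

    logger.info("evaluable cohort: %d of %d participants (%s)",
                counts["evaluable"], counts["participants"],
                " -> ".join(f"{k}={v}" for k, v in counts.items()))
    report = acc.AccuracyReport(agreement=agreement, paired=paired,
                                diagnostics=diagnostics, p30=p30_table,
                                bias=bias, n_evaluable=len(pids), strata=strata)
    report.filter_counts = counts  # accountability trail
    report.median_change_measured = ch
    return report


def write_report(report: acc.AccuracyReport, outdir, config: Optional[RunConfig] = None) -> None:
    """Write the report tables (CSV) plus a machine-readable JSON and run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {"agreement": report.agreement, "paired_comparisons": report.paired,
              "progression_diagnostics": report.diagnostics,
              "p30": report.p30, "bias": report.bias}
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
    blob = {name: table.to_dict(orient="records") for name, table in tables.items()}
    blob["n_evaluable"] = report.n_evaluable
    if report.strata:
        blob["strata"] = {
            k: {name: getattr(r, attr).to_dict(orient="records")
                for name, attr in (("agreement", "agreement"),
                                   ("progression_diagnostics", "diagnostics"))}
            for k, r in report.strata.items()}
    with open(outdir / "report.json", "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True, allow_nan=True)
    log = {"filter_counts": getattr(report, "filter_counts", None)}
    if config is not None:
        log.update(seed=config.seed, config_digest=config.digest(),
                   slope_method=config.slope_method,
                   equations=[e.value for e in config.equations])
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
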