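"""Seeded simulator of longitudinal moderate-CKD monitoring cohorts.

Emulates a three-year monitoring design: adults recruited with moderate
CKD, iohexol-style measured GFR at baseline and 36 months (with extra
measurements at 12 and 24 months in subsets), serum creatinine and
cystatin C every 6 months, and attrition from the recruited to the
evaluable cohort. Each participant has a latent linear true-GFR
trajectory; a progressor/non-progressor mixture on the true slope
produces a realistic share of participants crossing the ≥25% +
category-drop progression rule. Observables are the truth under
multiplicative log-normal measurement noise; biomarker concentrations
are obtained by inverting a chosen generating equation at the (possibly
biased/drifting) GFR the biomarker "sees", so that in the noise-free
limit the generating equation reproduces measured GFR exactly.

The latent truth (true slopes, progressor labels) is retained alongside
the observed visit table so parameter-recovery tests can compare the
pipeline's output against the generating process.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .equations import EquationId, estimate_gfr_vector

__all__ = ["SimulationConfig", "SyntheticCohort", "invert_equation",
           "invert_equation_vector", "simulate"]

VISIT_MONTHS = (0, 6, 12, 18, 24, 30, 36)
# true trajectories are floored just above the inversion clip so the
# noise-free limit stays exact even for participants reaching the floor
GFR_FLOOR = 6.0

# companion single-cystatin equation used when inverting a two-marker form
_CYS_COMPANION = {
    EquationId.CKDEPI_CRCYS_2012: EquationId.CKDEPI_CYS_2012,
    EquationId.CKDEPI_CRCYS_2021: EquationId.CKDEPI_CYS_2012,
    EquationId.EKFC_CRCYS: EquationId.EKFC_CYS,
}

_CYSTATIN_ONLY = frozenset({EquationId.CKDEPI_CYS_2012, EquationId.EKFC_CYS})


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic monitoring cohort.

    Demographic and baseline-GFR targets (age median 67.1, IQR 58.1–73.6;
    baseline measured GFR median 48.1, IQR 40.2–57.2; 57.7% male; 15.9%
    progressors; attrition 1229 recruited → 875 evaluable; extra measured
    GFR in 215 and 188 of 875 at 12 and 24 months) describe the cohort
    being emulated. Slope-mixture means/SDs and the 5% measurement CVs are
    implementer-chosen defaults — plausible for iohexol clearance and
    well-standardised biomarker assays — selected so progressors lose a
    median of roughly 16 mL/min/1.73 m² over three years against roughly
    3 in non-progressors; they are assumptions, not estimates from data.
    """

    n_participants: int = 875          # target evaluable cohort size
    attrition: float = 1.0 - 875.0 / 1229.0
    male_fraction: float = 0.577
    age_median: float = 67.1
    age_q1: float = 58.1
    age_q3: float = 73.6
    age_bounds: tuple = (18.0, 95.0)
    gfr_median: float = 48.1
    gfr_q1: float = 40.2
    gfr_q3: float = 57.2
    progressor_fraction: float = 0.159
    progressor_slope_mean: float = -5.5     # mL/min/1.73 m²/yr
    progressor_slope_sd: float = 1.5
    nonprogressor_slope_mean: float = -1.0
    nonprogressor_slope_sd: float = 1.5
    mgfr_cv: float = 0.05              # log-normal sigma of measured GFR
    biomarker_cv: float = 0.05         # visit-level log-normal sigma per biomarker
    person_bias_sd: float = 0.10       # person-level multiplicative biomarker bias
    egfr_drift_rate: float = 0.0       # yr⁻¹; >0 blunts the biomarker-implied decline
    creatinine_generator: EquationId = EquationId.CKDEPI_CR_2009
    cystatin_generator: EquationId = EquationId.CKDEPI_CYS_2012
    extra_mgfr_12m: int = 215          # at the reference n of 875; scaled with n
    extra_mgfr_24m: int = 188
    reference_n: int = 875
    recruitment_start: str = "2014-04-01"
    recruitment_days: int = 365
    visit_jitter_days: int = 14
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("need at least two participants")
        for name in ("attrition", "male_fraction", "progressor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        for name in ("mgfr_cv", "biomarker_cv", "person_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_recruited(self) -> int:
        return int(round(self.n_participants / (1.0 - self.attrition)))


def _marker_for(eq: EquationId) -> str:
    return "cystatin" if eq in _CYSTATIN_ONLY else "creatinine"


def invert_equation_vector(eq: EquationId, targets, ages, sexes) -> np.ndarray:
    """Biomarker concentrations at which ``eq`` returns each target GFR.

    Vectorized monotone bisection (60 halvings on the log-concentration
    scale, resolving well below 1e-8 relative). For two-marker equations
    the cystatin concentration is fixed at its own single-marker inversion
    and creatinine is solved. Returns creatinine in µmol/L or cystatin C
    in mg/L depending on which marker the equation is solved for.
    """
    eq = EquationId(eq)
    targets = np.asarray(targets, dtype=float)
    ages = np.broadcast_to(np.asarray(ages, dtype=float), targets.shape)
    sexes = np.broadcast_to(np.asarray(sexes), targets.shape)
    if np.any(targets <= 5.0) or np.any(targets >= 150.0):
        raise ValueError("target GFR must lie in (5, 150) mL/min/1.73 m²")

    scys_fixed = np.full(targets.shape, np.nan)
    if eq in _CYS_COMPANION:
        scys_fixed = invert_equation_vector(_CYS_COMPANION[eq], targets, ages, sexes)

    marker = _marker_for(eq)
    lo_conc, hi_conc = (0.01, 60.0) if marker == "cystatin" else (0.5, 20000.0)

    def f(conc):
        if marker == "cystatin":
            return estimate_gfr_vector(eq, np.full_like(conc, np.nan), conc,
                                       ages, sexes)
        return estimate_gfr_vector(eq, conc, scys_fixed, ages, sexes)

    lo = np.full(targets.shape, np.log(lo_conc))
    hi = np.full(targets.shape, np.log(hi_conc))
    f_lo, f_hi = f(np.exp(lo)), f(np.exp(hi))
    if np.any(f_lo < targets) or np.any(f_hi > targets):
        raise ValueError("target GFR outside the equation's achievable range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_high = f(np.exp(mid)) > targets  # GFR above target -> conc too low
        lo = np.where(too_high, mid, lo)
        hi = np.where(too_high, hi, mid)
    return np.exp(0.5 * (lo + hi))


def invert_equation(eq: EquationId, target_gfr: float, age: float,
                    sex: str) -> float:
    """Scalar convenience wrapper around :func:`invert_equation_vector`."""
    out = invert_equation_vector(eq, np.array([float(target_gfr)]),
                                 np.array([float(age)]), np.array([sex]))
    return float(out[0])


def _two_piece_quantile(p, mu, s1, s2):
    from scipy.stats import norm

    w = s1 / (s1 + s2)  # probability mass below the mode
    p = np.atleast_1d(np.asarray(p, dtype=float))
    lo = mu + s1 * norm.ppf(np.clip(p / (2 * w), 1e-12, 1 - 1e-12))
    hi = mu + s2 * norm.ppf(np.clip((p - w) / (2 * (1 - w)) + 0.5,
                                    1e-12, 1 - 1e-12))
    return np.where(p < w, lo, hi)


def _two_piece_normal_params(median, q1, q3):
    """Fit mode and side SDs of a two-piece normal to a median and IQR.

    Side SDs are bounded below so the fit stays non-degenerate (the exact
    quantile-matching root can collapse one side to zero); the residual on
    the three target quantiles is a fraction of a year.
    """
    def residual(params):
        mu, s1, s2 = params
        q = _two_piece_quantile([0.25, 0.5, 0.75], mu, s1, s2)
        return [q[0] - q1, q[1] - median, q[2] - q3]

    half_iqr = (q3 - q1) / 2
    sol = optimize.least_squares(
        residual, [median, 1.5 * half_iqr, half_iqr],
        bounds=([q1 - 3 * half_iqr, 0.3 * half_iqr, 0.3 * half_iqr],
                [q3 + 3 * half_iqr, 5 * half_iqr, 5 * half_iqr]))
    mu, s1, s2 = sol.x
    return float(mu), float(s1), float(s2)


def _draw_two_piece(rng, n, median, q1, q3, bounds):
    mu, s1, s2 = _two_piece_normal_params(median, q1, q3)
    w = s1 / (s1 + s2)
    out = np.empty(n)
    for i in range(n):
        while True:
            if rng.random() < w:
                x = mu - abs(rng.normal(0.0, s1))
            else:
                x = mu + abs(rng.normal(0.0, s2))
            if bounds[0] <= x <= bounds[1]:
                out[i] = x
                break
    return out


@dataclass
class SyntheticCohort:
    """A simulated cohort: observed visit table plus the latent truth."""

    participants: pd.DataFrame   # one row per recruited participant (truth)
    visits: pd.DataFrame         # long-format observed visits
    config: SimulationConfig

    @property
    def evaluable_ids(self) -> pd.Index:
        return pd.Index(
            self.participants.loc[self.participants["evaluable"], "participant_id"])

    def cohort_table(self) -> pd.DataFrame:
        """The long-format cohort table the analysis pipeline consumes."""
        cols = ["participant_id", "visit_date", "age_at_baseline", "sex",
                "serum_creatinine", "serum_cystatin_c", "measured_gfr"]
        return self.visits[cols].copy()

    def write(self, cohort_path, truth_path: Optional[str] = None) -> None:
        """Write the cohort CSV and, optionally, the ground-truth sidecar."""
        table = self.cohort_table()
        table = table.assign(visit_date=table["visit_date"].dt.strftime("%Y-%m-%d"))
        table.to_csv(cohort_path, index=False)
        if truth_path is not None:
            self.participants.to_csv(truth_path, index=False)


def simulate(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    n_rec = config.n_recruited
    n_eval = config.n_participants

    pid = np.array([f"P{i:05d}" for i in range(1, n_rec + 1)])
    male = rng.random(n_rec) < config.male_fraction
    sex = np.where(male, "male", "female")
    age = _draw_two_piece(rng, n_rec, config.age_median, config.age_q1,
                          config.age_q3, config.age_bounds)

    # log-normal baseline truth calibrated to the target median/IQR
    sigma = np.log(config.gfr_q3 / config.gfr_q1) / (2 * 0.6745)
    base_gfr = np.exp(rng.normal(np.log(config.gfr_median), sigma, n_rec))
    base_gfr = np.clip(base_gfr, GFR_FLOOR + 2.0, 145.0)

    progressor = rng.random(n_rec) < config.progressor_fraction
    slope = np.where(
        progressor,
        rng.normal(config.progressor_slope_mean, config.progressor_slope_sd, n_rec),
        rng.normal(config.nonprogressor_slope_mean, config.nonprogressor_slope_sd, n_rec))

    bias_cr = rng.normal(0.0, config.person_bias_sd, n_rec)
    bias_cys = rng.normal(0.0, config.person_bias_sd, n_rec)

    # attrition: a random subset never reaches the 36-month visit
    order = rng.permutation(n_rec)
    evaluable = np.zeros(n_rec, dtype=bool)
    evaluable[order[:n_eval]] = True
    dropout_last_month = np.full(n_rec, VISIT_MONTHS[-1])
    dropout_last_month[~evaluable] = rng.choice(VISIT_MONTHS[:-1],
                                                size=(~evaluable).sum())

    # extra measured-GFR subsets at 12 and 24 months, among the evaluable
    def _scaled(k):
        return int(round(k * n_eval / config.reference_n))
    eval_idx = np.flatnonzero(evaluable)
    extra12 = np.zeros(n_rec, dtype=bool)
    extra24 = np.zeros(n_rec, dtype=bool)
    extra12[rng.choice(eval_idx, size=min(_scaled(config.extra_mgfr_12m),
                                          eval_idx.size), replace=False)] = True
    extra24[rng.choice(eval_idx, size=min(_scaled(config.extra_mgfr_24m),
                                          eval_idx.size), replace=False)] = True

    start = pd.Timestamp(config.recruitment_start)
    base_offset = rng.integers(0, config.recruitment_days + 1, n_rec)

    rows = []
    for m in VISIT_MONTHS:
        attend = dropout_last_month >= m
        idx = np.flatnonzero(attend)
        if idx.size == 0:
            continue
        t_nominal = m / 12.0
        jitter = (np.zeros(idx.size, dtype=int) if m == 0 else
                  rng.integers(-config.visit_jitter_days,
                               config.visit_jitter_days + 1, idx.size))
        day_offset = base_offset[idx] + np.round(t_nominal * 365.25).astype(int) + jitter
        dates = start + pd.to_timedelta(day_offset, unit="D")
        t_actual = (day_offset - base_offset[idx]) / 365.25

        true_gfr = np.maximum(base_gfr[idx] + slope[idx] * t_actual, GFR_FLOOR)
        mgfr_here = (m in (0, 36)) | (extra12[idx] & (m == 12)) | (extra24[idx] & (m == 24))
        mgfr = true_gfr * np.exp(rng.normal(0.0, config.mgfr_cv, idx.size)
                                 if config.mgfr_cv > 0 else 0.0)
        mgfr = np.where(mgfr_here, mgfr, np.nan)

        def _biomarker(generator, person_bias):
            seen = true_gfr * np.exp(person_bias) * np.exp(config.egfr_drift_rate * t_actual)
            seen = np.clip(seen, 5.5, 148.0)  # keep inside the invertible range
            conc = invert_equation_vector(generator, seen, age[idx], sex[idx])
            noise = (np.exp(rng.normal(0.0, config.biomarker_cv, idx.size))
                     if config.biomarker_cv > 0 else 1.0)
            return conc * noise

        scr = _biomarker(config.creatinine_generator, bias_cr[idx])
        scys = _biomarker(config.cystatin_generator, bias_cys[idx])

        rows.append(pd.DataFrame({
            "participant_id": pid[idx], "visit_date": dates, "month": m,
            "age_at_baseline": age[idx], "sex": sex[idx],
            "serum_creatinine": scr, "serum_cystatin_c": scys,
            "measured_gfr": mgfr, "true_gfr": true_gfr,
        }))

    visits = (pd.concat(rows, ignore_index=True)
              .sort_values(["participant_id", "visit_date"])
              .reset_index(drop=True))

    participants = pd.DataFrame({
        "participant_id": pid, "sex": sex, "age_at_baseline": age,
        "true_baseline_gfr": base_gfr, "true_slope": slope,
        "progressor": progressor, "evaluable": evaluable,
        "last_month": dropout_last_month,
        "extra_mgfr_12m": extra12, "extra_mgfr_24m": extra24,
        "baseline_date": start + pd.to_timedelta(base_offset, unit="D"),
    })
    return SyntheticCohort(participants=participants, visits=visits, config=config)
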