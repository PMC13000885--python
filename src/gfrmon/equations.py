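"""Closed-form GFR estimating equations: the CKD-EPI and EKFC families.

Eight equations are supported, spanning single-biomarker (serum creatinine
or cystatin C) and dual-biomarker forms:

* CKD-EPI creatinine (2009), cystatin (2012), creatinine-cystatin (2012)
* CKD-EPI creatinine (2021), creatinine-cystatin (2021) — race-free revisions
* EKFC creatinine, EKFC cystatin, EKFC creatinine-cystatin

All return GFR indexed to 1.73 m² body surface area (mL/min/1.73 m²).
The CKD-EPI forms are piecewise power functions with a sex-specific knot
(κ for creatinine, 0.8 mg/L for cystatin C); the EKFC forms rescale the
biomarker by a healthy-population median Q and switch exponent at
marker/Q = 1. Every coefficient lives in the declarative ``COEFFICIENTS``
registry so the numbers can be audited against the original publications
in one place.

Creatinine is accepted in µmol/L (the usual European reporting unit) and
converted internally to mg/dL, the scale on which the CKD-EPI coefficients
were published; cystatin C is mg/L throughout. The 2009/2012 CKD-EPI race
coefficient is implemented behind ``apply_race_term`` (default off,
matching contemporary UK practice); the 2021 CKD-EPI and EKFC equations
have no race term and ignore the flag.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

import numpy as np

__all__ = [
    "EquationId",
    "BiomarkerPanel",
    "GFRValue",
    "COEFFICIENTS",
    "convert_creatinine_umol_to_mgdl",
    "estimate_gfr",
    "estimate_gfr_vector",
    "registry_json",
]

UMOL_PER_MGDL = 88.4


class EquationId(str, Enum):
    """The eight estimating equations evaluated by the package."""

    CKDEPI_CR_2009 = "CKDEPI_CR_2009"
    CKDEPI_CYS_2012 = "CKDEPI_CYS_2012"
    CKDEPI_CRCYS_2012 = "CKDEPI_CRCYS_2012"
    CKDEPI_CR_2021 = "CKDEPI_CR_2021"
    CKDEPI_CRCYS_2021 = "CKDEPI_CRCYS_2021"
    EKFC_CR = "EKFC_CR"
    EKFC_CYS = "EKFC_CYS"
    EKFC_CRCYS = "EKFC_CRCYS"


#: equations that consume serum creatinine
CREATININE_EQUATIONS = frozenset({
    EquationId.CKDEPI_CR_2009, EquationId.CKDEPI_CRCYS_2012,
    EquationId.CKDEPI_CR_2021, EquationId.CKDEPI_CRCYS_2021,
    EquationId.EKFC_CR, EquationId.EKFC_CRCYS,
})

#: equations that consume serum cystatin C
CYSTATIN_EQUATIONS = frozenset({
    EquationId.CKDEPI_CYS_2012, EquationId.CKDEPI_CRCYS_2012,
    EquationId.CKDEPI_CRCYS_2021, EquationId.EKFC_CYS, EquationId.EKFC_CRCYS,
})


# Declarative coefficient registry. CKD-EPI terms follow
#   A * min(m/k,1)^alpha * max(m/k,1)^beta  per marker, * g^age * sex * race;
# EKFC terms follow 107.3 / (m/Q)^x * 0.990^(age-40) [age > 40] with
# x = 0.322 below m/Q = 1 and 1.132 above. EKFC creatinine Q is sex-specific
# (µmol/L); EKFC cystatin Q is age-dependent and sex-free (mg/L).
COEFFICIENTS = {
    EquationId.CKDEPI_CR_2009: {
        "family": "ckdepi",
        "intercept": 141.0,
        "age_base": 0.993,
        "female_factor": 1.018,
        "race_factor": 1.159,
        "creatinine": {"kappa": {"male": 0.9, "female": 0.7},
                       "alpha": {"male": -0.411, "female": -0.329},
                       "beta": -1.209},
    },
    EquationId.CKDEPI_CYS_2012: {
        "family": "ckdepi",
        "intercept": 133.0,
        "age_base": 0.996,
        "female_factor": 0.932,
        "race_factor": None,
        "cystatin": {"kappa": 0.8, "alpha": -0.499, "beta": -1.328},
    },
    EquationId.CKDEPI_CRCYS_2012: {
        "family": "ckdepi",
        "intercept": 135.0,
        "age_base": 0.995,
        "female_factor": 0.969,
        "race_factor": 1.08,
        "creatinine": {"kappa": {"male": 0.9, "female": 0.7},
                       "alpha": {"male": -0.207, "female": -0.248},
                       "beta": -0.601},
        "cystatin": {"kappa": 0.8, "alpha": -0.375, "beta": -0.711},
    },
    EquationId.CKDEPI_CR_2021: {
        "family": "ckdepi",
        "intercept": 142.0,
        "age_base": 0.9938,
        "female_factor": 1.012,
        "race_factor": None,
        "creatinine": {"kappa": {"male": 0.9, "female": 0.7},
                       "alpha": {"male": -0.302, "female": -0.241},
                       "beta": -1.200},
    },
    EquationId.CKDEPI_CRCYS_2021: {
        "family": "ckdepi",
        "intercept": 135.0,
        "age_base": 0.9961,
        "female_factor": 0.963,
        "race_factor": None,
        "creatinine": {"kappa": {"male": 0.9, "female": 0.7},
                       "alpha": {"male": -0.144, "female": -0.219},
                       "beta": -0.544},
        "cystatin": {"kappa": 0.8, "alpha": -0.323, "beta": -0.778},
    },
    EquationId.EKFC_CR: {
        "family": "ekfc",
        "intercept": 107.3,
        "age_base": 0.990,
        "age_pivot": 40.0,
        "exponent_low": 0.322,
        "exponent_high": 1.132,
        "marker": "creatinine",
        "q_umol": {"male": 80.0, "female": 62.0},
    },
    EquationId.EKFC_CYS: {
        "family": "ekfc",
        "intercept": 107.3,
        "age_base": 0.990,
        "age_pivot": 40.0,
        "exponent_low": 0.322,
        "exponent_high": 1.132,
        "marker": "cystatin",
        "q_mgl_base": 0.83,
        "q_age_knot": 50.0,
        "q_age_slope": 0.005,
    },
    EquationId.EKFC_CRCYS: {
        "family": "ekfc_mean",
        "components": [EquationId.EKFC_CR, EquationId.EKFC_CYS],
    },
}


def registry_json() -> str:
    """Serialize the coefficient registry to JSON for external audit."""
    def _default(obj):
        if isinstance(obj, Enum):
            return obj.value
        raise TypeError(obj)

    return json.dumps({k.value: v for k, v in COEFFICIENTS.items()},
                      indent=2, default=_default)


@dataclass(frozen=True)
class BiomarkerPanel:
    """One visit's serum biomarkers plus the demographics the equations need.

    Parameters
    ----------
    serum_creatinine
        Serum creatinine concentration. Interpreted per ``creatinine_unit``
        (default µmol/L; pass ``"mg/dL"`` for US-style values).
    serum_cystatin_c
        Serum cystatin C in mg/L.
    age
        Age in years; the equations are adult forms so age must be ≥ 18.
    sex
        ``"male"`` or ``"female"`` (assigned sex, as the equations were fit).
    black_ethnicity
        Only consulted by the 2009/2012 CKD-EPI race term when
        ``apply_race_term`` is enabled.
    """

    serum_creatinine: Optional[float] = None
    serum_cystatin_c: Optional[float] = None
    age: float = 60.0
    sex: str = "male"
    black_ethnicity: Optional[bool] = None
    creatinine_unit: str = "umol/L"

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 18:
            raise ValueError(f"age must be >= 18 (adult equations), got {self.age}")
        if self.creatinine_unit not in ("umol/L", "mg/dL"):
            raise ValueError(f"unknown creatinine unit {self.creatinine_unit!r}")
        if self.serum_creatinine is not None and self.serum_creatinine <= 0:
            raise ValueError("serum creatinine must be positive")
        if self.serum_cystatin_c is not None and self.serum_cystatin_c <= 0:
            raise ValueError("serum cystatin C must be positive")

    @property
    def creatinine_umol(self) -> Optional[float]:
        if self.serum_creatinine is None:
            return None
        if self.creatinine_unit == "mg/dL":
            return self.serum_creatinine * UMOL_PER_MGDL
        return self.serum_creatinine


@dataclass(frozen=True)
class GFRValue:
    """A GFR value (mL/min/1.73 m²) tagged with its provenance."""

    value: float
    source: Union[str, EquationId] = "measured"

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValueError(f"GFR must be positive and finite, got {self.value}")


def convert_creatinine_umol_to_mgdl(scr_umol):
    """Convert serum creatinine from µmol/L to mg/dL (divide by 88.4)."""
    scr_umol = np.asarray(scr_umol, dtype=float)
    if np.any(scr_umol <= 0):
        raise ValueError("creatinine concentration must be positive")
    out = scr_umol / UMOL_PER_MGDL
    return float(out) if out.ndim == 0 else out


def _sexed(coef, female):
    """Pick the sex-specific value from a {male, female} pair (array-aware)."""
    return np.where(female, coef["female"], coef["male"])


def _ckdepi_marker_term(value, kappa, alpha, beta):
    ratio = value / kappa
    return np.minimum(ratio, 1.0) ** alpha * np.maximum(ratio, 1.0) ** beta


def _evaluate(eq, scr_umol, scys, age, female, black, apply_race_term):
    """Array-aware core: all inputs broadcastable numpy arrays/scalars."""
    spec = COEFFICIENTS[eq]
    family = spec["family"]

    if family == "ekfc_mean":
        parts = [_evaluate(c, scr_umol, scys, age, female, black, apply_race_term)
                 for c in spec["components"]]
        return 0.5 * (parts[0] + parts[1])

    if family == "ckdepi":
        gfr = np.asarray(spec["intercept"], dtype=float)
        if "creatinine" in spec:
            c = spec["creatinine"]
            scr_mgdl = scr_umol / UMOL_PER_MGDL
            gfr = gfr * _ckdepi_marker_term(
                scr_mgdl, _sexed(c["kappa"], female), _sexed(c["alpha"], female),
                c["beta"])
        if "cystatin" in spec:
            c = spec["cystatin"]
            gfr = gfr * _ckdepi_marker_term(scys, c["kappa"], c["alpha"], c["beta"])
        gfr = gfr * spec["age_base"] ** age
        gfr = gfr * np.where(female, spec["female_factor"], 1.0)
        if apply_race_term and spec["race_factor"] is not None:
            gfr = gfr * np.where(black, spec["race_factor"], 1.0)
        return gfr

    # EKFC single-marker form
    if spec["marker"] == "creatinine":
        q = _sexed({"male": spec["q_umol"]["male"],
                    "female": spec["q_umol"]["female"]}, female)
        ratio = scr_umol / q
    else:
        q = spec["q_mgl_base"] + spec["q_age_slope"] * np.maximum(
            np.asarray(age, dtype=float) - spec["q_age_knot"], 0.0)
        ratio = scys / q
    x = np.where(ratio < 1.0, spec["exponent_low"], spec["exponent_high"])
    gfr = spec["intercept"] * ratio ** (-x)
    age_term = spec["age_base"] ** np.maximum(
        np.asarray(age, dtype=float) - spec["age_pivot"], 0.0)
    return gfr * age_term


def _require_markers(eq, scr_umol, scys):
    if eq in CREATININE_EQUATIONS and scr_umol is None:
        raise ValueError(f"{eq.value} requires serum creatinine")
    if eq in CYSTATIN_EQUATIONS and scys is None:
        raise ValueError(f"{eq.value} requires serum cystatin C")


def estimate_gfr(eq: EquationId, panel: BiomarkerPanel,
                 apply_race_term: bool = False) -> GFRValue:
    """Evaluate one estimating equation on one biomarker panel.

    Returns the body-surface-indexed estimate as a :class:`GFRValue` whose
    ``source`` is the equation id. Raises ``ValueError`` if the panel lacks
    a biomarker the equation requires, or for an unknown equation id.
    """
    eq = EquationId(eq)
    _require_markers(eq, panel.creatinine_umol, panel.serum_cystatin_c)
    black = bool(panel.black_ethnicity) if panel.black_ethnicity is not None else False
    value = _evaluate(
        eq,
        np.nan if panel.creatinine_umol is None else panel.creatinine_umol,
        np.nan if panel.serum_cystatin_c is None else panel.serum_cystatin_c,
        panel.age, panel.sex == "female", black, apply_race_term)
    return GFRValue(value=float(value), source=eq)


def estimate_gfr_vector(eq: EquationId, scr_umol, scys, age, sex,
                        black=None, apply_race_term: bool = False) -> np.ndarray:
    """Vectorized estimation over aligned arrays (creatinine in µmol/L).

    ``sex`` is an array of ``"male"``/``"female"`` strings; missing
    biomarkers may be NaN (the result is NaN where a required marker is
    missing, mirroring pandas missing-data semantics).
    """
    eq = EquationId(eq)
    scr_umol = np.asarray(scr_umol, dtype=float)
    scys = np.asarray(scys, dtype=float)
    age = np.asarray(age, dtype=float)
    female = np.asarray(sex) == "female"
    if np.any(age < 18):
        raise ValueError("all ages must be >= 18")
    black_arr = (np.zeros_like(female, dtype=bool) if black is None
                 else np.asarray(black, dtype=bool))
    with np.errstate(invalid="ignore"):
        out = _evaluate(eq, scr_umol, scys, age, female, black_arr, apply_race_term)
    return np.asarray(out, dtype=float)
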