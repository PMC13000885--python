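"""KDIGO GFR categories and the binary kidney-disease progression rule.

The KDIGO G-categories partition GFR (mL/min/1.73 m²) at 90, 60, 45, 30
and 15. Progression between two timepoints is called when the GFR falls by
at least 25% *and* the follow-up value sits in a strictly worse G-category
than baseline — the GFR half of the internationally agreed KDIGO
definition (albuminuria staging is out of scope here). Boundary
convention: intervals are half-open with the lower bound in the less
severe category, so exactly 45 is G3a and exactly 15 is G4.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Union

import numpy as np

from .equations import GFRValue

__all__ = ["GFRCategory", "ProgressionCall", "categorize", "classify_progression",
           "categorize_vector", "progressed_vector"]


class GFRCategory(IntEnum):
    """KDIGO G-categories ordered by severity (higher = worse)."""

    G1 = 1   # >= 90
    G2 = 2   # 60-89
    G3a = 3  # 45-59
    G3b = 4  # 30-44
    G4 = 5   # 15-29
    G5 = 6   # < 15


_BOUNDS = (90.0, 60.0, 45.0, 30.0, 15.0)


@dataclass(frozen=True)
class ProgressionCall:
    """Outcome of the two-clause progression rule between two visits."""

    progressed: bool
    relative_reduction: float
    baseline_category: GFRCategory
    followup_category: GFRCategory


def _as_value(gfr: Union[GFRValue, float]) -> float:
    v = gfr.value if isinstance(gfr, GFRValue) else float(gfr)
    if not np.isfinite(v) or v <= 0:
        raise ValueError(f"GFR must be positive and finite, got {v}")
    return v


def categorize(gfr: Union[GFRValue, float]) -> GFRCategory:
    """Map a positive GFR to its KDIGO G-category."""
    v = _as_value(gfr)
    for cat, bound in zip((GFRCategory.G1, GFRCategory.G2, GFRCategory.G3a,
                           GFRCategory.G3b, GFRCategory.G4), _BOUNDS):
        if v >= bound:
            return cat
    return GFRCategory.G5


def categorize_vector(gfr) -> np.ndarray:
    """Vectorized :func:`categorize`: array of severity codes (1=G1 … 6=G5)."""
    v = np.asarray(gfr, dtype=float)
    if np.any(v[np.isfinite(v)] <= 0):
        raise ValueError("GFR values must be positive")
    # searchsorted over descending bounds: count of bounds strictly above v
    return 1 + np.searchsorted(-np.asarray(_BOUNDS), -v, side="left").astype(int)


def classify_progression(baseline: Union[GFRValue, float],
                         followup: Union[GFRValue, float]) -> ProgressionCall:
    """Apply the KDIGO-style progression rule to a baseline/follow-up pair.

    Progression requires both a relative reduction of at least 25% and a
    drop to a strictly worse G-category (of any number of steps).
    """
    b = _as_value(baseline)
    f = _as_value(followup)
    if isinstance(baseline, GFRValue) and isinstance(followup, GFRValue):
        if baseline.source != followup.source:
            raise ValueError("baseline and follow-up must share a GFR source")
    reduction = (b - f) / b
    cat_b = categorize(b)
    cat_f = categorize(f)
    progressed = reduction >= 0.25 and cat_f > cat_b
    return ProgressionCall(progressed=progressed, relative_reduction=reduction,
                           baseline_category=cat_b, followup_category=cat_f)


def progressed_vector(baseline, followup) -> np.ndarray:
    """Vectorized progression calls on aligned baseline/follow-up arrays."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    reduction = (b - f) / b
    return (reduction >= 0.25) & (categorize_vector(f) > categorize_vector(b))
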