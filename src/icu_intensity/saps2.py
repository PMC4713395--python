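"""SAPS II severity scoring and predicted hospital mortality.

The Simplified Acute Physiology Score II assigns integer points to the
worst value of each of 15 variables (12 physiologic measurements, age,
chronic disease, admission type) observed during the first 24 h in the
ICU, and converts the total S to a hospital-mortality probability via

    logit = -7.7631 + 0.0737 * S + 0.9971 * ln(S + 1)
    p     = exp(logit) / (1 + exp(logit))

The weight table and the logit constants below are transcribed verbatim
from the original 1993 multicentre development study of the score; they
are frozen here as the single versioned constant table for the package
and pinned by checksum-style tests so silent edits fail.

The *age-adjusted* score is the total minus the age-related points; it is
the conventional age-independent severity index and the inclusion
threshold (> 15) used by the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .records import MIN_AGE, Physiology, saps2_unknown_mask

__all__ = [
    "Saps2Result",
    "age_points",
    "age_adjusted",
    "predicted_mortality",
    "score_saps2",
    "score_frame",
    "SAPS2_MAX_SCORE",
]

# --- frozen weight table (original 1993 definition) -------------------------
# Each physiologic entry: (upper-edge list, points list) meaning
# value < edges[i] -> points[i]; value >= edges[-1] -> points[-1].
# Units follow the cohort schema (urine L/24h, urea mmol/L, bilirubin µmol/L).

_BANDS: dict[str, tuple[tuple[float, ...], tuple[int, ...]]] = {
    "heart_rate": ((40, 70, 120, 160), (11, 2, 0, 4, 7)),
    "systolic_bp": ((70, 100, 200), (13, 5, 0, 2)),
    "temperature": ((39,), (0, 3)),
    "pao2_fio2": ((100, 200), (11, 9, 6)),  # scored only if ventilated/CPAP
    "urine_output": ((0.5, 1.0), (11, 4, 0)),
    "serum_urea": ((10, 30), (0, 6, 10)),
    "wbc": ((1, 20), (12, 0, 3)),
    "potassium": ((3, 5), (3, 0, 3)),
    "sodium": ((125, 145), (5, 0, 1)),
    "bicarbonate": ((15, 20), (6, 3, 0)),
    "bilirubin": ((68.4, 102.6), (0, 4, 9)),
    "gcs": ((6, 9, 11, 14), (26, 13, 7, 5, 0)),
}

_AGE_EDGES = (40, 60, 70, 75, 80)
_AGE_POINTS = (0, 7, 12, 15, 16, 18)

_CHRONIC_POINTS = {
    "none": 0,
    "metastatic_cancer": 9,
    "hematologic_malignancy": 10,
    "aids": 17,
}
_ADMISSION_POINTS = {
    "scheduled_surgical": 0,
    "medical": 6,
    "unscheduled_surgical": 8,
}

_LOGIT_INTERCEPT = -7.7631
_LOGIT_SLOPE = 0.0737
_LOGIT_LOG_SLOPE = 0.9971

#: largest attainable total (every component at its maximum weight)
SAPS2_MAX_SCORE = 163


@dataclass(frozen=True)
class Saps2Result:
    """Component-wise SAPS II breakdown for one stay."""

    component_points: Mapping[str, int]
    total: int
    age_points: int
    age_adjusted: int
    predicted_mortality: float


def _band_points(name: str, value: float) -> int:
    edges, points = _BANDS[name]
    return points[int(np.searchsorted(edges, value, side="right"))]


def age_points(age: float) -> int:
    """Age-related SAPS II points on the six canonical bands.

    Bands are left-closed: <40 → 0, [40,60) → 7, [60,70) → 12,
    [70,75) → 15, [75,80) → 16, ≥80 → 18.
    """
    if age < MIN_AGE:
        raise ValueError(f"age={age} < {MIN_AGE}")
    return _AGE_POINTS[int(np.searchsorted(_AGE_EDGES, age, side="right"))]


def predicted_mortality(total: float) -> float:
    """Convert a SAPS II total to the predicted hospital-mortality probability."""
    if total < 0:
        raise ValueError(f"SAPS II total must be >= 0, got {total}")
    logit = _LOGIT_INTERCEPT + _LOGIT_SLOPE * total + _LOGIT_LOG_SLOPE * np.log(total + 1.0)
    return float(1.0 / (1.0 + np.exp(-logit)))


def age_adjusted(total: int, age: float) -> int:
    """Total minus the age-related points (age-independent severity index)."""
    pts = age_points(age)
    if total < pts:
        raise ValueError(
            f"inconsistent inputs: total {total} < age points {pts} for age {age}"
        )
    return int(total) - pts


def score_saps2(
    age: float, physiology: Physiology, ventilated: Optional[bool] = None
) -> Saps2Result:
    """Score one stay.

    Parameters
    ----------
    age
        Age at ICU admission in years (≥ 16).
    physiology
        Scoreable worst-in-first-24h values; must be non-null.
    ventilated
        Caller's ventilation/CPAP flag. If ``False`` while ``pao2_fio2`` is
        supplied, the input is rejected (the oxygenation component is defined
        only on ventilation or CPAP). ``None`` infers from ``pao2_fio2``.
    """
    if physiology is None:
        raise ValueError("cannot score a stay with unknown physiology")
    if ventilated is False and physiology.pao2_fio2 is not None:
        raise ValueError("pao2_fio2 supplied for a non-ventilated stay")

    components: dict[str, int] = {"age": age_points(age)}
    for name in _BANDS:
        if name == "pao2_fio2":
            value = physiology.pao2_fio2
            components[name] = 0 if value is None else _band_points(name, value)
        else:
            components[name] = _band_points(name, getattr(physiology, name))
    components["chronic_disease"] = _CHRONIC_POINTS[physiology.chronic_disease]
    components["admission_type"] = _ADMISSION_POINTS[physiology.admission_type]

    total = int(sum(components.values()))
    a_pts = components["age"]
    return Saps2Result(
        component_points=components,
        total=total,
        age_points=a_pts,
        age_adjusted=total - a_pts,
        predicted_mortality=predicted_mortality(total),
    )


def _vector_band_points(name: str, values: np.ndarray) -> np.ndarray:
    edges, points = _BANDS[name]
    out = np.asarray(points)[np.searchsorted(edges, values, side="right")]
    return out.astype(np.int64)


def score_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring of a cohort frame.

    Returns a copy with appended columns ``saps2_total``, ``saps2_age_points``,
    ``saps2_age_adjusted``, ``predicted_mortality`` and the boolean flag
    ``saps2_unknown``. Rows with unknown physiology get NaN scores and the
    flag set; no imputation is performed.
    """
    frame = frame.copy()
    unknown = saps2_unknown_mask(frame).to_numpy()
    n = len(frame)
    total = np.zeros(n, dtype=np.float64)

    age = frame["age"].to_numpy(dtype=np.float64)
    if (age < MIN_AGE).any():
        raise ValueError(f"age < {MIN_AGE} in cohort")
    a_pts = np.asarray(_AGE_POINTS)[np.searchsorted(_AGE_EDGES, age, side="right")]
    total += a_pts

    for name in _BANDS:
        values = frame[name].to_numpy(dtype=np.float64)
        pts = np.where(
            np.isnan(values), 0, _vector_band_points(name, np.nan_to_num(values))
        )
        total += pts
    chronic = frame["chronic_disease"].map(_CHRONIC_POINTS).to_numpy(dtype=np.float64)
    admission = frame["admission_type"].map(_ADMISSION_POINTS).to_numpy(dtype=np.float64)
    total += np.where(unknown, 0.0, chronic)
    total += np.where(unknown, 0.0, admission)

    total = np.where(unknown, np.nan, total)
    logit = (
        _LOGIT_INTERCEPT + _LOGIT_SLOPE * total + _LOGIT_LOG_SLOPE * np.log(total + 1.0)
    )
    frame["saps2_total"] = total
    frame["saps2_age_points"] = np.where(unknown, np.nan, a_pts.astype(np.float64))
    frame["saps2_age_adjusted"] = total - frame["saps2_age_points"]
    frame["predicted_mortality"] = 1.0 / (1.0 + np.exp(-logit))
    frame["saps2_unknown"] = unknown
    return frame
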