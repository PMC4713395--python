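"""Cohort inclusion rules and flowchart accounting.

A hospital stay enters the analysis cohort iff

* its ICU stay was in a *medical* ICU,
* it contained exactly one ICU stay,
* its SAPS II is known (physiology coded), and
* its age-adjusted SAPS II is strictly greater than 15 — the threshold
  used in France to separate intensive-care from intermediate-care stays.

A stay can fail several criteria; each is counted once under the first
failing reason in the fixed precedence order

    non-medical ICU → multiple ICU stays → unknown SAPS II → low severity

so that flowchart counts are reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .records import MIN_AGE

__all__ = [
    "AGE_BANDS",
    "FlowchartCounts",
    "age_band",
    "age_binary",
    "age_band_frame",
    "apply_inclusion",
    "AGE_ADJUSTED_THRESHOLD",
]

#: the qualitative age bands of the SAPS II score, left-closed
AGE_BANDS = ("<40", "40-59", "60-69", "70-74", "75-79", ">=80")
_AGE_EDGES = (40, 60, 70, 75, 80)

AGE_ADJUSTED_THRESHOLD = 15  # included iff age-adjusted SAPS II > 15 (strict)


@dataclass(frozen=True)
class FlowchartCounts:
    """Per-reason exclusion tally; ``n_input = n_included + Σ exclusions``."""

    n_input: int
    n_excluded_non_medical_icu: int
    n_excluded_multiple_icu: int
    n_excluded_unknown_saps2: int
    n_excluded_low_severity: int
    n_included: int

    def __post_init__(self) -> None:
        excluded = (
            self.n_excluded_non_medical_icu
            + self.n_excluded_multiple_icu
            + self.n_excluded_unknown_saps2
            + self.n_excluded_low_severity
        )
        if self.n_input != self.n_included + excluded:
            raise ValueError("flowchart counts do not partition the input")
        if min(asdict(self).values()) < 0:
            raise ValueError("flowchart counts must be non-negative")

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


def age_band(age: float) -> str:
    """Map an age to its SAPS II qualitative band (left-closed bands)."""
    if age < MIN_AGE:
        raise ValueError(f"age={age} < {MIN_AGE}")
    return AGE_BANDS[int(np.searchsorted(_AGE_EDGES, age, side="right"))]


def age_binary(age: float) -> str:
    """Dichotomize age at the 80-year threshold: ``"<80"`` or ``">=80"``."""
    if age < MIN_AGE:
        raise ValueError(f"age={age} < {MIN_AGE}")
    return ">=80" if age >= 80 else "<80"


def age_band_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Append ``age_band`` and ``age_binary`` columns (vectorized)."""
    frame = frame.copy()
    age = frame["age"].to_numpy(dtype=np.float64)
    if (age < MIN_AGE).any():
        raise ValueError(f"age < {MIN_AGE} in cohort")
    bands = np.asarray(AGE_BANDS, dtype=object)
    frame["age_band"] = bands[np.searchsorted(_AGE_EDGES, age, side="right")]
    frame["age_binary"] = np.where(age >= 80, ">=80", "<80").astype(object)
    return frame


def apply_inclusion(scored: pd.DataFrame) -> tuple[pd.DataFrame, FlowchartCounts]:
    """Apply the inclusion rules to a scored cohort frame.

    Parameters
    ----------
    scored
        Cohort frame already carrying ``saps2_age_adjusted`` and
        ``saps2_unknown`` columns (see :func:`icu_intensity.saps2.score_frame`).

    Returns
    -------
    (included, counts)
        The included sub-frame (original order, index reset) and the
        flowchart accounting.
    """
    for col in ("saps2_age_adjusted", "saps2_unknown"):
        if col not in scored.columns:
            raise ValueError(f"frame is not scored: missing column {col!r}")

    non_medical = (scored["icu_type"] != "medical").to_numpy()
    multiple = (scored["n_icu_stays_in_hospital_stay"] > 1).to_numpy()
    unknown = scored["saps2_unknown"].to_numpy(dtype=bool)
    adj = scored["saps2_age_adjusted"].to_numpy(dtype=np.float64)
    low_severity = ~unknown & ~(adj > AGE_ADJUSTED_THRESHOLD)

    # precedence: each record counted once under its first failing reason
    reason = np.full(len(scored), "included", dtype=object)
    reason[low_severity] = "low_severity"
    reason[unknown] = "unknown_saps2"
    reason[multiple] = "multiple_icu"
    reason[non_medical] = "non_medical_icu"

    counts = FlowchartCounts(
        n_input=len(scored),
        n_excluded_non_medical_icu=int((reason == "non_medical_icu").sum()),
        n_excluded_multiple_icu=int((reason == "multiple_icu").sum()),
        n_excluded_unknown_saps2=int((reason == "unknown_saps2").sum()),
        n_excluded_low_severity=int((reason == "low_severity").sum()),
        n_included=int((reason == "included").sum()),
    )
    included = scored.loc[reason == "included"].reset_index(drop=True)
    return included, counts
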