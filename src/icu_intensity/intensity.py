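"""Four-group ICU treatment-intensity classification.

The indicator grades the three most frequent organ supports — hemodynamic,
respiratory and renal — as *low-intense* or *high-intense* and combines
them into four groups:

======  ======================================================
group   definition
======  ======================================================
0       no support
1       one low-intense support
2       two low-intense supports, or one high-intense support
3       more intense support
======  ======================================================

Support levels (stay-level maxima; the database stores per-stay summaries,
not a timeline):

* hemodynamic — low: dobutamine or dopamine at ≤ 8 µg/kg/min;
  high: dobutamine/dopamine > 8 µg/kg/min, or any epinephrine or
  norepinephrine (no dose threshold).
* respiratory — low: noninvasive ventilation, or invasive mechanical
  ventilation with FiO2 < 0.6 **and** PEEP < 6 cm H2O;
  high: invasive ventilation with FiO2 ≥ 0.6 **or** PEEP ≥ 6 cm H2O.
* renal — any renal replacement therapy is high-intense (there is no
  low-intense renal support).

Group 3 ("more intense support") is formalized as intensity points ≥ 3
with low = 1 and high = 2 points per organ: the unique monotone extension
of the three defined groups (0 → 0, 1 → 1, 2 → 2 points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DOSE_DEPENDENT_CATECHOLAMINES, SupportEvents

__all__ = [
    "SupportProfile",
    "classify_supports",
    "intensity_group",
    "classify_frame",
    "DOSE_THRESHOLD",
    "FIO2_THRESHOLD",
    "PEEP_THRESHOLD",
]

DOSE_THRESHOLD = 8.0  # µg/kg/min; ≤ threshold is low-intense
FIO2_THRESHOLD = 0.6  # ≥ threshold is high-intense
PEEP_THRESHOLD = 6.0  # cm H2O; ≥ threshold is high-intense

LEVEL_POINTS = {"none": 0, "low": 1, "high": 2}


@dataclass(frozen=True)
class SupportProfile:
    """Per-organ support level and the derived intensity group of one stay."""

    hemodynamic: str
    respiratory: str
    renal: str
    intensity_points: int
    group: int


def _hemodynamic_level(supports: SupportEvents) -> str:
    agent = supports.catecholamine
    if agent in ("epinephrine", "norepinephrine"):
        return "high"
    if agent in DOSE_DEPENDENT_CATECHOLAMINES:
        return "low" if supports.catecholamine_max_dose <= DOSE_THRESHOLD else "high"
    return "none"


def _respiratory_level(supports: SupportEvents) -> str:
    # invasive settings decide when both NIV and invasive MV occurred (max rule)
    if supports.invasive_mv:
        if supports.mv_max_fio2 >= FIO2_THRESHOLD or supports.mv_max_peep >= PEEP_THRESHOLD:
            return "high"
        return "low"
    if supports.niv:
        return "low"
    return "none"


def classify_supports(supports: SupportEvents) -> SupportProfile:
    """Classify one stay's organ supports into levels and intensity group.

    Each organ takes the maximum level attained by any qualifying support
    of that organ over the whole stay; points are summed (low = 1,
    high = 2) and the group is ``min(points, 3)``.
    """
    hemo = _hemodynamic_level(supports)
    resp = _respiratory_level(supports)
    renal = "high" if supports.rrt else "none"
    points = LEVEL_POINTS[hemo] + LEVEL_POINTS[resp] + LEVEL_POINTS[renal]
    return SupportProfile(
        hemodynamic=hemo,
        respiratory=resp,
        renal=renal,
        intensity_points=points,
        group=min(points, 3),
    )


def intensity_group(records) -> list[int]:
    """Vectorized group assignment over an iterable of SupportEvents (order kept)."""
    return [classify_supports(s).group for s in records]


def classify_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of a cohort frame.

    Returns a copy with appended columns ``hemodynamic_level``,
    ``respiratory_level``, ``renal_level``, ``intensity_points`` and
    ``intensity_group``.
    """
    frame = frame.copy()
    agent = frame["catecholamine"].to_numpy(dtype=object)
    dose = frame["catecholamine_max_dose"].to_numpy(dtype=np.float64)
    hemo = np.where(
        np.isin(agent, ("epinephrine", "norepinephrine")),
        2,
        np.where(
            np.isin(agent, DOSE_DEPENDENT_CATECHOLAMINES),
            np.where(dose <= DOSE_THRESHOLD, 1, 2),
            0,
        ),
    )

    invasive = frame["invasive_mv"].to_numpy(dtype=bool)
    fio2 = np.nan_to_num(frame["mv_max_fio2"].to_numpy(dtype=np.float64))
    peep = np.nan_to_num(frame["mv_max_peep"].to_numpy(dtype=np.float64))
    inv_high = invasive & ((fio2 >= FIO2_THRESHOLD) | (peep >= PEEP_THRESHOLD))
    resp = np.where(
        inv_high, 2, np.where(invasive | frame["niv"].to_numpy(dtype=bool), 1, 0)
    )

    renal = np.where(frame["rrt"].to_numpy(dtype=bool), 2, 0)

    points = hemo + resp + renal
    level_names = np.array(["none", "low", "high"], dtype=object)
    frame["hemodynamic_level"] = level_names[hemo]
    frame["respiratory_level"] = level_names[resp]
    frame["renal_level"] = level_names[renal]
    frame["intensity_points"] = points.astype(np.int64)
    frame["intensity_group"] = np.minimum(points, 3).astype(np.int64)
    return frame
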