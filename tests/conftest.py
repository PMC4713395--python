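"""Shared fixtures: zero-point physiology, random record generators."""

from __future__ import annotations

import numpy as np
import pytest

from icu_intensity.records import (
    ADMISSION_TYPES,
    CHRONIC_DISEASES,
    Physiology,
    SupportEvents,
)


@pytest.fixture
def zero_band_physiology() -> Physiology:
    """Every scored component in its zero-point band (total contribution 0)."""
    return Physiology(
        heart_rate=80,
        systolic_bp=120,
        temperature=37.0,
        pao2_fio2=None,
        urine_output=1.5,
        serum_urea=5.0,
        wbc=8.0,
        potassium=4.0,
        sodium=140,
        bicarbonate=24.0,
        bilirubin=10.0,
        gcs=15,
        chronic_disease="none",
        admission_type="scheduled_surgical",
    )


def random_physiology(rng: np.random.Generator) -> Physiology:
    """One physiology draw spanning all point bands (bounds-respecting)."""
    return Physiology(
        heart_rate=float(rng.uniform(20, 220)),
        systolic_bp=float(rng.uniform(40, 260)),
        temperature=float(rng.uniform(30, 42)),
        pao2_fio2=float(rng.uniform(40, 500)) if rng.random() < 0.5 else None,
        urine_output=float(rng.uniform(0, 5)),
        serum_urea=float(rng.uniform(1, 60)),
        wbc=float(rng.uniform(0.2, 50)),
        potassium=float(rng.uniform(1.5, 8)),
        sodium=float(rng.uniform(110, 170)),
        bicarbonate=float(rng.uniform(4, 40)),
        bilirubin=float(rng.uniform(1, 300)),
        gcs=int(rng.integers(3, 16)),
        chronic_disease=str(rng.choice(CHRONIC_DISEASES)),
        admission_type=str(rng.choice(ADMISSION_TYPES)),
    )


def random_supports(rng: np.random.Generator) -> SupportEvents:
    """One valid SupportEvents draw; doses/settings straddle every threshold."""
    agent = str(
        rng.choice(["none", "dobutamine", "dopamine", "epinephrine", "norepinephrine"])
    )
    dose = None
    if agent in ("dobutamine", "dopamine"):
        dose = float(rng.choice([2.0, 5.0, 7.9, 8.0, 8.1, 12.0, 20.0]))
    invasive = bool(rng.random() < 0.5)
    fio2 = peep = None
    if invasive:
        fio2 = float(rng.choice([0.21, 0.4, 0.59, 0.6, 0.61, 0.8, 1.0]))
        peep = float(rng.choice([0.0, 4.0, 5.0, 6.0, 7.0, 10.0, 14.0]))
    return SupportEvents(
        catecholamine=agent,
        catecholamine_max_dose=dose,
        niv=bool(rng.random() < 0.3),
        invasive_mv=invasive,
        mv_max_fio2=fio2,
        mv_max_peep=peep,
        rrt=bool(rng.random() < 0.3),
    )
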