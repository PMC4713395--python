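"""SAPS II scoring: frozen-table pins, examples, and an independent oracle."""

from __future__ import annotations

import numpy as np
import pytest

from icu_intensity.records import Physiology
from icu_intensity.saps2 import (
    SAPS2_MAX_SCORE,
    Saps2Result,
    age_adjusted,
    age_points,
    predicted_mortality,
    score_frame,
    score_saps2,
)

from conftest import random_physiology


# -- independent oracle: explicit if-chain transcription of the weight table --

def oracle_points(age: float, p: Physiology) -> int:
    pts = 0
    if age < 40:
        pts += 0
    elif age < 60:
        pts += 7
    elif age < 70:
        pts += 12
    elif age < 75:
        pts += 15
    elif age < 80:
        pts += 16
    else:
        pts += 18
    hr = p.heart_rate
    pts += 11 if hr < 40 else 2 if hr < 70 else 0 if hr < 120 else 4 if hr < 160 else 7
    bp = p.systolic_bp
    pts += 13 if bp < 70 else 5 if bp < 100 else 0 if bp < 200 else 2
    pts += 3 if p.temperature >= 39 else 0
    if p.pao2_fio2 is not None:
        pf = p.pao2_fio2
        pts += 11 if pf < 100 else 9 if pf < 200 else 6
    uo = p.urine_output
    pts += 11 if uo < 0.5 else 4 if uo < 1.0 else 0
    pts += 0 if p.serum_urea < 10 else 6 if p.serum_urea < 30 else 10
    pts += 12 if p.wbc < 1 else 0 if p.wbc < 20 else 3
    pts += 3 if p.potassium < 3 else 0 if p.potassium < 5 else 3
    pts += 5 if p.sodium < 125 else 0 if p.sodium < 145 else 1
    pts += 6 if p.bicarbonate < 15 else 3 if p.bicarbonate < 20 else 0
    bili = p.bilirubin
    pts += 0 if bili < 68.4 else 4 if bili < 102.6 else 9
    g = p.gcs
    pts += 26 if g < 6 else 13 if g < 9 else 7 if g < 11 else 5 if g < 14 else 0
    pts += {"none": 0, "metastatic_cancer": 9, "hematologic_malignancy": 10, "aids": 17}[
        p.chronic_disease
    ]
    pts += {"scheduled_surgical": 0, "medical": 6, "unscheduled_surgical": 8}[
        p.admission_type
    ]
    return pts


def test_zero_band_physiology_scores_zero(zero_band_physiology):
    result = score_saps2(30, zero_band_physiology)
    assert result.total == 0
    assert result.age_points == 0
    assert result.age_adjusted == 0
    assert all(v == 0 for v in result.component_points.values())


def test_age_is_only_nonzero_component_at_82(zero_band_physiology):
    result = score_saps2(82, zero_band_physiology)
    assert result.total == result.age_points == 18
    assert result.age_adjusted == 0


@pytest.mark.parametrize(
    "age,expected",
    [(16, 0), (39, 0), (40, 7), (59, 7), (60, 12), (69, 12), (70, 15), (74, 15),
     (75, 16), (79, 16), (80, 18), (95, 18)],
)
def test_age_points_bands_left_closed(age, expected):
    assert age_points(age) == expected


def test_age_points_rejects_pediatric_age():
    with pytest.raises(ValueError):
        age_points(15)


def test_age_points_consistent_with_full_score(zero_band_physiology):
    for age in (20, 45, 65, 72, 77, 90):
        assert age_points(age) == score_saps2(age, zero_band_physiology).total


@pytest.mark.parametrize(
    "score,expected,tol",
    [(0, 0.000423, 5e-6), (36, 0.181, 5e-4), (77, 0.905, 5e-4)],
)
def test_predicted_mortality_reference_values(score, expected, tol):
    # frozen by direct evaluation of the published logistic conversion
    assert predicted_mortality(score) == pytest.approx(expected, abs=tol)


def test_predicted_mortality_strictly_monotone_full_grid():
    probs = [predicted_mortality(s) for s in range(SAPS2_MAX_SCORE + 1)]
    assert all(0 < p < 1 for p in probs)
    assert all(b > a for a, b in zip(probs, probs[1:]))


def test_predicted_mortality_rejects_negative_score():
    with pytest.raises(ValueError):
        predicted_mortality(-1)


def test_age_adjusted_examples():
    assert age_adjusted(43, 82) == 43 - 18
    assert age_adjusted(36, 30) == 36
    with pytest.raises(ValueError):
        age_adjusted(15, 82)


def test_pao2_fio2_rejected_for_declared_nonventilated(zero_band_physiology):
    from dataclasses import replace

    phys = replace(zero_band_physiology, pao2_fio2=250.0)
    with pytest.raises(ValueError):
        score_saps2(50, phys, ventilated=False)
    # accepted when the flag says ventilated
    assert score_saps2(50, phys, ventilated=True).component_points["pao2_fio2"] == 6


def test_weight_table_checksum_pins():
    """Sum of all weights and the maximal score pin the frozen table."""
    from icu_intensity.saps2 import _ADMISSION_POINTS, _AGE_POINTS, _BANDS, _CHRONIC_POINTS

    checksum = (
        sum(sum(points) for _, points in _BANDS.values())
        + sum(_AGE_POINTS)
        + sum(_CHRONIC_POINTS.values())
        + sum(_ADMISSION_POINTS.values())
    )
    assert checksum == 322
    max_total = (
        sum(max(points) for _, points in _BANDS.values())
        + max(_AGE_POINTS)
        + max(_CHRONIC_POINTS.values())
        + max(_ADMISSION_POINTS.values())
    )
    assert max_total == SAPS2_MAX_SCORE == 163


def test_score_matches_oracle_and_conserves_components():
    rng = np.random.default_rng(42)
    for _ in range(2000):
        age = float(rng.uniform(16, 100))
        phys = random_physiology(rng)
        result = score_saps2(age, phys)
        assert result.total == sum(result.component_points.values())
        assert result.total == oracle_points(age, phys)
        assert result.age_adjusted == result.total - result.age_points


def test_age_adjusted_independent_of_age_at_fixed_physiology():
    rng = np.random.default_rng(7)
    for _ in range(200):
        phys = random_physiology(rng)
        adjusted = {score_saps2(age, phys).age_adjusted for age in (20, 45, 65, 85)}
        assert len(adjusted) == 1


def test_vectorized_scoring_agrees_with_per_record():
    import pandas as pd

    rng = np.random.default_rng(11)
    rows, expected = [], []
    for _ in range(500):
        age = int(rng.integers(16, 100))
        phys = random_physiology(rng)
        result = score_saps2(age, phys)
        expected.append(result.total)
        row = {"age": age}
        for name in ("heart_rate", "systolic_bp", "temperature", "pao2_fio2",
                     "urine_output", "serum_urea", "wbc", "potassium", "sodium",
                     "bicarbonate", "bilirubin", "gcs", "chronic_disease",
                     "admission_type"):
            row[name] = getattr(phys, name)
        rows.append(row)
    frame = score_frame(pd.DataFrame(rows))
    assert frame["saps2_total"].to_numpy().tolist() == expected
    assert not frame["saps2_unknown"].any()
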