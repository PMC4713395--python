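"""Synthetic administrative ICU cohort generator with known ground truth.

The generator emulates the *structure* the analysis assumes, not any real
joint distribution: one row per hospital stay; age drawn from a truncated
normal mixture with mean ≈ 58 y and a ≥80-y tail; one standard-normal
latent severity per stay, mildly correlated with age; physiology fields
as monotone deformations of the latent plus noise; organ-support
allocation logistic in the latent (inducing the severity–intensity
correlation); and hospital death drawn Bernoulli with

    p = min(1, m_stratum · p_SAPS2)

where ``p_SAPS2`` is the SAPS II predicted mortality of the generated
physiology and ``m_stratum`` a configurable multiplier per
(age band × intensity group) stratum — so the stratum SMR equals the
multiplier in expectation (exactly, when no clamping occurs), giving a
closed-form recovery target. Strata are assigned with the *same* scoring,
classification and age-band code the analysis uses.

Dose, FiO2 and PEEP values are generated on both sides of (and exactly
at) every classification threshold — 8 µg/kg/min, FiO2 0.6, PEEP 6 cm
H2O — so boundary behavior is always exercised.

All randomness flows from one seeded :func:`numpy.random.default_rng`
generator; generation is a pure function of the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .filters import AGE_BANDS, age_band_frame
from .intensity import classify_frame
from .records import COHORT_COLUMNS, PHYSIOLOGY_COLUMNS, normalize_frame
from .saps2 import score_frame

__all__ = [
    "AgeMixture",
    "SimulationConfig",
    "ConfigurationError",
    "generate_cohort",
    "true_death_probability",
    "load_config",
    "save_config",
    "INTENSITY_GROUPS",
    "DEFAULT_SEED",
]

INTENSITY_GROUPS = (0, 1, 2, 3)
DEFAULT_SEED = 20060101


class ConfigurationError(ValueError):
    """An invalid simulation configuration; the message names the field."""

    def __init__(self, fieldname: str, message: str) -> None:
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class AgeMixture:
    """Truncated normal mixture for age at ICU admission.

    Defaults give mean ≈ 58.3 y, SD ≈ 18.4 y and ≈ 14 % of stays aged
    ≥ 80 y, emulating a large adult medical-ICU case mix.
    """

    means: tuple[float, ...] = (40.0, 63.0, 84.0)
    sds: tuple[float, ...] = (12.0, 10.0, 5.5)
    weights: tuple[float, ...] = (0.35, 0.49, 0.16)
    min_age: float = 16.0
    max_age: float = 105.0

    def validate(self) -> None:
        if not (len(self.means) == len(self.sds) == len(self.weights)):
            raise ConfigurationError(
                "age_distribution", "means, sds and weights must have equal length"
            )
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError("age_distribution.weights", "must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ConfigurationError("age_distribution.weights", "must be >= 0")
        if any(s <= 0 for s in self.sds):
            raise ConfigurationError("age_distribution.sds", "must be > 0")
        if not 16 <= self.min_age < self.max_age:
            raise ConfigurationError(
                "age_distribution", "need 16 <= min_age < max_age"
            )


def _uniform_multipliers(value: float = 1.0) -> dict[str, float]:
    return {f"{band}:{group}": value for band in AGE_BANDS for group in INTENSITY_GROUPS}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic cohort.

    ``mortality_multipliers`` maps ``"<age band>:<intensity group>"`` (for
    example ``">=80:3"``) to the multiplier applied to the SAPS II
    predicted mortality in that stratum; omitted strata default to 1.
    """

    n_stays: int = 10_000
    seed: int = DEFAULT_SEED
    age_distribution: AgeMixture = field(default_factory=AgeMixture)
    #: coefficient of standardized age in the latent severity draw
    latent_severity_model: Mapping[str, float] = field(
        default_factory=lambda: {"age_coef": 0.15, "field_loading": 0.7}
    )
    #: logistic (intercept, slope-in-latent) per support channel
    support_allocation: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "invasive_mv": (-0.5, 1.3),
            "niv": (-2.0, 0.4),
            "catecholamine": (-0.6, 1.4),
            "rrt": (-1.8, 1.1),
        }
    )
    mortality_multipliers: Mapping[str, float] = field(
        default_factory=_uniform_multipliers
    )
    frac_multiple_icu_stays: float = 0.176
    frac_unknown_saps2: float = 0.03
    frac_other_icu: float = 0.05

    def __post_init__(self) -> None:
        if self.n_stays < 0:
            raise ConfigurationError("n_stays", "must be >= 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed", "must be an integer")
        self.age_distribution.validate()
        for name in ("frac_multiple_icu_stays", "frac_unknown_saps2", "frac_other_icu"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(name, "must be a probability in [0, 1]")
        for channel in ("invasive_mv", "niv", "catecholamine", "rrt"):
            if channel not in self.support_allocation:
                raise ConfigurationError(
                    "support_allocation", f"missing channel {channel!r}"
                )
        full = _uniform_multipliers()
        for key, value in self.mortality_multipliers.items():
            if key not in full:
                raise ConfigurationError(
                    "mortality_multipliers",
                    f"unknown stratum {key!r}; keys are '<band>:<group>' with "
                    f"bands {AGE_BANDS} and groups {INTENSITY_GROUPS}",
                )
            if value < 0:
                raise ConfigurationError(
                    "mortality_multipliers", f"multiplier for {key!r} must be >= 0"
                )
        full.update(self.mortality_multipliers)
        object.__setattr__(self, "mortality_multipliers", full)

    def multiplier(self, band: str, group: int) -> float:
        return self.mortality_multipliers[f"{band}:{group}"]

    def with_multipliers(self, multipliers: Mapping[str, float]) -> "SimulationConfig":
        return replace(self, mortality_multipliers=dict(multipliers))

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_stays": self.n_stays,
            "seed": self.seed,
            "age_distribution": {
                "means": list(self.age_distribution.means),
                "sds": list(self.age_distribution.sds),
                "weights": list(self.age_distribution.weights),
                "min_age": self.age_distribution.min_age,
                "max_age": self.age_distribution.max_age,
            },
            "latent_severity_model": dict(self.latent_severity_model),
            "support_allocation": {
                k: list(v) for k, v in self.support_allocation.items()
            },
            "mortality_multipliers": dict(self.mortality_multipliers),
            "frac_multiple_icu_stays": self.frac_multiple_icu_stays,
            "frac_unknown_saps2": self.frac_unknown_saps2,
            "frac_other_icu": self.frac_other_icu,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "age_distribution" in data:
            ad = dict(data["age_distribution"])
            for key in ("means", "sds", "weights"):
                if key in ad:
                    ad[key] = tuple(ad[key])
            data["age_distribution"] = AgeMixture(**ad)
        if "support_allocation" in data:
            data["support_allocation"] = {
                k: tuple(v) for k, v in data["support_allocation"].items()
            }
        return cls(**data)


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML (or JSON) file."""
    with open(path) as handle:
        return SimulationConfig.from_dict(yaml.safe_load(handle))


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=False)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _truncated_mixture(rng: np.random.Generator, mix: AgeMixture, n: int) -> np.ndarray:
    component = rng.choice(len(mix.weights), size=n, p=np.asarray(mix.weights))
    ages = rng.normal(np.asarray(mix.means)[component], np.asarray(mix.sds)[component])
    out_of_bounds = (ages < mix.min_age) | (ages > mix.max_age)
    while out_of_bounds.any():
        k = int(out_of_bounds.sum())
        comp = rng.choice(len(mix.weights), size=k, p=np.asarray(mix.weights))
        ages[out_of_bounds] = rng.normal(
            np.asarray(mix.means)[comp], np.asarray(mix.sds)[comp]
        )
        out_of_bounds = (ages < mix.min_age) | (ages > mix.max_age)
    return np.floor(ages).astype(np.int64)


def _clip(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(values, lo, hi)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a synthetic cohort as a frame with the canonical CSV schema.

    Identical configs (including seed) produce bit-identical frames. Use
    :func:`icu_intensity.records.frame_to_records` for the typed view.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_stays
    if n == 0:
        return normalize_frame(
            pd.DataFrame({col: pd.Series(dtype=object) for col in COHORT_COLUMNS})
        )

    age = _truncated_mixture(rng, config.age_distribution, n)

    age_coef = float(config.latent_severity_model.get("age_coef", 0.15))
    loading = float(config.latent_severity_model.get("field_loading", 0.7))
    severity = age_coef * (age - 58.0) / 18.0 + rng.normal(size=n)

    def deform(scale_noise: float = 1.0) -> np.ndarray:
        # per-field latent: shares `loading` of the severity signal
        return loading * severity + math.sqrt(max(0.0, 1 - loading**2)) * rng.normal(
            size=n
        ) * scale_noise

    frame = pd.DataFrame(index=np.arange(n))
    frame["stay_id"] = np.array([f"stay-{i:07d}" for i in range(n)], dtype=object)
    frame["age"] = age
    frame["sex"] = np.where(rng.random(n) < 0.595, "male", "female").astype(object)
    frame["n_icu_stays_in_hospital_stay"] = np.where(
        rng.random(n) < config.frac_multiple_icu_stays, rng.integers(2, 5, size=n), 1
    ).astype(np.int64)
    frame["icu_type"] = np.where(
        rng.random(n) < config.frac_other_icu, "other", "medical"
    ).astype(object)

    # physiology: monotone deformations of the severity latent plus noise;
    # scales calibrated so the included cohort's age-adjusted SAPS II has
    # mean ≈ 40 and SD ≈ 20 (a severe adult medical-ICU case mix)
    frame["heart_rate"] = _clip(np.round(96 + 36 * deform(), 0), 30, 220)
    frame["systolic_bp"] = _clip(np.round(112 - 38 * deform(), 0), 40, 260)
    frame["temperature"] = _clip(np.round(37.2 + 1.3 * deform(), 1), 30, 42)
    frame["urine_output"] = _clip(np.round(1.4 - 1.2 * deform(), 2), 0.0, 6.0)
    frame["serum_urea"] = _clip(np.round(13 + 16 * deform(), 1), 1.0, 80.0)
    frame["wbc"] = _clip(np.round(11 + 9 * deform(), 1), 0.2, 80.0)
    frame["potassium"] = _clip(np.round(4.1 + 0.95 * deform(), 1), 1.5, 9.0)
    frame["sodium"] = _clip(np.round(138 + 7.0 * rng.normal(size=n), 0), 110, 175)
    frame["bicarbonate"] = _clip(np.round(20 - 8 * deform(), 1), 4.0, 45.0)
    frame["bilirubin"] = _clip(np.round(np.exp(3.1 + 1.4 * deform()), 0), 1.0, 700.0)
    frame["gcs"] = _clip(
        np.round(15 - 8.0 * np.maximum(deform(), 0.0), 0), 3, 15
    ).astype(np.float64)
    frame["chronic_disease"] = rng.choice(
        np.array(["none", "metastatic_cancer", "hematologic_malignancy", "aids"],
                 dtype=object),
        size=n,
        p=[0.82, 0.08, 0.07, 0.03],
    )
    frame["admission_type"] = rng.choice(
        np.array(["medical", "unscheduled_surgical", "scheduled_surgical"],
                 dtype=object),
        size=n,
        p=[0.85, 0.10, 0.05],
    )

    # organ-support allocation, logistic in the severity latent
    alloc = config.support_allocation
    invasive = rng.random(n) < _sigmoid(
        alloc["invasive_mv"][0] + alloc["invasive_mv"][1] * severity
    )
    niv = rng.random(n) < _sigmoid(alloc["niv"][0] + alloc["niv"][1] * severity)
    cat_any = rng.random(n) < _sigmoid(
        alloc["catecholamine"][0] + alloc["catecholamine"][1] * severity
    )
    rrt = rng.random(n) < _sigmoid(alloc["rrt"][0] + alloc["rrt"][1] * severity)

    agent = np.full(n, "none", dtype=object)
    agent_draw = rng.choice(
        np.array(["dobutamine", "dopamine", "norepinephrine", "epinephrine"],
                 dtype=object),
        size=n,
        p=[0.20, 0.15, 0.55, 0.10],
    )
    agent[cat_any] = agent_draw[cat_any]

    # doses/settings straddle (and occasionally hit exactly) each threshold
    dose = np.round(rng.uniform(2.0, 14.0, size=n), 1)
    dose[rng.random(n) < 0.05] = 8.0
    dose = np.where(np.isin(agent, ("dobutamine", "dopamine")), dose, np.nan)

    fio2 = np.round(rng.uniform(0.25, 1.0, size=n), 2)
    fio2[rng.random(n) < 0.05] = 0.6
    peep = rng.integers(0, 15, size=n).astype(np.float64)
    fio2 = np.where(invasive, fio2, np.nan)
    peep = np.where(invasive, peep, np.nan)

    ventilated = invasive | niv
    pao2_fio2 = _clip(np.round(230 - 110 * deform(), 0), 40.0, 600.0)
    pao2_fio2 = np.where(ventilated, pao2_fio2, np.nan)
    frame["pao2_fio2"] = pao2_fio2

    frame["catecholamine"] = agent
    frame["catecholamine_max_dose"] = dose
    frame["niv"] = niv
    frame["invasive_mv"] = invasive
    frame["mv_max_fio2"] = fio2
    frame["mv_max_peep"] = peep
    frame["rrt"] = rrt

    # stratum assignment uses the same scoring/classification as the analysis
    frame["hospital_death"] = False  # placeholder; drawn below
    frame = frame[list(COHORT_COLUMNS)]
    p_death = true_death_probability(frame, config)
    frame["hospital_death"] = rng.random(n) < p_death

    # finally, null out physiology for the unknown-SAPS2 fraction
    unknown = rng.random(n) < config.frac_unknown_saps2
    frame.loc[unknown, list(PHYSIOLOGY_COLUMNS)] = np.nan

    return normalize_frame(frame.reset_index(drop=True))


def true_death_probability(
    frame: pd.DataFrame, config: SimulationConfig
) -> np.ndarray:
    """Exact per-stay death probability min(1, m_stratum · p_SAPS2).

    Recomputable from any cohort frame with known physiology; this is the
    generator's ground truth used by parameter-recovery tests.
    """
    work = age_band_frame(classify_frame(score_frame(frame)))
    keys = work["age_band"].astype(str) + ":" + work["intensity_group"].astype(str)
    multipliers = keys.map(config.mortality_multipliers).to_numpy(dtype=np.float64)
    predicted = work["predicted_mortality"].to_numpy(dtype=np.float64)
    return np.minimum(1.0, multipliers * predicted)
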