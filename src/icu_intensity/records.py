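"""Core record types and the flat cohort-table schema.

One row of the cohort table = one hospital stay with a single set of
stay-level summaries: demographics, the physiologic values used for
severity scoring (already the scoreable worst-in-first-24h values), the
organ-support procedure summaries, and hospital vital status.

The canonical in-memory container for a cohort is a :class:`pandas.DataFrame`
with columns :data:`COHORT_COLUMNS`; the dataclasses here give a typed
per-record view used for single-record operations and for validation.
A stay with unknown severity data is represented by *all* physiology
columns empty (``physiology is None`` on the record).
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd

SEXES = ("male", "female")
ICU_TYPES = ("medical", "other")
CHRONIC_DISEASES = ("none", "metastatic_cancer", "hematologic_malignancy", "aids")
ADMISSION_TYPES = ("scheduled_surgical", "medical", "unscheduled_surgical")
CATECHOLAMINES = ("none", "dobutamine", "dopamine", "epinephrine", "norepinephrine")

#: catecholamines whose intensity level depends on the infused dose
DOSE_DEPENDENT_CATECHOLAMINES = ("dobutamine", "dopamine")

MIN_AGE = 16

#: physiologic plausibility bounds (inclusive) enforced on generation and on read
PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (MIN_AGE, 120),
    "heart_rate": (0.0, 300.0),
    "systolic_bp": (0.0, 300.0),
    "temperature": (25.0, 45.0),
    "pao2_fio2": (20.0, 700.0),
    "urine_output": (0.0, 20.0),
    "serum_urea": (0.0, 150.0),
    "wbc": (0.0, 200.0),
    "potassium": (0.5, 12.0),
    "sodium": (90.0, 200.0),
    "bicarbonate": (1.0, 60.0),
    "bilirubin": (0.0, 1000.0),
    "gcs": (3, 15),
    "catecholamine_max_dose": (0.0, 100.0),
    "mv_max_fio2": (0.21, 1.0),
    "mv_max_peep": (0.0, 30.0),
}

PHYSIOLOGY_NUMERIC_COLUMNS = (
    "heart_rate",
    "systolic_bp",
    "temperature",
    "pao2_fio2",
    "urine_output",
    "serum_urea",
    "wbc",
    "potassium",
    "sodium",
    "bicarbonate",
    "bilirubin",
    "gcs",
)
PHYSIOLOGY_CATEGORICAL_COLUMNS = ("chronic_disease", "admission_type")
PHYSIOLOGY_COLUMNS = PHYSIOLOGY_NUMERIC_COLUMNS + PHYSIOLOGY_CATEGORICAL_COLUMNS

SUPPORT_COLUMNS = (
    "catecholamine",
    "catecholamine_max_dose",
    "niv",
    "invasive_mv",
    "mv_max_fio2",
    "mv_max_peep",
    "rrt",
)

COHORT_COLUMNS = (
    "stay_id",
    "age",
    "sex",
    "n_icu_stays_in_hospital_stay",
    "icu_type",
    *PHYSIOLOGY_COLUMNS,
    *SUPPORT_COLUMNS,
    "hospital_death",
)

BOOL_COLUMNS = ("niv", "invasive_mv", "rrt", "hospital_death")
INT_COLUMNS = ("age", "n_icu_stays_in_hospital_stay")


class CohortValidationError(ValueError):
    """A cohort table or record violates the declared schema or invariants."""


@dataclass(frozen=True)
class Physiology:
    """Scoreable physiologic values of one stay (worst of first 24 h).

    ``pao2_fio2`` is defined only for stays on mechanical ventilation or
    CPAP; ``None`` otherwise.
    """

    heart_rate: float
    systolic_bp: float
    temperature: float
    urine_output: float
    serum_urea: float
    wbc: float
    potassium: float
    sodium: float
    bicarbonate: float
    bilirubin: float
    gcs: int
    chronic_disease: str
    admission_type: str
    pao2_fio2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in PHYSIOLOGY_NUMERIC_COLUMNS:
            value = getattr(self, name)
            if value is None:
                if name == "pao2_fio2":
                    continue
                raise CohortValidationError(f"physiology field {name!r} may not be null")
            lo, hi = PLAUSIBILITY_BOUNDS[name]
            if not (lo <= value <= hi):
                raise CohortValidationError(
                    f"{name}={value!r} outside plausibility bounds [{lo}, {hi}]"
                )
        if int(self.gcs) != self.gcs:
            raise CohortValidationError(f"gcs must be an integer, got {self.gcs!r}")
        if self.chronic_disease not in CHRONIC_DISEASES:
            raise CohortValidationError(
                f"chronic_disease={self.chronic_disease!r} not in {CHRONIC_DISEASES}"
            )
        if self.admission_type not in ADMISSION_TYPES:
            raise CohortValidationError(
                f"admission_type={self.admission_type!r} not in {ADMISSION_TYPES}"
            )


@dataclass(frozen=True)
class SupportEvents:
    """Stay-level organ-support procedure summary.

    Invariants: ventilator settings are present iff the stay had invasive
    mechanical ventilation; a catecholamine dose is present iff the agent
    is dose-dependent (dobutamine or dopamine).
    """

    catecholamine: str = "none"
    catecholamine_max_dose: Optional[float] = None
    niv: bool = False
    invasive_mv: bool = False
    mv_max_fio2: Optional[float] = None
    mv_max_peep: Optional[float] = None
    rrt: bool = False

    def __post_init__(self) -> None:
        if self.catecholamine not in CATECHOLAMINES:
            raise CohortValidationError(
                f"catecholamine={self.catecholamine!r} not in {CATECHOLAMINES}"
            )
        dose_needed = self.catecholamine in DOSE_DEPENDENT_CATECHOLAMINES
        if dose_needed != (self.catecholamine_max_dose is not None):
            raise CohortValidationError(
                "catecholamine_max_dose must be present iff the agent is "
                f"dobutamine/dopamine (agent={self.catecholamine!r}, "
                f"dose={self.catecholamine_max_dose!r})"
            )
        settings_present = self.mv_max_fio2 is not None and self.mv_max_peep is not None
        if self.invasive_mv != settings_present or (
            (self.mv_max_fio2 is None) != (self.mv_max_peep is None)
        ):
            raise CohortValidationError(
                "mv_max_fio2/mv_max_peep must both be present iff invasive_mv is true"
            )
        for name in ("catecholamine_max_dose", "mv_max_fio2", "mv_max_peep"):
            value = getattr(self, name)
            if value is not None:
                lo, hi = PLAUSIBILITY_BOUNDS[name]
                if not (lo <= value <= hi):
                    raise CohortValidationError(
                        f"{name}={value!r} outside plausibility bounds [{lo}, {hi}]"
                    )


@dataclass(frozen=True)
class StayRecord:
    """One hospital stay. ``physiology is None`` models unknown severity data."""

    stay_id: str
    age: int
    sex: str
    n_icu_stays_in_hospital_stay: int
    icu_type: str
    physiology: Optional[Physiology]
    supports: SupportEvents
    hospital_death: bool

    def __post_init__(self) -> None:
        if self.age < MIN_AGE:
            raise CohortValidationError(f"age={self.age} < {MIN_AGE}")
        if self.age > PLAUSIBILITY_BOUNDS["age"][1]:
            raise CohortValidationError(f"age={self.age} implausible")
        if self.n_icu_stays_in_hospital_stay < 1:
            raise CohortValidationError(
                f"n_icu_stays_in_hospital_stay={self.n_icu_stays_in_hospital_stay} < 1"
            )
        if self.sex not in SEXES:
            raise CohortValidationError(f"sex={self.sex!r} not in {SEXES}")
        if self.icu_type not in ICU_TYPES:
            raise CohortValidationError(f"icu_type={self.icu_type!r} not in {ICU_TYPES}")

    @property
    def saps2_unknown(self) -> bool:
        return self.physiology is None


def record_to_row(record: StayRecord) -> dict:
    """Flatten one :class:`StayRecord` into a cohort-table row dict."""
    row: dict = {
        "stay_id": record.stay_id,
        "age": record.age,
        "sex": record.sex,
        "n_icu_stays_in_hospital_stay": record.n_icu_stays_in_hospital_stay,
        "icu_type": record.icu_type,
        "hospital_death": record.hospital_death,
    }
    if record.physiology is None:
        for col in PHYSIOLOGY_COLUMNS:
            row[col] = None
    else:
        for f in dc_fields(Physiology):
            row[f.name] = getattr(record.physiology, f.name)
    for f in dc_fields(SupportEvents):
        row[f.name] = getattr(record.supports, f.name)
    return row


def row_to_record(row: dict) -> StayRecord:
    """Build one validated :class:`StayRecord` from a cohort-table row."""

    def _missing(value) -> bool:
        return value is None or (isinstance(value, float) and np.isnan(value))

    phys_values = {col: row[col] for col in PHYSIOLOGY_COLUMNS}
    missing = [col for col, v in phys_values.items() if _missing(v)]
    if set(missing) - {"pao2_fio2"} == set(PHYSIOLOGY_COLUMNS) - {"pao2_fio2"}:
        physiology = None
    elif not set(missing) - {"pao2_fio2"}:
        physiology = Physiology(
            heart_rate=float(row["heart_rate"]),
            systolic_bp=float(row["systolic_bp"]),
            temperature=float(row["temperature"]),
            pao2_fio2=None if _missing(row["pao2_fio2"]) else float(row["pao2_fio2"]),
            urine_output=float(row["urine_output"]),
            serum_urea=float(row["serum_urea"]),
            wbc=float(row["wbc"]),
            potassium=float(row["potassium"]),
            sodium=float(row["sodium"]),
            bicarbonate=float(row["bicarbonate"]),
            bilirubin=float(row["bilirubin"]),
            gcs=int(row["gcs"]),
            chronic_disease=str(row["chronic_disease"]),
            admission_type=str(row["admission_type"]),
        )
    else:
        raise CohortValidationError(
            "physiology must be fully present or fully absent; "
            f"missing only {sorted(set(missing) - {'pao2_fio2'})}"
        )
    supports = SupportEvents(
        catecholamine=str(row["catecholamine"]),
        catecholamine_max_dose=(
            None
            if _missing(row["catecholamine_max_dose"])
            else float(row["catecholamine_max_dose"])
        ),
        niv=bool(row["niv"]),
        invasive_mv=bool(row["invasive_mv"]),
        mv_max_fio2=None if _missing(row["mv_max_fio2"]) else float(row["mv_max_fio2"]),
        mv_max_peep=None if _missing(row["mv_max_peep"]) else float(row["mv_max_peep"]),
        rrt=bool(row["rrt"]),
    )
    return StayRecord(
        stay_id=str(row["stay_id"]),
        age=int(row["age"]),
        sex=str(row["sex"]),
        n_icu_stays_in_hospital_stay=int(row["n_icu_stays_in_hospital_stay"]),
        icu_type=str(row["icu_type"]),
        physiology=physiology,
        supports=supports,
        hospital_death=bool(row["hospital_death"]),
    )


def records_to_frame(records) -> pd.DataFrame:
    """Collection of StayRecord -> cohort DataFrame (column order fixed)."""
    rows = [record_to_row(r) for r in records]
    frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return normalize_frame(frame)


def frame_to_records(frame: pd.DataFrame) -> list[StayRecord]:
    """Cohort DataFrame -> list of validated StayRecord, preserving order."""
    return [row_to_record(row) for row in frame.to_dict(orient="records")]


def normalize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Coerce a cohort frame to the canonical dtypes (float64/bool/int64/object)."""
    frame = frame.copy()
    for col in INT_COLUMNS:
        frame[col] = frame[col].astype(np.int64)
    for col in BOOL_COLUMNS:
        frame[col] = frame[col].astype(bool)
    for col in PHYSIOLOGY_NUMERIC_COLUMNS + (
        "catecholamine_max_dose",
        "mv_max_fio2",
        "mv_max_peep",
    ):
        frame[col] = frame[col].astype(np.float64)
    for col in ("stay_id", "sex", "icu_type", "catecholamine") + PHYSIOLOGY_CATEGORICAL_COLUMNS:
        frame[col] = frame[col].astype(object)
    return frame


def saps2_unknown_mask(frame: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows whose severity data is unknown (null physiology)."""
    core = [c for c in PHYSIOLOGY_COLUMNS if c != "pao2_fio2"]
    return frame[core].isna().all(axis=1)


def validate_frame(frame: pd.DataFrame) -> None:
    """Validate schema, bounds and cross-field invariants of a cohort frame.

    Raises :class:`CohortValidationError` naming the offending column and the
    first offending row (0-based data row index).
    """
    unknown_cols = [c for c in frame.columns if c not in COHORT_COLUMNS]
    missing_cols = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if unknown_cols or missing_cols:
        raise CohortValidationError(
            f"unknown columns {unknown_cols}, missing columns {missing_cols}; "
            f"accepted schema: {list(COHORT_COLUMNS)}"
        )

    def _fail(mask: pd.Series, message: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise CohortValidationError(f"row {row}: {message}")

    unknown = saps2_unknown_mask(frame)
    core = [c for c in PHYSIOLOGY_COLUMNS if c != "pao2_fio2"]
    partially = frame[core].isna().any(axis=1) & ~unknown
    _fail(partially, "physiology must be fully present or fully absent")

    for col in ("age", "heart_rate", "systolic_bp", "temperature", "pao2_fio2",
                "urine_output", "serum_urea", "wbc", "potassium", "sodium",
                "bicarbonate", "bilirubin", "gcs", "catecholamine_max_dose",
                "mv_max_fio2", "mv_max_peep"):
        lo, hi = PLAUSIBILITY_BOUNDS[col]
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.notna() & ((values < lo) | (values > hi))
        _fail(bad, f"{col} outside plausibility bounds [{lo}, {hi}]")

    _fail(frame["n_icu_stays_in_hospital_stay"] < 1, "n_icu_stays_in_hospital_stay < 1")
    for col, allowed in (
        ("sex", SEXES),
        ("icu_type", ICU_TYPES),
        ("catecholamine", CATECHOLAMINES),
    ):
        _fail(~frame[col].isin(allowed), f"{col} not in {allowed}")
    for col, allowed in (
        ("chronic_disease", CHRONIC_DISEASES),
        ("admission_type", ADMISSION_TYPES),
    ):
        _fail(frame[col].notna() & ~frame[col].isin(allowed), f"{col} not in {allowed}")

    dose_dependent = frame["catecholamine"].isin(DOSE_DEPENDENT_CATECHOLAMINES)
    _fail(
        dose_dependent != frame["catecholamine_max_dose"].notna(),
        "catecholamine_max_dose present iff agent is dobutamine/dopamine",
    )
    settings = frame["mv_max_fio2"].notna() & frame["mv_max_peep"].notna()
    either = frame["mv_max_fio2"].notna() | frame["mv_max_peep"].notna()
    _fail(
        (frame["invasive_mv"] != settings) | (either & ~settings),
        "mv_max_fio2/mv_max_peep present iff invasive_mv",
    )
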