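"""Cohort CSV reading and writing.

Fixed dialect: header row with the canonical column names, UTF-8, "."
decimal separator, empty cell = null. ``read_cohort(write_cohort(x)) ``
is field-for-field identical to ``x`` (float64 values round-trip through
their shortest repr).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import (
    BOOL_COLUMNS,
    COHORT_COLUMNS,
    CohortValidationError,
    normalize_frame,
    validate_frame,
)

__all__ = ["read_cohort", "write_cohort"]


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort frame to CSV in the fixed dialect."""
    validate_frame(frame)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; returns the canonical frame.

    Raises :class:`CohortValidationError` on unknown columns, malformed
    values (with the 0-based data row number) or invariant violations.
    """
    raw = pd.read_csv(path, dtype=object, keep_default_na=False, encoding="utf-8")
    unknown = [c for c in raw.columns if c not in COHORT_COLUMNS]
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if unknown or missing:
        raise CohortValidationError(
            f"unknown columns {unknown}, missing columns {missing}; "
            f"accepted schema: {list(COHORT_COLUMNS)}"
        )
    frame = pd.DataFrame(index=raw.index)
    for col in COHORT_COLUMNS:
        values = raw[col].replace("", None)
        if col in ("stay_id", "sex", "icu_type", "catecholamine", "chronic_disease",
                   "admission_type"):
            frame[col] = values.astype(object)
        elif col in BOOL_COLUMNS:
            mapped = values.map({"True": True, "False": False})
            bad = mapped.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"row {row}: column {col!r} must be 'True' or 'False', "
                    f"got {values.iloc[row]!r}"
                )
            frame[col] = mapped.astype(bool)
        else:
            numeric = pd.to_numeric(values, errors="coerce")
            bad = numeric.isna() & values.notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"row {row}: column {col!r} is not numeric: {values.iloc[row]!r}"
                )
            if col in ("age", "n_icu_stays_in_hospital_stay"):
                if numeric.isna().any():
                    row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
                    raise CohortValidationError(f"row {row}: column {col!r} is required")
                frame[col] = numeric.astype(np.int64)
            else:
                frame[col] = numeric.astype(np.float64)
    validate_frame(frame)
    return normalize_frame(frame)
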