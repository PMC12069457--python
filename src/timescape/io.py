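"""Schema-checked CSV round-tripping for cell, clinical and result tables.

All tables are plain CSV. Writers use a fixed float format (6 significant
digits) and a stable row order so identical inputs produce byte-identical
files; readers validate the documented schemas and report the offending
column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_cells",
    "write_cells",
    "read_clinical",
    "write_clinical",
    "read_results",
    "write_results",
]

FLOAT_FORMAT = "%.6g"

CELL_REQUIRED = ["sample_id", "patient_id", "x_um", "y_um"]
CLINICAL_REQUIRED = ["patient_id", "time_months", "event"]


class SchemaError(ValueError):
    """A table violates its documented schema."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing required column(s): {', '.join(missing)}")


def read_cells(path) -> pd.DataFrame:
    """Read a per-cell table (sample_id, patient_id, x_um, y_um, markers...)."""
    df = pd.read_csv(path)
    _require_columns(df, CELL_REQUIRED, "cells")
    for col in ("x_um", "y_um"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"cells column {col!r} must be numeric")
        if df[col].isna().any():
            bad = int(df[col].isna().idxmax())
            raise SchemaError(f"cells column {col!r} has missing value at row {bad}")
    return df


def write_cells(df: pd.DataFrame, path) -> None:
    _require_columns(df, CELL_REQUIRED, "cells")
    out = df.sort_values(["sample_id", "x_um", "y_um"], kind="mergesort")
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_clinical(path) -> pd.DataFrame:
    """Read a per-patient clinical table (patient_id, time_months, event, ...)."""
    df = pd.read_csv(path)
    _require_columns(df, CLINICAL_REQUIRED, "clinical")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise SchemaError(f"clinical table has duplicate patient_id {dup!r}")
    if not set(pd.unique(df["event"])) <= {0, 1}:
        raise SchemaError("clinical column 'event' must contain only 0/1")
    if (df["time_months"] <= 0).any():
        bad = int((df["time_months"] <= 0).idxmax())
        raise SchemaError(f"clinical column 'time_months' must be > 0 (row {bad})")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    _require_columns(df, CLINICAL_REQUIRED, "clinical")
    out = df.sort_values("patient_id", kind="mergesort")
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_results(df: pd.DataFrame, path, sort_by: list[str] | None = None) -> None:
    out = df
    if sort_by:
        out = df.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)
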