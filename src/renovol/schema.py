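"""Patient-record CSV schema: column contract, validation, round-trip I/O.

The on-disk format is plain CSV (comma separator, UTF-8, "." decimal).
Lengths are centimeters, volumes cm³, eGFR mL/min/1.73 m², creatinine
mg/dL.  Unknown columns are preserved with a warning; known columns are
checked cell by cell and every violation is reported before aborting.
Floats are serialized with repr-faithful precision so write → read
round-trips are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ColumnSpec",
    "SchemaError",
    "PATIENT_COLUMNS",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    unit: str
    required: bool = False
    min: float | None = None
    max: float | None = None
    min_exclusive: bool = False
    allowed: tuple[str, ...] | None = None


#: Known patient-record columns, their units and per-cell constraints.
PATIENT_COLUMNS: tuple[ColumnSpec, ...] = (
    ColumnSpec("patient_id", ""),
    ColumnSpec("age", "years", required=True, min=0, min_exclusive=True),
    ColumnSpec("sex", "", required=True, allowed=("M", "F", "male", "female")),
    ColumnSpec("tumor_diameter_cm", "cm", min=0, min_exclusive=True),
    ColumnSpec("invasion_depth_cm", "cm", min=0),
    ColumnSpec("kidney_length_cm", "cm", min=0, min_exclusive=True),
    ColumnSpec("kidney_width_cm", "cm", min=0, min_exclusive=True),
    ColumnSpec("kidney_height_cm", "cm", min=0, min_exclusive=True),
    ColumnSpec("margin_cm", "cm", min=0),
    ColumnSpec("offset_x_cm", "cm"),
    ColumnSpec("offset_y_cm", "cm"),
    ColumnSpec("offset_z_cm", "cm"),
    ColumnSpec("preop_scr", "mg/dL", min=0, min_exclusive=True),
    ColumnSpec("preop_egfr", "mL/min/1.73m2", min=0, min_exclusive=True),
    ColumnSpec("nadir_egfr", "mL/min/1.73m2", min=0, min_exclusive=True),
    ColumnSpec("pct_reduction", "%"),
    ColumnSpec("cold_ischemia_min", "min", min=0),
    ColumnSpec("blood_loss_ml", "mL", min=0),
    ColumnSpec("renal_score", "", min=4, max=12),
    ColumnSpec("padua_score", "", min=6, max=13),
    ColumnSpec("cindex", "", min=0),
    ColumnSpec("raiv", "cm3", min=0),
    ColumnSpec("praiv", "%", min=0, max=100),
    ColumnSpec("black_race", ""),
)

_KNOWN = {c.name: c for c in PATIENT_COLUMNS}


class SchemaError(ValueError):
    """Validation failure; ``errors`` lists every bad cell as (row, column, message)."""

    def __init__(self, errors: list[tuple[object, str, str]]):
        self.errors = errors
        lines = [f"  row {r}, column {c}: {m}" for r, c, m in errors]
        super().__init__("cohort CSV failed validation:\n" + "\n".join(lines))


def validate_cohort(
    table: pd.DataFrame, required: tuple[str, ...] | None = None
) -> list[tuple[object, str, str]]:
    """Check a cohort table against the patient-record schema.

    Returns the list of cell-level violations and raises :class:`SchemaError`
    if any exist.  ``required`` overrides the default required-column set.
    Unknown columns only produce a warning.
    """
    errors: list[tuple[object, str, str]] = []
    if required is None:
        required = tuple(c.name for c in PATIENT_COLUMNS if c.required)
    for name in required:
        if name not in table.columns:
            errors.append(("-", name, "required column missing"))
    unknown = [c for c in table.columns if c not in _KNOWN]
    if unknown:
        logger.warning("unknown columns preserved untouched: %s", ", ".join(unknown))

    for name in table.columns:
        spec = _KNOWN.get(name)
        if spec is None:
            continue
        col = table[name]
        if spec.allowed is not None:
            bad = ~col.astype(str).isin(spec.allowed) & col.notna()
            for idx in table.index[bad]:
                errors.append(
                    (idx, name, f"value {col[idx]!r} not in {spec.allowed}")
                )
            continue
        if spec.min is None and spec.max is None:
            continue
        numeric = pd.to_numeric(col, errors="coerce")
        not_num = numeric.isna() & col.notna()
        for idx in table.index[not_num]:
            errors.append((idx, name, f"value {col[idx]!r} is not numeric"))
        if spec.min is not None:
            bad = (numeric <= spec.min) if spec.min_exclusive else (numeric < spec.min)
            for idx in table.index[bad.fillna(False)]:
                op = ">" if spec.min_exclusive else ">="
                errors.append((idx, name, f"value {numeric[idx]} must be {op} {spec.min}"))
        if spec.max is not None:
            for idx in table.index[(numeric > spec.max).fillna(False)]:
                errors.append((idx, name, f"value {numeric[idx]} must be <= {spec.max}"))
    if errors:
        raise SchemaError(errors)
    return errors


def read_cohort(
    path: str | Path, validate: bool = True, required: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Read a patient-record CSV, optionally validating it."""
    table = pd.read_csv(path, float_precision="round_trip")
    if validate:
        validate_cohort(table, required=required)
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV with repr-faithful float precision (exact round-trip)."""
    out = table.copy()
    for name in out.columns:
        if np.issubdtype(out[name].dtype, np.floating):
            out[name] = out[name].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)
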