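"""Read/write cohort tables, prediction tables, constants and reports.

CSV dialect is fixed: comma separator, ``.`` decimal, UTF-8, mandatory
header. A missing observed refraction is an empty ``postop_se`` cell.
Constants files are JSON keyed by lens model:
``{"YP2.2": {"A": 119.2, "SF": 1.93, "pACD": 5.792, "a0": -1.72, "a1": 0.277, "a2": 0.26}}``
with each formula's constant independently optional.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .records import COHORT_COLUMNS, Cohort, check_cohort, validate_record

PREDICTION_COLUMNS = ["eye_id", "method", "predicted_se", "error"]
CONSTANT_KEYS = ("A", "SF", "pACD", "a0", "a1", "a2")

NUMERIC_COLUMNS = [
    "age",
    "axial_length",
    "corneal_radius",
    "acd",
    "lens_thickness",
    "wtw",
    "iol_power",
    "postop_se",
]


class SchemaError(ValueError):
    """CSV header does not match the fixed cohort schema."""


class CohortValidationError(ValueError):
    """One or more rows violate record invariants."""


def read_cohort(path: str | Path, strict: bool = True) -> Cohort:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` naming any missing column, ``ValueError``
    with the row number for non-numeric cells, and
    :class:`CohortValidationError` listing offending fields when a row
    breaks a biometry bound (unless ``strict=False``, which keeps the
    offending rows and leaves validation to the caller).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cohort file {path} missing column(s): {', '.join(missing)}")
    frame = frame[COHORT_COLUMNS]

    for col in NUMERIC_COLUMNS:
        raw = frame[col].str.strip()
        blank = raw == ""
        if col != "postop_se" and blank.any():
            row = int(np.flatnonzero(blank.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: empty cell in required column {col!r} at line {row}")
        parsed = pd.to_numeric(raw.where(~blank, None), errors="coerce")
        bad = (~blank) & parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column {col!r} at line {row}"
            )
        frame[col] = parsed

    cohort = Cohort.from_frame(frame, provenance=str(path))
    check_cohort(cohort.records)
    if strict:
        problems = []
        for i, rec in enumerate(cohort.records):
            for v in validate_record(rec):
                problems.append(f"row {i + 2} ({rec.eye_id}): {v.field}={v.value} outside {v.bound}")
        if problems:
            raise CohortValidationError(f"{path}: " + "; ".join(problems))
    return cohort


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV in the fixed dialect (empty cell for missing postop_se)."""
    frame = cohort.to_frame()
    frame.to_csv(path, index=False, encoding="utf-8", na_rep="")


def read_predictions(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"predictions file {path} missing column(s): {', '.join(missing)}")
    return frame[PREDICTION_COLUMNS]


def write_predictions(frame: pd.DataFrame, path: str | Path) -> None:
    frame[PREDICTION_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_constants(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a per-lens-model constants JSON; unknown keys rejected."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    out: dict[str, dict[str, float]] = {}
    for model, entry in raw.items():
        bad = [k for k in entry if k not in CONSTANT_KEYS]
        if bad:
            raise ValueError(f"constants for {model!r}: unknown key(s) {bad}")
        out[model] = {k: float(v) for k, v in entry.items()}
    return out


def write_constants(constants: Mapping[str, Mapping[str, float]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({m: dict(e) for m, e in constants.items()}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report(report: Mapping, path: str | Path) -> None:
    """Serialize an evaluation report to JSON (numpy scalars coerced)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=default)
        fh.write("\n")
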