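"""Domain records: per-eye biometry, cohorts, and validation.

A :class:`BiometryRecord` holds one eye's preoperative measurements
(axial length, mean corneal radius, anterior chamber depth, lens
thickness, white-to-white), the implanted lens model and power, and the
observed postoperative subjective spherical equivalent (absent for
prediction-only records). All lengths are millimetres, powers and
refractions diopters, age years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, NamedTuple, Optional

import pandas as pd

#: Hard physiologic bounds per field: value must lie strictly inside (lo, hi).
BOUNDS: dict[str, tuple[float, float]] = {
    "axial_length": (15.0, 40.0),
    "corneal_radius": (5.5, 11.0),
    "acd": (1.0, 6.0),
    "lens_thickness": (2.0, 7.5),
    "wtw": (8.0, 14.0),
    "iol_power": (-10.0, 45.0),
}

LATERALITIES = ("left", "right")

#: Fixed CSV column order for cohort files.
COHORT_COLUMNS = [
    "patient_id",
    "eye_id",
    "laterality",
    "age",
    "axial_length",
    "corneal_radius",
    "acd",
    "lens_thickness",
    "wtw",
    "iol_model",
    "iol_power",
    "postop_se",
]


class Violation(NamedTuple):
    """One invariant violation: which field, its value, and the allowed bound."""

    field: str
    value: object
    bound: str


@dataclass
class BiometryRecord:
    patient_id: str
    eye_id: str
    laterality: str
    age: float
    axial_length: float
    corneal_radius: float
    acd: float
    lens_thickness: float
    wtw: float
    iol_model: str
    iol_power: float
    postop_se: Optional[float] = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def validate_record(rec: BiometryRecord) -> list[Violation]:
    """Return every invariant violation of ``rec``; empty list iff valid.

    Total: never raises on bad values, including NaN (NaN fails every
    open-interval check and is reported as out of bounds).
    """
    out: list[Violation] = []
    for name, (lo, hi) in BOUNDS.items():
        v = getattr(rec, name)
        try:
            ok = lo < float(v) < hi
        except (TypeError, ValueError):
            ok = False
        if not ok:
            out.append(Violation(name, v, f"({lo}, {hi})"))
    if rec.laterality not in LATERALITIES:
        out.append(Violation("laterality", rec.laterality, "{left, right}"))
    try:
        if not (0.0 <= float(rec.age) < 130.0):
            out.append(Violation("age", rec.age, "[0, 130)"))
    except (TypeError, ValueError):
        out.append(Violation("age", rec.age, "[0, 130)"))
    if rec.postop_se is not None and not math.isfinite(float(rec.postop_se)):
        out.append(Violation("postop_se", rec.postop_se, "finite or absent"))
    return out


@dataclass
class Cohort:
    """Ordered collection of validated eyes, with free-text provenance."""

    records: list[BiometryRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BiometryRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame in the fixed column order (postop_se NaN if absent)."""
        rows = []
        for r in self.records:
            d = r.as_dict()
            if d["postop_se"] is None:
                d["postop_se"] = float("nan")
            rows.append(d)
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "Cohort":
        recs = []
        for _, row in frame.iterrows():
            se = row["postop_se"]
            recs.append(
                BiometryRecord(
                    patient_id=str(row["patient_id"]),
                    eye_id=str(row["eye_id"]),
                    laterality=str(row["laterality"]),
                    age=float(row["age"]),
                    axial_length=float(row["axial_length"]),
                    corneal_radius=float(row["corneal_radius"]),
                    acd=float(row["acd"]),
                    lens_thickness=float(row["lens_thickness"]),
                    wtw=float(row["wtw"]),
                    iol_model=str(row["iol_model"]),
                    iol_power=float(row["iol_power"]),
                    postop_se=None if pd.isna(se) else float(se),
                )
            )
        return cls(records=recs, provenance=provenance)


def check_cohort(records: Iterable[BiometryRecord]) -> None:
    """Raise ``ValueError`` when (patient_id, eye_id) pairs collide."""
    seen = set()
    for r in records:
        key = (r.patient_id, r.eye_id)
        if key in seen:
            raise ValueError(f"duplicate (patient_id, eye_id): {key}")
        seen.add(key)
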