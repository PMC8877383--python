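"""The i-BIO integrated biomarker.

i-BIO is a 0-17 point composite for non-invasive assessment of coronary
atherosclerosis.  It sums seven components: sex (male = 1), a carotid
ultrasound composite (a 3-bit code over CIMT > 0.9 mm, plaque count >= 3 and
maximal carotid stenosis > 45%, worth 0-7), and banded triglycerides (0-2),
glucose (0-3), fibrinogen (0-1), hsCRP (0-2) and adiponectin (0-1, inverted:
*low* adiponectin scores).  Patients with a total above 4 are called positive
for the presence of coronary atherosclerosis; totals of 9 or more are called
positive for severe disease.

The full point table is shipped as one machine-readable definition file,
``data/ibio_definition.json``; every banding function below evaluates that
file, so the score is auditable and versionable in a single place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .cohort import IBIO_INPUT_FIELDS, PatientRecord, Sex

__all__ = [
    "IBIOInputs",
    "IBIOBreakdown",
    "DEFINITION",
    "PRESENCE_THRESHOLD",
    "SEVERITY_THRESHOLD",
    "MAX_TOTAL",
    "sex_points",
    "ultrasound_points",
    "tg_points",
    "glucose_points",
    "fibrinogen_points",
    "hscrp_points",
    "adiponectin_points",
    "ibio_total",
    "score_cohort",
]


def _load_definition() -> dict:
    text = (
        resources.files("ibioscore.data")
        .joinpath("ibio_definition.json")
        .read_text(encoding="utf-8")
    )
    return json.loads(text)


#: The machine-readable i-BIO point table (see module docstring).
DEFINITION = _load_definition()

PRESENCE_THRESHOLD: int = DEFINITION["thresholds"]["presence"]["threshold"]
SEVERITY_THRESHOLD: int = DEFINITION["thresholds"]["severity"]["threshold"]

_OPS = {
    ">": lambda x, t: x > t,
    ">=": lambda x, t: x >= t,
    "<": lambda x, t: x < t,
    "<=": lambda x, t: x <= t,
}


def _component_points(component: str, **values: float) -> int:
    spec = DEFINITION["components"][component]
    for name, v in values.items():
        if v is None:
            raise ValueError(f"missing i-BIO input: {name}")
        if name != "sex" and v < 0:
            raise ValueError(f"{name} must be non-negative, got {v!r}")
    if spec["kind"] == "categorical":
        key = values[spec["input"]]
        if isinstance(key, Sex):
            key = key.value
        return int(spec["points"][key])
    total = 0
    for cut in spec["cuts"]:
        if _OPS[cut["op"]](values[cut["input"]], cut["threshold"]):
            total += cut["points"]
    return total


def sex_points(sex: Sex | str) -> int:
    """0 for female, 1 for male."""
    return _component_points("sex", sex=Sex(sex))


def ultrasound_points(
    cimt_mm: float, plaque_count: int, carotid_stenosis_pct: float
) -> int:
    """Carotid ultrasound composite, 0-7.

    Binary encoding of the three abnormality criteria: CIMT > 0.9 mm adds 1,
    plaque count >= 3 adds 2, maximal carotid stenosis > 45% adds 4, so the
    value enumerates all eight criterion combinations.
    """
    if carotid_stenosis_pct is not None and not 0 <= carotid_stenosis_pct <= 100:
        raise ValueError(
            f"carotid_stenosis_pct must be in [0, 100], got {carotid_stenosis_pct!r}"
        )
    return _component_points(
        "ultrasound",
        cimt_mm=cimt_mm,
        plaque_count=plaque_count,
        carotid_stenosis_pct=carotid_stenosis_pct,
    )


def tg_points(tg: float) -> int:
    """Triglycerides (mmol/L): <1.7 -> 0; 1.7-<2.0 -> 1; >=2.0 -> 2."""
    return _component_points("tg", tg=tg)


def glucose_points(glucose: float) -> int:
    """Glucose (mmol/L): <=5.5 -> 0; >5.5-6.0 -> 1; >6.0-<7.0 -> 2; >=7.0 -> 3."""
    return _component_points("glucose", glucose=glucose)


def fibrinogen_points(fibrinogen: float) -> int:
    """Fibrinogen (g/L): <=4.0 -> 0; >4.0 -> 1."""
    return _component_points("fibrinogen", fibrinogen=fibrinogen)


def hscrp_points(hscrp: float) -> int:
    """hsCRP (mg/L): <1.0 -> 0; 1.0-<3.0 -> 1; >=3.0 -> 2."""
    return _component_points("hscrp", hscrp=hscrp)


def adiponectin_points(adiponectin: float) -> int:
    """Adiponectin (ug/mL): >=8.0 -> 0; <8.0 -> 1 (low values score)."""
    return _component_points("adiponectin", adiponectin=adiponectin)


@dataclass(frozen=True)
class IBIOInputs:
    """The seven measurements the i-BIO score consumes; all mandatory."""

    sex: Sex
    cimt_mm: float
    plaque_count: int
    carotid_stenosis_pct: float
    tg: float
    glucose: float
    fibrinogen: float
    hscrp: float
    adiponectin: float

    @classmethod
    def from_record(cls, record: PatientRecord) -> "IBIOInputs":
        missing = record.missing_ibio_fields()
        if missing:
            raise ValueError(
                f"patient {record.patient_id}: record not scoreable, "
                f"missing i-BIO inputs: {list(missing)}"
            )
        return cls(**{f: getattr(record, f) for f in IBIO_INPUT_FIELDS})


MAX_TOTAL = 17


@dataclass(frozen=True)
class IBIOBreakdown:
    """Per-component points, total, and the two threshold classifications."""

    sex_pts: int
    ultrasound_pts: int
    tg_pts: int
    glucose_pts: int
    fibrinogen_pts: int
    hscrp_pts: int
    adiponectin_pts: int

    @property
    def total(self) -> int:
        return (
            self.sex_pts
            + self.ultrasound_pts
            + self.tg_pts
            + self.glucose_pts
            + self.fibrinogen_pts
            + self.hscrp_pts
            + self.adiponectin_pts
        )

    @property
    def presence_positive(self) -> bool:
        """Positive call for any coronary atherosclerosis: total > 4."""
        return self.total > PRESENCE_THRESHOLD

    @property
    def severity_positive(self) -> bool:
        """Positive call for severe coronary atherosclerosis: total >= 9."""
        return self.total >= SEVERITY_THRESHOLD


def ibio_total(inputs: IBIOInputs | PatientRecord) -> IBIOBreakdown:
    """Score one patient.

    Accepts either explicit :class:`IBIOInputs` or a
    :class:`~ibioscore.cohort.PatientRecord`; a record with any i-BIO input
    missing raises (listing the missing fields) rather than silently scoring
    a partial total.
    """
    if isinstance(inputs, PatientRecord):
        inputs = IBIOInputs.from_record(inputs)
    missing = [
        f for f in IBIO_INPUT_FIELDS if getattr(inputs, f, None) is None
    ]
    if missing:
        raise ValueError(f"missing i-BIO inputs: {missing}")
    return IBIOBreakdown(
        sex_pts=sex_points(inputs.sex),
        ultrasound_pts=ultrasound_points(
            inputs.cimt_mm, inputs.plaque_count, inputs.carotid_stenosis_pct
        ),
        tg_pts=tg_points(inputs.tg),
        glucose_pts=glucose_points(inputs.glucose),
        fibrinogen_pts=fibrinogen_points(inputs.fibrinogen),
        hscrp_pts=hscrp_points(inputs.hscrp),
        adiponectin_pts=adiponectin_points(inputs.adiponectin),
    )


def score_cohort(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Score every scoreable record; one row per scored patient.

    Non-scoreable records are omitted (callers audit them via
    :meth:`PatientRecord.scoreable`).
    """
    rows = []
    for rec in records:
        if not rec.scoreable:
            continue
        b = ibio_total(rec)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "sex_pts": b.sex_pts,
                "ultrasound_pts": b.ultrasound_pts,
                "tg_pts": b.tg_pts,
                "glucose_pts": b.glucose_pts,
                "fibrinogen_pts": b.fibrinogen_pts,
                "hscrp_pts": b.hscrp_pts,
                "adiponectin_pts": b.adiponectin_pts,
                "ibio_total": b.total,
                "presence_positive": b.presence_positive,
                "severity_positive": b.severity_positive,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "sex_pts", "ultrasound_pts", "tg_pts",
            "glucose_pts", "fibrinogen_pts", "hscrp_pts", "adiponectin_pts",
            "ibio_total", "presence_positive", "severity_positive",
        ],
    )
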