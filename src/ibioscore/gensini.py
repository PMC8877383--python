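"""Gensini angiographic score.

The Gensini score quantifies coronary atherosclerosis burden from an
angiogram: each lesion receives severity points that double with worsening
stenosis band (25% -> 1, 50% -> 2, 75% -> 4, 90% -> 8, 99% -> 16, total
occlusion -> 32), multiplied by a weight reflecting the functional importance
of the diseased segment (left main 5, proximal LAD/LCx 2.5, mid LAD 1.5,
right coronary and most major branches 1, small/distal branches 0.5); the
total is the sum over all lesions.  Band edges are lower-inclusive, and
stenoses below 25% are not scored, so a total of 0 means angiographically
unaffected arteries.

The segment vocabulary and weights live in one editable table,
``data/gensini_segments.csv``, shipped with the package.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable, Mapping, Sequence

from .cohort import GSCategory, assign_gs_category

__all__ = [
    "SegmentLesion",
    "LesionScore",
    "GensiniResult",
    "SEGMENT_MULTIPLIERS",
    "SEVERITY_BANDS",
    "severity_points",
    "segment_multiplier",
    "gensini_score",
    "read_lesions",
]

# (lower band edge in %, severity points); bands are lower-inclusive and a
# band applies up to the next edge.  100% (total occlusion) scores 32.
SEVERITY_BANDS: tuple[tuple[float, int], ...] = (
    (0.0, 0),
    (25.0, 1),
    (50.0, 2),
    (75.0, 4),
    (90.0, 8),
    (99.0, 16),
    (100.0, 32),
)


def _load_segments() -> dict[str, tuple[str, float]]:
    text = (
        resources.files("ibioscore.data")
        .joinpath("gensini_segments.csv")
        .read_text(encoding="utf-8")
    )
    table: dict[str, tuple[str, float]] = {}
    for row in csv.DictReader(text.splitlines()):
        table[row["segment_code"]] = (
            row["description"],
            float(row["multiplier"]),
        )
    return table


_SEGMENTS = _load_segments()

#: segment_code -> multiplier, loaded from the shipped segment table.
SEGMENT_MULTIPLIERS: dict[str, float] = {
    code: mult for code, (_, mult) in _SEGMENTS.items()
}


def severity_points(stenosis_pct: float) -> int:
    """Severity points for one lesion from its % diameter stenosis.

    Lower-inclusive geometric banding: <25 -> 0 (not scored), >=25 -> 1,
    >=50 -> 2, >=75 -> 4, >=90 -> 8, >=99 -> 16, 100 -> 32.
    """
    if not 0.0 <= stenosis_pct <= 100.0:
        raise ValueError(
            f"stenosis_pct must be in [0, 100], got {stenosis_pct!r}"
        )
    points = 0
    for edge, pts in SEVERITY_BANDS:
        if stenosis_pct >= edge:
            points = pts
    return points


def segment_multiplier(segment_code: str) -> float:
    """Functional-importance weight of a coronary segment."""
    try:
        return SEGMENT_MULTIPLIERS[segment_code]
    except KeyError:
        raise ValueError(
            f"unknown segment code {segment_code!r}; accepted codes: "
            f"{sorted(SEGMENT_MULTIPLIERS)}"
        ) from None


@dataclass(frozen=True)
class SegmentLesion:
    """One angiographic lesion: coronary segment and % diameter stenosis."""

    segment_code: str
    stenosis_pct: float

    def __post_init__(self) -> None:
        segment_multiplier(self.segment_code)  # validates the code
        if not 0.0 <= self.stenosis_pct <= 100.0:
            raise ValueError(
                f"stenosis_pct must be in [0, 100], got {self.stenosis_pct!r}"
            )


@dataclass(frozen=True)
class LesionScore:
    """Scored lesion: severity points x segment multiplier = contribution."""

    lesion: SegmentLesion
    severity_points: int
    multiplier: float

    @property
    def contribution(self) -> float:
        return self.severity_points * self.multiplier


@dataclass(frozen=True)
class GensiniResult:
    lesions: tuple[LesionScore, ...]
    total: float
    category: GSCategory


def gensini_score(lesions: Iterable[SegmentLesion]) -> GensiniResult:
    """Total Gensini score over a patient's lesions.

    At most one lesion per segment is scored; duplicated segments keep the
    maximal stenosis, with a warning.
    """
    by_segment: dict[str, SegmentLesion] = {}
    for lesion in lesions:
        prev = by_segment.get(lesion.segment_code)
        if prev is not None:
            warnings.warn(
                f"duplicate lesion in segment {lesion.segment_code!r}: "
                f"keeping maximal stenosis",
                stacklevel=2,
            )
            if lesion.stenosis_pct <= prev.stenosis_pct:
                continue
        by_segment[lesion.segment_code] = lesion

    scored = tuple(
        LesionScore(
            lesion=les,
            severity_points=severity_points(les.stenosis_pct),
            multiplier=segment_multiplier(les.segment_code),
        )
        for les in by_segment.values()
    )
    total = float(sum(s.contribution for s in scored))
    return GensiniResult(
        lesions=scored, total=total, category=assign_gs_category(total)
    )


def read_lesions(
    source: str | IO[str], delimiter: str | None = None
) -> dict[str, list[SegmentLesion]]:
    """Read per-patient lesion lists from delimited text.

    Expects columns ``patient_id``, ``segment_code``, ``stenosis_pct``.
    """
    import pandas as pd

    df = pd.read_csv(source, sep=delimiter, engine="python")
    required = {"patient_id", "segment_code", "stenosis_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lesion file lacks columns: {sorted(missing)}")
    out: dict[str, list[SegmentLesion]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["patient_id"]), []).append(
            SegmentLesion(
                segment_code=str(row["segment_code"]),
                stenosis_pct=float(row["stenosis_pct"]),
            )
        )
    return out


def attach_gensini(
    records: Sequence,
    lesions_by_patient: Mapping[str, Sequence[SegmentLesion]],
    atol: float = 1e-6,
) -> list:
    """Fill each record's Gensini score from its lesion list.

    Records with a precomputed score keep it, but a conflict with the
    lesion-derived total beyond ``atol`` is a hard error.
    """
    out = []
    for rec in records:
        if rec.patient_id in lesions_by_patient:
            total = gensini_score(lesions_by_patient[rec.patient_id]).total
            if rec.gensini is not None and abs(rec.gensini - total) > atol:
                raise ValueError(
                    f"patient {rec.patient_id}: precomputed Gensini "
                    f"{rec.gensini} disagrees with lesion-derived {total}"
                )
            rec = rec.replace(gensini=total)
        out.append(rec)
    return out
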