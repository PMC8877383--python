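"""Patient records, Gensini-score categorisation, and cohort input/output.

A cohort is a list of :class:`PatientRecord` objects, one per patient, holding
demographics, carotid-ultrasound measurements, serum biochemistry, and the
angiographic outcome (Gensini score).  Records are read from and written to
delimited text with an explicit column mapping; no header guessing is done.

Gensini-score strata follow the study cut-offs: GS = 0 means angiographically
unaffected coronary arteries, GS > 0 any coronary atherosclerosis, and
GS >= 35 severe disease; 0 < GS < 35 is called subclinical.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "GSLabel",
    "GSCategory",
    "PatientRecord",
    "CohortSummary",
    "IBIO_INPUT_FIELDS",
    "SEVERE_GS_CUTOFF",
    "assign_gs_category",
    "read_cohort",
    "write_cohort",
    "cohort_to_frame",
    "summarize_cohort",
]

#: Gensini-score cut-off above which (inclusive) coronary atherosclerosis is
#: classified as severe.
SEVERE_GS_CUTOFF = 35.0

#: PatientRecord fields that the i-BIO score consumes.  A record missing any
#: of these is not scoreable and is excluded (and counted) during evaluation.
IBIO_INPUT_FIELDS = (
    "sex",
    "cimt_mm",
    "plaque_count",
    "carotid_stenosis_pct",
    "tg",
    "glucose",
    "fibrinogen",
    "hscrp",
    "adiponectin",
)

#: Continuous variables summarised in cohort tables.
SUMMARY_VARIABLES = (
    "age",
    "tc",
    "ldl_c",
    "hdl_c",
    "tg",
    "apo_ai",
    "apo_b",
    "hscrp",
    "fibrinogen",
    "glucose",
    "insulin",
    "adiponectin",
    "leptin",
    "cimt_mm",
    "carotid_stenosis_pct",
)


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class GSLabel(str, Enum):
    """Mutually exclusive Gensini strata partitioning [0, inf)."""

    FREE = "free"          # GS = 0
    SUBCLINICAL = "subclinical"  # 0 < GS < 35
    SEVERE = "severe"      # GS >= 35


@dataclass(frozen=True)
class GSCategory:
    """Gensini stratum of one patient plus the two binary study endpoints.

    ``presence`` is the "any coronary atherosclerosis" endpoint (GS > 0) and
    ``severe`` the "severe coronary atherosclerosis" endpoint (GS >= 35).
    """

    label: GSLabel
    presence: bool
    severe: bool


def assign_gs_category(gs: float) -> GSCategory:
    """Map a Gensini score onto its stratum and binary endpoints.

    Parameters
    ----------
    gs : float
        Total Gensini score; must be >= 0.
    """
    if gs is None or (isinstance(gs, float) and math.isnan(gs)):
        raise ValueError("Gensini score is missing; cannot categorise")
    if gs < 0:
        raise ValueError(f"Gensini score must be non-negative, got {gs!r}")
    if gs == 0:
        return GSCategory(GSLabel.FREE, presence=False, severe=False)
    if gs < SEVERE_GS_CUTOFF:
        return GSCategory(GSLabel.SUBCLINICAL, presence=True, severe=False)
    return GSCategory(GSLabel.SEVERE, presence=True, severe=True)


# Field name -> (lower bound, upper bound) validation ranges.  None = open.
_NUMERIC_RANGES: dict[str, tuple[float | None, float | None]] = {
    "age": (0.0, None),
    "cimt_mm": (0.0, None),
    "plaque_count": (0.0, None),
    "carotid_stenosis_pct": (0.0, 100.0),
    "tc": (0.0, None),
    "ldl_c": (0.0, None),
    "hdl_c": (0.0, None),
    "tg": (0.0, None),
    "glucose": (0.0, None),
    "apo_ai": (0.0, None),
    "apo_b": (0.0, None),
    "fibrinogen": (0.0, None),
    "hscrp": (0.0, None),
    "insulin": (0.0, None),
    "adiponectin": (0.0, None),
    "leptin": (0.0, None),
    "gensini": (0.0, None),
}


@dataclass
class PatientRecord:
    """One patient: demographics, imaging, biochemistry, angiographic outcome.

    ``None`` marks a missing value.  Units are fixed: CIMT in mm, carotid
    stenosis in percent, lipids/glucose in mmol/L, apolipoproteins and
    fibrinogen in g/L, hsCRP in mg/L, insulin in uU/mL, adiponectin in ug/mL,
    leptin in ng/mL.  No unit conversion is attempted.
    """

    patient_id: str
    sex: Sex | None = None
    age: float | None = None
    cimt_mm: float | None = None
    plaque_count: int | None = None
    carotid_stenosis_pct: float | None = None
    tc: float | None = None
    ldl_c: float | None = None
    hdl_c: float | None = None
    tg: float | None = None
    glucose: float | None = None
    apo_ai: float | None = None
    apo_b: float | None = None
    fibrinogen: float | None = None
    hscrp: float | None = None
    insulin: float | None = None
    adiponectin: float | None = None
    leptin: float | None = None
    gensini: float | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be a non-empty string")
        if self.sex is not None:
            self.sex = Sex(self.sex)
        for name, (lo, hi) in _NUMERIC_RANGES.items():
            value = getattr(self, name)
            if value is None:
                continue
            if isinstance(value, float) and math.isnan(value):
                setattr(self, name, None)
                continue
            if lo is not None and value < lo:
                raise ValueError(f"{name}={value!r} below lower bound {lo}")
            if hi is not None and value > hi:
                raise ValueError(f"{name}={value!r} above upper bound {hi}")
        if self.plaque_count is not None:
            if self.plaque_count != int(self.plaque_count):
                raise ValueError(
                    f"plaque_count must be an integer, got {self.plaque_count!r}"
                )
            self.plaque_count = int(self.plaque_count)

    def missing_ibio_fields(self) -> tuple[str, ...]:
        """Names of i-BIO inputs absent from this record."""
        return tuple(f for f in IBIO_INPUT_FIELDS if getattr(self, f) is None)

    @property
    def scoreable(self) -> bool:
        """True iff every i-BIO input is present."""
        return not self.missing_ibio_fields()

    def gs_category(self) -> GSCategory:
        if self.gensini is None:
            raise ValueError(
                f"patient {self.patient_id}: no Gensini score available"
            )
        return assign_gs_category(self.gensini)

    def replace(self, **changes) -> "PatientRecord":
        return replace(self, **changes)


_RECORD_FIELDS = tuple(
    f.name for f in fields(PatientRecord)
)


def _identity_map() -> dict[str, str]:
    return {name: name for name in _RECORD_FIELDS}


def read_cohort(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[PatientRecord]:
    """Read a patient cohort from delimited text.

    Parameters
    ----------
    source : path or text stream
        CSV/TSV with a header row, UTF-8, "." decimal point.
    column_map : mapping, optional
        Maps :class:`PatientRecord` field names to column names in the file.
        Fields absent from the mapping fall back to their own name; columns
        absent from the file are treated as entirely missing.  The
        ``patient_id`` column is mandatory.
    delimiter : str, optional
        Field delimiter; sniffed from the header (comma vs tab) when omitted.

    Returns
    -------
    list of PatientRecord
        One record per data row, in file order.  Unparseable numeric cells
        become missing values; their count is logged.
    """
    cmap = _identity_map()
    if column_map:
        cmap.update(column_map)

    import csv as _csv

    try:
        df = pd.read_csv(source, sep=delimiter, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, _csv.Error):
        raise ValueError("cohort file is empty or has no parseable header") from None
    if df.empty and len(df.columns) == 0:
        raise ValueError("cohort file is empty")

    id_col = cmap["patient_id"]
    if id_col not in df.columns:
        raise ValueError(
            f"mandatory identifier column {id_col!r} not found; "
            f"available columns: {list(df.columns)}"
        )

    records: list[PatientRecord] = []
    n_unparseable = 0
    for _, row in df.iterrows():
        kwargs: dict[str, object] = {}
        for name in _RECORD_FIELDS:
            col = cmap.get(name, name)
            if col not in df.columns:
                continue
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            raw = str(raw).strip()
            if raw == "":
                continue
            if name == "patient_id":
                kwargs[name] = raw
            elif name == "sex":
                try:
                    kwargs[name] = Sex(raw.lower())
                except ValueError:
                    n_unparseable += 1
            else:
                try:
                    kwargs[name] = float(raw)
                except ValueError:
                    n_unparseable += 1
        if "patient_id" not in kwargs:
            raise ValueError(f"row {len(records)} has an empty patient_id cell")
        records.append(PatientRecord(**kwargs))

    if n_unparseable:
        logger.warning("read_cohort: %d unparseable cells set to missing",
                       n_unparseable)
    logger.info("read_cohort: %d records", len(records))
    return records


def cohort_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabulate a cohort as a DataFrame (missing values as NaN/None)."""
    rows = []
    for r in records:
        row = {}
        for name in _RECORD_FIELDS:
            v = getattr(r, name)
            if isinstance(v, Sex):
                v = v.value
            row[name] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=_RECORD_FIELDS)


def write_cohort(
    records: Sequence[PatientRecord],
    dest: str | IO[str],
    delimiter: str = ",",
) -> None:
    """Write a cohort as delimited text readable by :func:`read_cohort`."""
    df = cohort_to_frame(records)
    df.to_csv(dest, sep=delimiter, index=False)


@dataclass
class VariableSummary:
    """Descriptive and comparative statistics for one variable, two groups."""

    variable: str
    normal: bool
    test: str  # "welch_t" or "mann_whitney"
    p_value: float
    # per-group descriptors keyed by group name
    stats: dict[str, dict[str, float]] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)


@dataclass
class CohortSummary:
    """Per-variable two-group summary of a cohort.

    Variables for which a per-group Shapiro-Wilk test (alpha = 0.05, both
    groups required to pass) does not reject normality are described as
    mean +- SD and compared with Welch's t-test; all others as
    median (Q25-Q75) with the Mann-Whitney U test.
    """

    endpoint: str
    group_sizes: dict[str, int]
    variables: dict[str, VariableSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, vs in self.variables.items():
            row: dict[str, object] = {"variable": name,
                                      "presentation": "mean_sd" if vs.normal else "median_iqr",
                                      "test": vs.test, "p_value": vs.p_value}
            for g, st in vs.stats.items():
                for k, v in st.items():
                    row[f"{g}_{k}"] = v
                row[f"{g}_n"] = vs.n[g]
            rows.append(row)
        return pd.DataFrame(rows)


_SHAPIRO_ALPHA = 0.05


def summarize_cohort(
    records: Sequence[PatientRecord],
    endpoint: str = "presence",
    variables: Sequence[str] = SUMMARY_VARIABLES,
) -> CohortSummary:
    """Produce a two-group summary table for a cohort.

    Parameters
    ----------
    records : sequence of PatientRecord
        Every record must carry a Gensini score.
    endpoint : {"presence", "severe"}
        Grouping: ``presence`` contrasts GS = 0 vs GS > 0; ``severe``
        contrasts GS < 35 vs GS >= 35.
    variables : sequence of str
        Record fields to summarise; fields with < 3 non-missing values in
        either group raise.
    """
    if endpoint not in ("presence", "severe"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if endpoint == "presence":
        names = ("gs0", "gs_gt0")
        split = lambda r: r.gs_category().presence  # noqa: E731
    else:
        names = ("gs_lt35", "gs_ge35")
        split = lambda r: r.gs_category().severe  # noqa: E731

    groups: dict[str, list[PatientRecord]] = {names[0]: [], names[1]: []}
    for r in records:
        groups[names[1] if split(r) else names[0]].append(r)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"group {g!r} is empty; cannot summarise")

    out: dict[str, VariableSummary] = {}
    for var in variables:
        samples = {}
        for g, members in groups.items():
            vals = np.array(
                [getattr(r, var) for r in members if getattr(r, var) is not None],
                dtype=float,
            )
            if vals.size < 3:
                raise ValueError(
                    f"variable {var!r}: fewer than 3 non-missing values in "
                    f"group {g!r}"
                )
            samples[g] = np.sort(vals)

        # zero-range groups cannot be normality-tested; present as medians
        normal = all(np.ptp(v) > 0 for v in samples.values()) and all(
            stats.shapiro(v).pvalue > _SHAPIRO_ALPHA for v in samples.values()
        )
        a, b = (samples[g] for g in names)
        if normal:
            test = "welch_t"
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            desc = {
                g: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
                for g, v in samples.items()
            }
        else:
            test = "mann_whitney"
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            desc = {
                g: {
                    "median": float(np.median(v)),
                    "q25": float(np.percentile(v, 25)),
                    "q75": float(np.percentile(v, 75)),
                }
                for g, v in samples.items()
            }
        out[var] = VariableSummary(
            variable=var, normal=normal, test=test, p_value=float(p),
            stats=desc, n={g: int(v.size) for g, v in samples.items()},
        )

    return CohortSummary(
        endpoint=endpoint,
        group_sizes={g: len(m) for g, m in groups.items()},
        variables=out,
    )
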