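"""Patient-record data model, CSV I/O, validation and indicator encoding.

A :class:`PatientRecord` holds one subject's clinical and laboratory values
at the diagnosis of diabetes, plus an optional group label (antibody-positive
case vs. type-2 reference).  A :class:`Cohort` is an ordered collection of
records with provenance.  :func:`encode_indicators` maps a record onto the
seven binary dummy variables used by the discriminant stage: two age-at-onset
bins, two BMI bins, and cutoff exceedances for triglycerides, HbA1c and HDL
cholesterol.

Bin convention: all intervals are half-open, closed on the left.  Age bins
are [20, 30), [30, 50), [50, inf); BMI bins are (0, 23), [23, 25), [25, inf).
The reference levels (age >= 50, BMI >= 25) carry no dummy.  Cutoff
exceedance indicators use >= (boundary values count as exceeding).
"""

from __future__ import annotations

import csv
import enum
import json
import logging
import math
from dataclasses import dataclass, field, fields as _dc_fields
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EncodingError, SchemaError

logger = logging.getLogger(__name__)


class Group(str, enum.Enum):
    """Diagnostic group label. GADA_POS is the positive (case) class."""

    GADA_POS = "GADA_POS"
    T2DM = "T2DM"


class Gender(str, enum.Enum):
    M = "M"
    F = "F"


#: Continuous analysis variables, in report order.
NUMERIC_FIELDS = (
    "age_onset",
    "bmi",
    "total_chol",
    "tg",
    "hdl",
    "hba1c",
    "gpt",
    "creatinine",
)

#: Binary habit / medication flags.
BOOL_FIELDS = ("smoking", "statin", "fibrate")

#: Canonical CSV column order.
CSV_COLUMNS = ("group", "gender") + NUMERIC_FIELDS + BOOL_FIELDS

#: Fields that must be strictly positive when present.
_POSITIVE_FIELDS = ("bmi", "total_chol", "tg", "hdl", "hba1c", "gpt", "creatinine")

#: The seven dummy variables of the published discriminant function, in order.
INDICATOR_FIELDS = (
    "age_lt30",
    "age_30to50",
    "bmi_lt23",
    "bmi_23to25",
    "tg_ge_cut",
    "hba1c_ge_cut",
    "hdl_ge_cut",
)

MIN_AGE_ONSET = 20.0


@dataclass
class PatientRecord:
    """One subject's raw values. Any field may be ``None`` (missing)."""

    group: Optional[Group] = None
    gender: Optional[Gender] = None
    age_onset: Optional[float] = None
    bmi: Optional[float] = None
    total_chol: Optional[float] = None
    tg: Optional[float] = None
    hdl: Optional[float] = None
    hba1c: Optional[float] = None
    gpt: Optional[float] = None
    creatinine: Optional[float] = None
    smoking: Optional[bool] = None
    statin: Optional[bool] = None
    fibrate: Optional[bool] = None

    def validation_errors(self) -> list[str]:
        """Return invariant violations (empty list when the record is valid)."""
        errs: list[str] = []
        if self.age_onset is not None:
            if not math.isfinite(self.age_onset) or self.age_onset < MIN_AGE_ONSET:
                errs.append(f"age_onset={self.age_onset!r} violates age_onset >= {MIN_AGE_ONSET}")
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value <= 0):
                errs.append(f"{name}={value!r} must be strictly positive")
        return errs

    def is_complete(self, fields: Sequence[str] = NUMERIC_FIELDS) -> bool:
        return all(getattr(self, name) is not None for name in fields)


@dataclass
class ValidationReport:
    """Row-level diagnostics from :func:`read_cohort`."""

    n_rows: int = 0
    n_kept: int = 0
    n_rejected: int = 0
    n_incomplete_dropped: int = 0
    #: (1-based file line number, human-readable reason) per dropped row.
    rejections: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_rows": self.n_rows,
                "n_kept": self.n_kept,
                "n_rejected": self.n_rejected,
                "n_incomplete_dropped": self.n_incomplete_dropped,
                "rejections": [{"line": ln, "reason": r} for ln, r in self.rejections],
            },
            indent=2,
        )


@dataclass
class Cohort:
    """Ordered list of records plus free-text provenance."""

    records: list = field(default_factory=list)
    provenance: str = ""
    validation: Optional[ValidationReport] = None

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> dict:
        """Record count per group (records without a label are ignored)."""
        out = {Group.GADA_POS: 0, Group.T2DM: 0}
        for rec in self.records:
            if rec.group is not None:
                out[rec.group] += 1
        return out

    def require_two_groups(self, minimum: int = 2) -> None:
        counts = self.counts()
        if any(c < minimum for c in counts.values()):
            raise DomainError(
                f"both groups need >= {minimum} records for fitting; got "
                f"{counts[Group.GADA_POS]} GADA_POS and {counts[Group.T2DM]} T2DM"
            )

    def split(self) -> tuple[list, list]:
        """(case records, reference records), preserving order."""
        cases = [r for r in self.records if r.group is Group.GADA_POS]
        refs = [r for r in self.records if r.group is Group.T2DM]
        return cases, refs

    def to_dataframe(self) -> pd.DataFrame:
        """Flat frame with canonical columns; enums as strings, bools as 0/1."""
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "group": rec.group.value if rec.group else None,
                    "gender": rec.gender.value if rec.gender else None,
                    **{name: getattr(rec, name) for name in NUMERIC_FIELDS},
                    **{
                        name: (None if getattr(rec, name) is None else int(getattr(rec, name)))
                        for name in BOOL_FIELDS
                    },
                }
            )
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index: weight in kilograms over height in meters squared."""
    if not (weight_kg > 0 and height_m > 0):
        raise DomainError(f"weight and height must be positive, got ({weight_kg}, {height_m})")
    return weight_kg / height_m**2


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"1", "true", "t", "y", "yes"}
_FALSE_TOKENS = {"0", "false", "f", "n", "no"}
_GROUP_TOKENS = {
    "gada_pos": Group.GADA_POS,
    "gada+": Group.GADA_POS,
    "gada": Group.GADA_POS,
    "case": Group.GADA_POS,
    "t2dm": Group.T2DM,
    "reference": Group.T2DM,
}
_GENDER_TOKENS = {"m": Gender.M, "male": Gender.M, "f": Gender.F, "female": Gender.F}


def _parse_bool(token: str, column: str) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise ValueError(f"unparseable boolean {token!r} in column {column!r}")


def _parse_row(raw: Mapping[str, str], schema: Mapping[str, str]) -> PatientRecord:
    kwargs: dict = {}
    for canon in CSV_COLUMNS:
        token = raw.get(schema[canon], "")
        token = "" if token is None else str(token).strip()
        if token == "" or token.lower() in {"na", "nan", "none"}:
            kwargs[canon] = None
            continue
        if canon == "group":
            key = token.strip().lower()
            if key not in _GROUP_TOKENS:
                raise ValueError(f"unknown group label {token!r}")
            kwargs[canon] = _GROUP_TOKENS[key]
        elif canon == "gender":
            key = token.strip().lower()
            if key not in _GENDER_TOKENS:
                raise ValueError(f"unknown gender {token!r}")
            kwargs[canon] = _GENDER_TOKENS[key]
        elif canon in BOOL_FIELDS:
            kwargs[canon] = _parse_bool(token, schema[canon])
        else:
            try:
                kwargs[canon] = float(token)
            except ValueError:
                raise ValueError(f"unparseable numeric {token!r} in column {schema[canon]!r}")
    return PatientRecord(**kwargs)


def read_cohort(
    path,
    schema: Optional[Mapping[str, str]] = None,
    complete_case: bool = True,
    complete_fields: Sequence[str] = NUMERIC_FIELDS,
) -> Cohort:
    """Read and validate a cohort CSV.

    ``schema`` maps canonical field names to CSV column names (identity by
    default).  Rows violating record invariants, or failing to parse, are
    rejected with line-numbered diagnostics in ``cohort.validation``; with
    ``complete_case`` (default) rows missing any of ``complete_fields`` are
    dropped as well, with counts logged.
    """
    schema = dict(schema) if schema else {c: c for c in CSV_COLUMNS}
    for canon in CSV_COLUMNS:
        schema.setdefault(canon, canon)

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [schema[c] for c in CSV_COLUMNS if c not in ("group",)]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s) in {path}: {missing}")
    has_group = schema["group"] in frame.columns

    report = ValidationReport(n_rows=len(frame))
    records: list[PatientRecord] = []
    for idx, raw in enumerate(frame.to_dict("records")):
        line = idx + 2  # header is line 1
        if not has_group:
            raw = dict(raw)
            raw[schema["group"]] = ""
        try:
            rec = _parse_row(raw, schema)
        except ValueError as exc:
            report.rejections.append((line, str(exc)))
            report.n_rejected += 1
            continue
        errs = rec.validation_errors()
        if errs:
            report.rejections.append((line, "; ".join(errs)))
            report.n_rejected += 1
            continue
        if complete_case and not rec.is_complete(complete_fields):
            missing_fields = [f for f in complete_fields if getattr(rec, f) is None]
            report.rejections.append((line, f"incomplete: missing {missing_fields}"))
            report.n_incomplete_dropped += 1
            continue
        records.append(rec)
    report.n_kept = len(records)
    if report.n_rejected or report.n_incomplete_dropped:
        logger.warning(
            "read_cohort(%s): kept %d of %d rows (%d invalid, %d incomplete)",
            path, report.n_kept, report.n_rows, report.n_rejected, report.n_incomplete_dropped,
        )
    return Cohort(records=records, provenance=str(path), validation=report)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to canonical CSV (UTF-8, header, round-trip floats)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in cohort.records:
            row = []
            for name in CSV_COLUMNS:
                value = getattr(rec, name)
                if value is None:
                    row.append("")
                elif name in ("group", "gender"):
                    row.append(value.value)
                elif name in BOOL_FIELDS:
                    row.append(int(value))
                else:
                    row.append(repr(float(value)))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Indicator encoding
# ---------------------------------------------------------------------------


@dataclass
class CutoffSet:
    """Cutoffs used by the exceedance indicators.

    Defaults are the published ROC-derived values (TG 98 mg/dL, HbA1c 8.6 %,
    HDL-C 46 mg/dL).  ``extra`` holds cutoffs for any additional variables
    (e.g. total cholesterol, GPT) derived in a re-analysis.
    """

    tg: float = 98.0
    hba1c: float = 8.6
    hdl: float = 46.0
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"tg": self.tg, "hba1c": self.hba1c, "hdl": self.hdl, **self.extra}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "CutoffSet":
        mapping = dict(mapping)
        return cls(
            tg=float(mapping.pop("tg")),
            hba1c=float(mapping.pop("hba1c")),
            hdl=float(mapping.pop("hdl")),
            extra={k: float(v) for k, v in mapping.items()},
        )


@dataclass(frozen=True)
class IndicatorVector:
    """The seven 0/1 dummies feeding the published discriminant function."""

    age_lt30: int
    age_30to50: int
    bmi_lt23: int
    bmi_23to25: int
    tg_ge_cut: int
    hba1c_ge_cut: int
    hdl_ge_cut: int

    def __post_init__(self):
        for name in INDICATOR_FIELDS:
            if getattr(self, name) not in (0, 1):
                raise DomainError(f"indicator {name} must be 0 or 1")
        if self.age_lt30 + self.age_30to50 > 1:
            raise DomainError("age bin dummies are mutually exclusive")
        if self.bmi_lt23 + self.bmi_23to25 > 1:
            raise DomainError("BMI bin dummies are mutually exclusive")

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, name) for name in INDICATOR_FIELDS)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in INDICATOR_FIELDS}

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple(), dtype=float)


def encode_value(rec: PatientRecord, name: str, cutoffs: Mapping[str, float]) -> int:
    """Encode one named dummy from a record.

    Recognized names: the age/BMI bin dummies, ``<var>_ge_cut`` for any
    numeric variable with an entry in ``cutoffs``, and the raw binary flags
    (``smoking``/``statin``/``fibrate``/``male``).
    """

    def need(fieldname: str) -> float:
        value = getattr(rec, fieldname, None)
        if value is None:
            raise EncodingError(f"cannot encode {name!r}: record is missing {fieldname!r}")
        return value

    if name == "age_lt30":
        return int(need("age_onset") < 30)
    if name == "age_30to50":
        return int(30 <= need("age_onset") < 50)
    if name == "bmi_lt23":
        return int(need("bmi") < 23)
    if name == "bmi_23to25":
        return int(23 <= need("bmi") < 25)
    if name.endswith("_ge_cut"):
        var = name[: -len("_ge_cut")]
        if var not in cutoffs:
            raise EncodingError(f"no cutoff supplied for variable {var!r}")
        return int(need(var) >= cutoffs[var])
    if name in BOOL_FIELDS:
        if getattr(rec, name) is None:
            raise EncodingError(f"cannot encode {name!r}: record is missing {name!r}")
        return int(getattr(rec, name))
    if name == "male":
        if rec.gender is None:
            raise EncodingError("cannot encode 'male': record is missing 'gender'")
        return int(rec.gender is Gender.M)
    raise EncodingError(f"unknown indicator name {name!r}")


def encode_indicators(rec: PatientRecord, cuts: Optional[CutoffSet] = None) -> IndicatorVector:
    """Map a record to the seven published dummies under the given cutoffs."""
    cuts = cuts or CutoffSet()
    cutoffs = cuts.as_dict()
    values = {name: encode_value(rec, name, cutoffs) for name in INDICATOR_FIELDS}
    return IndicatorVector(**values)


def indicator_matrix(
    records: Iterable[PatientRecord],
    names: Sequence[str],
    cutoffs: Mapping[str, float],
) -> pd.DataFrame:
    """Encode many records into a 0/1 design matrix with columns ``names``."""
    rows = [[encode_value(rec, name, cutoffs) for name in names] for rec in records]
    return pd.DataFrame(rows, columns=list(names), dtype=float)
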