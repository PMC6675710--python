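"""Domain types, validation, and normalization for ER-positive breast cancer cases.

A :class:`CaseRecord` carries the clinicopathologic measurements used by the
modified Magee equations and the RoMMa triage rules -- Nottingham score,
modified ER/PR H-scores, HER-2 status (IHC and reflex FISH), Ki-67 percentage,
and tumor size -- plus optional Oncotype DX recurrence score and outcome
fields (recurrence, follow-up, node status, lymphovascular invasion,
therapies).

HER-2 is resolved to a three-level status with FISH taking precedence over
IHC whenever a FISH result exists: an equivocal IHC (2+) without FISH remains
unresolved and is flagged rather than silently classified.
"""

from __future__ import annotations

import enum
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "Her2Status",
    "FishResult",
    "LymphNodeStatus",
    "LviStatus",
    "CaseRecord",
    "ValidationReport",
    "MissingFieldError",
    "DuplicateCaseError",
    "normalize_her2",
    "validate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "records_to_frame",
    "COHORT_COLUMNS",
]


class Her2Status(str, enum.Enum):
    """Resolved HER-2 status after applying the reflex-FISH rule."""

    NEGATIVE = "negative"
    EQUIVOCAL = "equivocal"
    POSITIVE = "positive"


class FishResult(str, enum.Enum):
    AMPLIFIED = "amplified"
    NOT_AMPLIFIED = "not_amplified"


class LymphNodeStatus(str, enum.Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"
    UNKNOWN = "unknown"


class LviStatus(str, enum.Enum):
    IDENTIFIED = "identified"
    NOT_IDENTIFIED = "not_identified"
    SUSPICIOUS = "suspicious"
    UNKNOWN = "unknown"


class MissingFieldError(ValueError):
    """A field required to resolve or score a case is absent."""


class DuplicateCaseError(ValueError):
    """Two records in one cohort share a case_id."""


class CaseRecord(BaseModel):
    """One tumor's clinicopathologic measurements.

    ``er_h_score`` and ``pr_h_score`` are modified H-scores already computed
    from staining intensity and percent-positive classes; this package treats
    them as integer inputs in 0-300 and does not re-derive them.

    Unknown lymph-node or LVI status is a distinct enum level and is never
    imputed; analyses exclude unknowns from their denominators.
    """

    model_config = ConfigDict(validate_assignment=True)

    case_id: str
    patient_id: str
    nottingham_score: int = Field(ge=3, le=9)
    er_h_score: int = Field(ge=0, le=300)
    pr_h_score: int = Field(ge=0, le=300)
    her2_ihc: Optional[int] = Field(default=None, ge=0, le=3)
    her2_fish: Optional[FishResult] = None
    ki67_pct: Optional[float] = Field(default=None, ge=0, le=100)
    tumor_size_cm: Optional[float] = Field(default=None, gt=0)
    odx_rs: Optional[int] = Field(default=None, ge=0, le=100)
    age_years: Optional[int] = Field(default=None, ge=0, le=130)
    ln_status: LymphNodeStatus = LymphNodeStatus.UNKNOWN
    lvi_status: LviStatus = LviStatus.UNKNOWN
    recurred: Optional[bool] = None
    followup_years: Optional[float] = Field(default=None, ge=0)
    hormonal_therapy: Optional[bool] = None
    chemotherapy: Optional[bool] = None
    radiation: Optional[bool] = None

    def her2_status(self) -> Her2Status:
        """Resolved HER-2 status for this case (FISH overrides IHC)."""
        return normalize_her2(self.her2_ihc, self.her2_fish, case_id=self.case_id)


def normalize_her2(
    her2_ihc: Optional[int] = None,
    her2_fish: Optional[Union[FishResult, str]] = None,
    *,
    case_id: str = "<unknown>",
) -> Her2Status:
    """Resolve HER-2 to negative / equivocal / positive.

    FISH, when present, determines the status regardless of the IHC score
    (amplified -> positive, not amplified -> negative). Without FISH, IHC
    0/1+ is negative, 3+ is positive, and 2+ remains equivocal (unresolved).

    Raises
    ------
    MissingFieldError
        If both inputs are absent.
    """
    if her2_ihc is None and her2_fish is None:
        raise MissingFieldError(
            f"case {case_id}: neither HER-2 IHC nor FISH is available"
        )
    if her2_fish is not None:
        fish = FishResult(her2_fish)
        return Her2Status.POSITIVE if fish is FishResult.AMPLIFIED else Her2Status.NEGATIVE
    if her2_ihc in (0, 1):
        return Her2Status.NEGATIVE
    if her2_ihc == 3:
        return Her2Status.POSITIVE
    return Her2Status.EQUIVOCAL


class ValidationReport(BaseModel):
    """Partition of a cohort into usable and flagged records.

    ``usable + flagged == n_records`` always holds; a record is usable iff it
    carries no flag. ``flag_counts`` counts records per reason (a record with
    two flags appears under both reasons but is counted once in ``flagged``).
    """

    n_records: int
    usable: int
    flagged: int
    flag_counts: dict[str, int]
    flags_by_case: dict[str, list[str]]

    def is_usable(self, case_id: str) -> bool:
        return case_id not in self.flags_by_case


_BOUND_ERROR_TYPES = {
    "greater_than",
    "greater_than_equal",
    "less_than",
    "less_than_equal",
}


def _record_flags(record: CaseRecord) -> list[str]:
    flags = []
    if record.ki67_pct is None:
        flags.append("missing_ki67")
    if record.tumor_size_cm is None:
        flags.append("missing_size")
    try:
        status = record.her2_status()
    except MissingFieldError:
        flags.append("missing_her2")
    else:
        if status is Her2Status.EQUIVOCAL:
            flags.append("unresolved_her2")
    return flags


def validate_cohort(
    records: Sequence[Union[CaseRecord, Mapping]],
) -> ValidationReport:
    """Audit a cohort: every record is either usable for scoring or flagged.

    Accepts parsed :class:`CaseRecord` objects or raw mappings; mappings that
    fail type/range validation are flagged ``out_of_range`` (bound violations)
    or ``invalid`` (other schema failures) rather than raising.

    Raises
    ------
    DuplicateCaseError
        If two records share a ``case_id``.
    """
    flags_by_case: dict[str, list[str]] = {}
    seen: set[str] = set()
    n = 0
    for i, item in enumerate(records):
        n += 1
        if isinstance(item, CaseRecord):
            record, case_id, flags = item, item.case_id, _record_flags(item)
        else:
            case_id = str(item.get("case_id", f"<row {i}>"))
            try:
                record = CaseRecord.model_validate(dict(item))
            except ValidationError as exc:
                kinds = {e["type"] for e in exc.errors()}
                flags = ["out_of_range" if kinds & _BOUND_ERROR_TYPES else "invalid"]
            else:
                flags = _record_flags(record)
        if case_id in seen:
            raise DuplicateCaseError(f"duplicate case_id {case_id!r} in cohort")
        seen.add(case_id)
        if flags:
            flags_by_case[case_id] = flags
    counts = Counter(flag for flags in flags_by_case.values() for flag in flags)
    return ValidationReport(
        n_records=n,
        usable=n - len(flags_by_case),
        flagged=len(flags_by_case),
        flag_counts=dict(counts),
        flags_by_case=flags_by_case,
    )


#: Fixed column order of the cohort CSV schema (UTF-8, empty field = missing).
COHORT_COLUMNS = [
    "case_id",
    "patient_id",
    "nottingham_score",
    "er_h_score",
    "pr_h_score",
    "her2_ihc",
    "her2_fish",
    "ki67_pct",
    "tumor_size_cm",
    "odx_rs",
    "age_years",
    "ln_status",
    "lvi_status",
    "recurred",
    "followup_years",
    "hormonal_therapy",
    "chemotherapy",
    "radiation",
]

_BOOL_COLUMNS = ("recurred", "hormonal_therapy", "chemotherapy", "radiation")
_INT_COLUMNS = ("nottingham_score", "er_h_score", "pr_h_score", "her2_ihc", "odx_rs", "age_years")
_FLOAT_COLUMNS = ("ki67_pct", "tumor_size_cm", "followup_years")

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(value: str, column: str) -> bool:
    token = value.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValueError(f"column {column}: cannot parse boolean from {value!r}")


def _row_to_kwargs(row: Mapping[str, object]) -> dict:
    kwargs: dict = {}
    for column, value in row.items():
        if value is None or (isinstance(value, float) and pd.isna(value)):
            continue
        if isinstance(value, str) and value.strip() == "":
            continue
        if column in _BOOL_COLUMNS and isinstance(value, str):
            value = _parse_bool(value, column)
        elif column in _INT_COLUMNS and not isinstance(value, int):
            value = int(float(value))
        elif column in _FLOAT_COLUMNS and not isinstance(value, float):
            value = float(value)
        kwargs[column] = value
    return kwargs


def read_cohort_csv(path: Union[str, Path]) -> list[CaseRecord]:
    """Read a cohort CSV (one row per case) into validated records."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(frame.columns) - set(COHORT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown cohort columns: {sorted(unknown)}")
    records = []
    for _, row in frame.iterrows():
        records.append(CaseRecord.model_validate(_row_to_kwargs(row.to_dict())))
    return records


def _cell(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def write_cohort_csv(records: Iterable[CaseRecord], path: Union[str, Path]) -> None:
    """Write records to the cohort CSV schema (missing values as empty fields)."""
    rows = []
    for record in records:
        data = record.model_dump()
        rows.append({column: _cell(data[column]) for column in COHORT_COLUMNS})
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def records_to_frame(records: Sequence[CaseRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame with native dtypes (enums as their string values)."""
    rows = []
    for record in records:
        data = record.model_dump()
        for key in ("her2_fish", "ln_status", "lvi_status"):
            if isinstance(data[key], enum.Enum):
                data[key] = data[key].value
        rows.append(data)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
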