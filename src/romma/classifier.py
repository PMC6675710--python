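"""RoMMa risk stratification.

The Rochester Modified Magee algorithm triages ER-positive breast cancer
cases on the average modified Magee score (amMs) plus a histologic low-risk
criterion, deciding which cases need send-out Oncotype DX testing:

* amMs <= 9                       -> lowest risk
* amMs <= 12, or histologic low
  risk (NS < 6, ER and PR H-score
  >= 150, Ki-67 < 10%)            -> low risk
* amMs > 30                       -> high risk
* otherwise                       -> intermediate (reflex to ODX testing)

Only intermediate cases are recommended for send-out testing. Cases with
amMs <= 18 are additionally predicted to fall below the TAILORx ODXRS-26
boundary. All thresholds are config-overridable; the defaults pin the
published rules, and threshold comparisons always use the unrounded amMs.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import yaml
from pydantic import BaseModel, Field, model_validator

import pandas as pd

from .data_model import CaseRecord
from .magee import EquationSpec, MageeResult, score_cohort

__all__ = [
    "RiskCategory",
    "OdxBandPrediction",
    "RommaThresholds",
    "RommaCall",
    "CohortSummary",
    "histologic_low_risk",
    "classify",
    "classify_cohort",
    "calls_to_frame",
]


class RiskCategory(str, enum.Enum):
    LOWEST_RISK = "lowest_risk"
    LOW_RISK = "low_risk"
    INTERMEDIATE = "intermediate"
    HIGH_RISK = "high_risk"


#: Ordering used for monotonicity checks and patient-level roll-ups.
CATEGORY_RANK = {
    RiskCategory.LOWEST_RISK: 0,
    RiskCategory.LOW_RISK: 1,
    RiskCategory.INTERMEDIATE: 2,
    RiskCategory.HIGH_RISK: 3,
}


class OdxBandPrediction(str, enum.Enum):
    LOW = "low"            # predicted ODXRS < 18
    HIGH = "high"          # predicted ODXRS > 30
    BELOW_26 = "below_26"  # predicted ODXRS < 26 (TAILORx lower-risk band)
    INDETERMINATE = "indeterminate"


class RommaThresholds(BaseModel):
    """Decision thresholds with the published defaults pinned.

    ``histologic_ns_max`` is exclusive (NS < 6), ``histologic_h_min``
    inclusive (H-score >= 150), ``histologic_ki67_max`` exclusive (< 10%).
    """

    lowest_cutoff: float = 9.0
    low_cutoff: float = 12.0
    odx26_cutoff: float = 18.0
    high_cutoff: float = 30.0
    histologic_ns_max: int = 6
    histologic_h_min: int = 150
    histologic_ki67_max: float = 10.0

    @model_validator(mode="after")
    def _ordered(self) -> "RommaThresholds":
        if not (
            self.lowest_cutoff <= self.low_cutoff <= self.odx26_cutoff < self.high_cutoff
        ):
            raise ValueError(
                "thresholds must satisfy lowest <= low <= odx26 < high"
            )
        return self

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RommaThresholds":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


class RommaCall(BaseModel):
    """The algorithm's output for one case."""

    case_id: str
    category: RiskCategory
    histologic_low_risk: bool
    histologic_indeterminate: bool = False
    predicted_odx_band: OdxBandPrediction
    send_for_odx: bool
    amms: float
    rationale: List[str]


def _histologic(
    record: CaseRecord, thresholds: RommaThresholds
) -> Tuple[bool, bool]:
    """(low_risk, indeterminate): missing ER/PR/Ki-67 yields (False, True)."""
    if record.ki67_pct is None:
        return False, True
    value = (
        record.nottingham_score < thresholds.histologic_ns_max
        and record.er_h_score >= thresholds.histologic_h_min
        and record.pr_h_score >= thresholds.histologic_h_min
        and record.ki67_pct < thresholds.histologic_ki67_max
    )
    return value, False


def histologic_low_risk(
    record: CaseRecord, thresholds: Optional[RommaThresholds] = None
) -> bool:
    """Histologic low-risk rule: NS < 6 AND ER >= 150 AND PR >= 150 AND Ki-67 < 10.

    Both H-scores must clear 150 (the "and" reading of the published rule).
    A missing Ki-67 makes the rule indeterminate and returns False.
    """
    return _histologic(record, thresholds or RommaThresholds())[0]


def classify(
    magee: MageeResult,
    record: CaseRecord,
    thresholds: Optional[RommaThresholds] = None,
) -> RommaCall:
    """Apply the RoMMa decision rules to one scored case."""
    th = thresholds or RommaThresholds()
    amms = magee.average_score
    hist, hist_indet = _histologic(record, th)
    rationale: List[str] = []

    if amms <= th.lowest_cutoff:
        category = RiskCategory.LOWEST_RISK
        rationale.append(f"amMs {amms:.1f} <= {th.lowest_cutoff:g} (lowest risk)")
    elif amms <= th.low_cutoff:
        category = RiskCategory.LOW_RISK
        rationale.append(f"amMs {amms:.1f} <= {th.low_cutoff:g} (low risk)")
    elif hist:
        category = RiskCategory.LOW_RISK
        rationale.append(
            f"histologic low risk (NS < {th.histologic_ns_max}, "
            f"ER/PR >= {th.histologic_h_min}, Ki-67 < {th.histologic_ki67_max:g}%)"
        )
    elif amms > th.high_cutoff:
        category = RiskCategory.HIGH_RISK
        rationale.append(f"amMs {amms:.1f} > {th.high_cutoff:g} (high risk)")
    else:
        category = RiskCategory.INTERMEDIATE
        rationale.append(
            f"amMs {amms:.1f} in ({th.low_cutoff:g}, {th.high_cutoff:g}] "
            "without histologic low-risk criteria (intermediate)"
        )
    if hist_indet:
        rationale.append("histologic criteria indeterminate (missing Ki-67)")

    if category in (RiskCategory.LOWEST_RISK, RiskCategory.LOW_RISK):
        band = OdxBandPrediction.LOW
    elif category is RiskCategory.HIGH_RISK:
        band = OdxBandPrediction.HIGH
    elif amms <= th.odx26_cutoff:
        band = OdxBandPrediction.BELOW_26
        rationale.append(f"amMs {amms:.1f} <= {th.odx26_cutoff:g}: predicted ODXRS < 26")
    else:
        band = OdxBandPrediction.INDETERMINATE

    return RommaCall(
        case_id=magee.case_id,
        category=category,
        histologic_low_risk=hist,
        histologic_indeterminate=hist_indet,
        predicted_odx_band=band,
        send_for_odx=category is RiskCategory.INTERMEDIATE,
        amms=amms,
        rationale=rationale,
    )


class CohortSummary(BaseModel):
    """Category frequencies over the scorable cases of a cohort.

    ``low_risk_combined`` counts lowest+low together (the granularity at
    which low-risk triage fractions are usually quoted); percentages are
    over scorable cases and sum to 100 across the four categories.
    """

    n_cases: int
    n_scored: int
    counts: dict[str, int]
    percentages: dict[str, float]
    low_risk_combined: int
    low_risk_combined_pct: float
    high_risk_pct: float
    send_for_odx: int = Field(ge=0)


def classify_cohort(
    records: Sequence[CaseRecord],
    specs: Optional[Sequence[EquationSpec]] = None,
    thresholds: Optional[RommaThresholds] = None,
    on_unscorable: str = "raise",
) -> Tuple[List[RommaCall], CohortSummary]:
    """Classify a cohort; returns per-case calls plus a frequency summary."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    results = score_cohort(records, specs, on_unscorable=on_unscorable)
    by_id = {record.case_id: record for record in records}
    calls = [classify(result, by_id[result.case_id], thresholds) for result in results]
    if not calls:
        raise ValueError("no scorable cases in cohort")
    counts = {category.value: 0 for category in RiskCategory}
    for call in calls:
        counts[call.category.value] += 1
    n = len(calls)
    low_combined = (
        counts[RiskCategory.LOWEST_RISK.value] + counts[RiskCategory.LOW_RISK.value]
    )
    summary = CohortSummary(
        n_cases=len(records),
        n_scored=n,
        counts=counts,
        percentages={key: 100.0 * value / n for key, value in counts.items()},
        low_risk_combined=low_combined,
        low_risk_combined_pct=100.0 * low_combined / n,
        high_risk_pct=100.0 * counts[RiskCategory.HIGH_RISK.value] / n,
        send_for_odx=counts[RiskCategory.INTERMEDIATE.value],
    )
    return calls, summary


def calls_to_frame(calls: Sequence[RommaCall]) -> pd.DataFrame:
    """Calls as a DataFrame (rationale joined with '; ')."""
    rows = []
    for call in calls:
        data = call.model_dump()
        data["category"] = call.category.value
        data["predicted_odx_band"] = call.predicted_odx_band.value
        data["rationale"] = "; ".join(call.rationale)
        rows.append(data)
    return pd.DataFrame(rows)
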