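"""Recurrence-outcome statistics.

Outcome analyses run at the patient level: a patient with multiple tumors
takes their highest-risk call. Strata (RoMMa categories, ODX bands, or
covariate levels) are summarized as recurrence counts and rates with
follow-up descriptives; covariate associations use 2x2 odds ratios with
Fisher exact p-values, and continuous covariates are compared between
outcome groups with Welch's unequal-variance t-test. Patients with unknown
or suspicious covariate status are excluded from that covariate's
denominator, never imputed.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .concordance import ContingencyTable2x2, DiagnosticMetrics, diagnostic_metrics

__all__ = [
    "StratumOutcome",
    "StratumReport",
    "OddsRatioResult",
    "WelchResult",
    "patient_level",
    "recurrence_by_stratum",
    "covariate_odds_ratio",
    "covariate_odds_ratio_from_counts",
    "group_mean_test",
]

_CATEGORY_RANK = {"lowest_risk": 0, "low_risk": 1, "intermediate": 2, "high_risk": 3}


class StratumOutcome(BaseModel):
    """Recurrence summary for one stratum."""

    label: str
    n_patients: int = Field(ge=0)
    n_recurred: int = Field(ge=0)
    rate: float
    mean_followup_years: Optional[float] = None
    followup_range: Optional[Tuple[float, float]] = None


class StratumReport(BaseModel):
    """Stratum outcomes plus the provenance of the filters applied."""

    filters_applied: List[str]
    n_input: int
    n_after_filters: int
    strata: List[StratumOutcome]


class OddsRatioResult(BaseModel):
    odds_ratio: float
    p_value: float
    ci95: Tuple[float, float]
    table: ContingencyTable2x2


class WelchResult(BaseModel):
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def patient_level(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse a case-level frame to one row per patient.

    Takes the highest-risk row per patient: by ``category`` rank when a
    category column is present, otherwise by the largest ``amms``.
    """
    if "patient_id" not in frame.columns:
        raise ValueError("frame must have a patient_id column")
    work = frame.copy()
    if "category" in work.columns:
        work["_rank"] = work["category"].map(_CATEGORY_RANK)
    elif "amms" in work.columns:
        work["_rank"] = work["amms"]
    else:
        raise ValueError("frame needs a category or amms column to rank tumors")
    work = work.sort_values("_rank", kind="stable").groupby("patient_id", sort=False).tail(1)
    return work.drop(columns="_rank").reset_index(drop=True)


Predicate = Callable[[pd.DataFrame], pd.Series]


def recurrence_by_stratum(
    patients: pd.DataFrame,
    strata: Sequence[Tuple[str, Predicate]],
    filters: Sequence[Tuple[str, Predicate]] = (),
) -> StratumReport:
    """Per-stratum recurrence counts and rates after explicit filters.

    ``strata`` and ``filters`` are (label, predicate) pairs; each predicate
    maps the patient frame to a boolean mask. Rows with a missing
    ``recurred`` value are dropped before stratification. An empty stratum
    is reported with zero counts, not raised.
    """
    n_input = len(patients)
    work = patients.dropna(subset=["recurred"]).copy()
    work["recurred"] = work["recurred"].astype(bool)
    applied = []
    for label, predicate in filters:
        work = work[np.asarray(predicate(work), dtype=bool)]
        applied.append(label)
    outcomes = []
    for label, predicate in strata:
        sub = work[np.asarray(predicate(work), dtype=bool)]
        n = len(sub)
        n_rec = int(sub["recurred"].sum())
        followup = sub["followup_years"].dropna() if "followup_years" in sub else pd.Series(dtype=float)
        outcomes.append(
            StratumOutcome(
                label=label,
                n_patients=n,
                n_recurred=n_rec,
                rate=n_rec / n if n else 0.0,
                mean_followup_years=float(followup.mean()) if len(followup) else None,
                followup_range=(
                    (float(followup.min()), float(followup.max())) if len(followup) else None
                ),
            )
        )
    return StratumReport(
        filters_applied=applied,
        n_input=n_input,
        n_after_filters=len(work),
        strata=outcomes,
    )


def covariate_odds_ratio_from_counts(
    recurred_with: int,
    recurred_total: int,
    not_recurred_with: int,
    not_recurred_total: int,
) -> OddsRatioResult:
    """Odds ratio for a binary covariate from group counts.

    ``recurred_with`` of ``recurred_total`` recurred patients carry the
    covariate, against ``not_recurred_with`` of ``not_recurred_total``
    patients without recurrence.
    """
    table = ContingencyTable2x2(
        tp=recurred_with,
        fp=recurred_total - recurred_with,
        fn=not_recurred_with,
        tn=not_recurred_total - not_recurred_with,
    )
    metrics = diagnostic_metrics(table)
    return OddsRatioResult(
        odds_ratio=metrics.odds_ratio,
        p_value=metrics.p_value,
        ci95=metrics.or_ci95,
        table=table,
    )


_POSITIVE_LEVELS = {True, "true", "identified", "positive", 1}
_NEGATIVE_LEVELS = {False, "false", "not_identified", "negative", 0}


def covariate_odds_ratio(
    patients: pd.DataFrame,
    covariate: str,
    outcome: str = "recurred",
) -> OddsRatioResult:
    """Odds ratio of a binary covariate for recurrence (Fisher exact p).

    Covariate levels outside the recognized positive/negative values
    (e.g. unknown or suspicious LVI) are excluded from the denominators.

    Raises
    ------
    ValueError
        If only one covariate level is present among evaluable patients.
    """
    work = patients.dropna(subset=[outcome, covariate])
    values = work[covariate]
    positive = values.isin(_POSITIVE_LEVELS)
    negative = values.isin(_NEGATIVE_LEVELS)
    work = work[positive | negative]
    if len(work) == 0 or work[covariate].isin(_POSITIVE_LEVELS).nunique() < 2:
        raise ValueError(f"covariate {covariate!r} has fewer than two levels")
    exposed = work[covariate].isin(_POSITIVE_LEVELS).to_numpy()
    recurred = work[outcome].astype(bool).to_numpy()
    return covariate_odds_ratio_from_counts(
        recurred_with=int(np.sum(exposed & recurred)),
        recurred_total=int(np.sum(recurred)),
        not_recurred_with=int(np.sum(exposed & ~recurred)),
        not_recurred_total=int(np.sum(~recurred)),
    )


def group_mean_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> WelchResult:
    """Welch two-sample t-test (unequal variances) between outcome groups.

    Raises
    ------
    ValueError
        If either group has fewer than two observations (named).
    """
    a = np.asarray(pd.Series(values_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(values_b).dropna(), dtype=float)
    for name, vec in (("first", a), ("second", b)):
        if vec.size < 2:
            raise ValueError(f"{name} group has fewer than two observations")
    result = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_statistic=float(result.statistic),
        p_value=float(result.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )
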