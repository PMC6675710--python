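"""Agreement between the average modified Magee score and Oncotype DX.

Three views of concordance:

* cumulative band-agreement tables (counts of ODX low / intermediate / high
  within nested amMs groups, with the percent falling in the concordant ODX
  category);
* 2x2 diagnostic accuracy of the rule "amMs <= t" against the reference
  "ODXRS < r" (sensitivity, specificity, PPV, NPV, odds ratio, Fisher exact
  p-value, Woolf 95% CI);
* per-case discordance labelling on the ODX risk bands (low < 18,
  intermediate 18-30, high > 30), flagging two-step (low <-> high) cases
  for review.

Distributional comparisons between two populations (Pearson correlation of
score-group frequencies, chi-squared independence on threshold splits) are
also provided.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .classifier import RommaThresholds

__all__ = [
    "OdxBands",
    "ContingencyTable2x2",
    "DiagnosticMetrics",
    "two_by_two",
    "diagnostic_metrics",
    "band_agreement_table",
    "band_agreement_from_counts",
    "agreement_percent",
    "discordance_report",
    "pearson_frequency_correlation",
    "chi2_independence",
]


class OdxBands(BaseModel):
    """Oncotype DX recurrence-score bands (they partition 0-100).

    low: ODXRS < ``low_upper``; intermediate: ``low_upper``-``high_lower``
    inclusive; high: > ``high_lower``. ``tailorx_upper`` is the TAILORx
    lower-risk boundary (< 26) and ``very_low_upper`` the classic low-risk
    boundary (< 11).
    """

    low_upper: int = 18
    high_lower: int = 30
    tailorx_upper: int = 26
    very_low_upper: int = 11

    @model_validator(mode="after")
    def _ordered(self) -> "OdxBands":
        if not (0 < self.very_low_upper <= self.low_upper <= self.tailorx_upper <= self.high_lower):
            raise ValueError("ODX band boundaries out of order")
        return self

    def band(self, odx_rs: float) -> str:
        if odx_rs < self.low_upper:
            return "low"
        if odx_rs > self.high_lower:
            return "high"
        return "intermediate"

    def band_index(self, odx_rs: float) -> int:
        return {"low": 0, "intermediate": 1, "high": 2}[self.band(odx_rs)]


class ContingencyTable2x2(BaseModel):
    """2x2 counts: rows = test condition, columns = reference condition."""

    tp: int = Field(ge=0)
    fp: int = Field(ge=0)
    fn: int = Field(ge=0)
    tn: int = Field(ge=0)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)


class DiagnosticMetrics(BaseModel):
    """Rates, odds ratio, and Fisher exact p for a 2x2 table.

    The odds ratio is the cross-product (tp*tn)/(fp*fn); with a zero off-
    diagonal cell it is reported as ``inf`` (or 0.0 when a diagonal cell is
    zero), never silently adjusted. The 95% CI uses the Woolf log method and
    is only finite when all four cells are positive.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    odds_ratio: float
    or_ci95: Tuple[float, float]
    p_value: float


def two_by_two(
    amms: Sequence[float],
    odx_rs: Sequence[float],
    amms_cutoff: float = 18.0,
    odx_cutoff: float = 26.0,
) -> ContingencyTable2x2:
    """Cross-tabulate the test "amMs <= cutoff" against "ODXRS < cutoff".

    Inputs are paired per case; pairs with a missing value are dropped.
    """
    amms = np.asarray(amms, dtype=float)
    odx = np.asarray(odx_rs, dtype=float)
    if amms.shape != odx.shape:
        raise ValueError("amms and odx_rs must be paired (equal length)")
    keep = ~(np.isnan(amms) | np.isnan(odx))
    amms, odx = amms[keep], odx[keep]
    if amms.size == 0:
        raise ValueError("no paired amMs/ODXRS observations")
    test = amms <= amms_cutoff
    ref = odx < odx_cutoff
    return ContingencyTable2x2(
        tp=int(np.sum(test & ref)),
        fp=int(np.sum(test & ~ref)),
        fn=int(np.sum(~test & ref)),
        tn=int(np.sum(~test & ~ref)),
    )


def _woolf_ci(table: ContingencyTable2x2) -> Tuple[float, float]:
    cells = (table.tp, table.fp, table.fn, table.tn)
    if any(cell == 0 for cell in cells):
        return (0.0, math.inf)
    log_or = math.log(table.tp * table.tn / (table.fp * table.fn))
    se = math.sqrt(sum(1.0 / cell for cell in cells))
    return (math.exp(log_or - 1.959963984540054 * se), math.exp(log_or + 1.959963984540054 * se))


def diagnostic_metrics(table: ContingencyTable2x2) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV, odds ratio, and Fisher exact p.

    Raises
    ------
    ValueError
        For an all-zero table or when a rate's denominator is zero.
    """
    if table.total == 0:
        raise ValueError("all-zero 2x2 table")
    for name, denom in (
        ("sensitivity", table.tp + table.fn),
        ("specificity", table.fp + table.tn),
        ("ppv", table.tp + table.fp),
        ("npv", table.fn + table.tn),
    ):
        if denom == 0:
            raise ValueError(f"zero denominator for {name}")
    if table.fp * table.fn > 0:
        odds_ratio = (table.tp * table.tn) / (table.fp * table.fn)
    elif table.tp * table.tn > 0:
        odds_ratio = math.inf
    else:
        odds_ratio = 0.0
    _, p_value = stats.fisher_exact(table.to_array(), alternative="two-sided")
    return DiagnosticMetrics(
        sensitivity=table.tp / (table.tp + table.fn),
        specificity=table.tn / (table.fp + table.tn),
        ppv=table.tp / (table.tp + table.fp),
        npv=table.tn / (table.fn + table.tn),
        odds_ratio=odds_ratio,
        or_ci95=_woolf_ci(table),
        p_value=float(p_value),
    )


def agreement_percent(
    n_high: int, n_intermediate: int, n_low: int, concordant_band: str = "low"
) -> float:
    """Percent of cases in the concordant ODX band (unrounded)."""
    counts = {"high": n_high, "intermediate": n_intermediate, "low": n_low}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty band-agreement group")
    return 100.0 * counts[concordant_band] / total


def _default_groups(thresholds: RommaThresholds):
    th = thresholds
    return [
        (f"amMs <{th.lowest_cutoff:g}", lambda a, c=th.lowest_cutoff: a < c),
        ("amMs <=10", lambda a: a <= 10),
        ("amMs <=11", lambda a: a <= 11),
        (f"amMs <={th.low_cutoff:g}", lambda a, c=th.low_cutoff: a <= c),
        ("amMs <=14", lambda a: a <= 14),
        ("amMs <=15", lambda a: a <= 15),
        (f"amMs <{th.odx26_cutoff:g}", lambda a, c=th.odx26_cutoff: a < c),
    ]


def band_agreement_table(
    frame: pd.DataFrame,
    bands: Optional[OdxBands] = None,
    thresholds: Optional[RommaThresholds] = None,
) -> pd.DataFrame:
    """Cumulative amMs groups x ODX category counts with percent agreement.

    ``frame`` needs ``amms`` and ``odx_rs`` columns; when the histology
    columns (``nottingham_score``, ``er_h_score``, ``pr_h_score``,
    ``ki67_pct``) are present, a histologic-criteria row is added. Groups
    are nested (each contains the previous), plus the high-risk
    ``amMs > 30`` row, whose concordant band is ODX high instead of low.
    Cases without an ODXRS are excluded; the count is in
    ``result.attrs["n_excluded"]``.
    """
    bands = bands or OdxBands()
    th = thresholds or RommaThresholds()
    usable = frame.dropna(subset=["amms", "odx_rs"])
    n_excluded = len(frame) - len(usable)
    amms = usable["amms"].to_numpy(dtype=float)
    odx_band = np.array([bands.band(value) for value in usable["odx_rs"]])

    rows = []

    def add_row(label: str, mask: np.ndarray, concordant: str) -> None:
        n_high = int(np.sum(mask & (odx_band == "high")))
        n_int = int(np.sum(mask & (odx_band == "intermediate")))
        n_low = int(np.sum(mask & (odx_band == "low")))
        total = n_high + n_int + n_low
        pct = (
            agreement_percent(n_high, n_int, n_low, concordant) if total else math.nan
        )
        rows.append(
            {
                "group": label,
                "n_high": n_high,
                "n_intermediate": n_int,
                "n_low": n_low,
                "concordant_band": concordant,
                "percent_concordant": pct,
            }
        )

    for label, rule in _default_groups(th):
        add_row(label, rule(amms), "low")

    histology_columns = {"nottingham_score", "er_h_score", "pr_h_score", "ki67_pct"}
    if histology_columns <= set(usable.columns):
        hist_mask = (
            (usable["nottingham_score"].to_numpy(dtype=float) < th.histologic_ns_max)
            & (usable["er_h_score"].to_numpy(dtype=float) >= th.histologic_h_min)
            & (usable["pr_h_score"].to_numpy(dtype=float) >= th.histologic_h_min)
            & (usable["ki67_pct"].to_numpy(dtype=float) < th.histologic_ki67_max)
        )
        add_row("histologic low risk", np.asarray(hist_mask), "low")

    add_row(f"amMs >{th.high_cutoff:g}", amms > th.high_cutoff, "high")

    result = pd.DataFrame(rows)
    result.attrs["n_excluded"] = n_excluded
    return result


def band_agreement_from_counts(
    rows: Sequence[Tuple[str, int, int, int]],
) -> pd.DataFrame:
    """Band-agreement table from already-tabulated (label, high, int, low) counts.

    The concordant band is ODX low for every group except labels containing
    ``>``, which are high-risk groups concordant with ODX high.
    """
    out = []
    for label, n_high, n_int, n_low in rows:
        concordant = "high" if ">" in label else "low"
        out.append(
            {
                "group": label,
                "n_high": n_high,
                "n_intermediate": n_int,
                "n_low": n_low,
                "concordant_band": concordant,
                "percent_concordant": agreement_percent(n_high, n_int, n_low, concordant),
            }
        )
    return pd.DataFrame(out)


def discordance_report(
    frame: pd.DataFrame, bands: Optional[OdxBands] = None
) -> pd.DataFrame:
    """Label each case concordant / one_step / two_step on the ODX risk bands.

    Both the amMs and the ODXRS are banded with the ODX criteria (< 18 low,
    18-30 intermediate, > 30 high); the step count is the band distance, so
    two-step means low on one score and high on the other. The full input
    row is echoed for two-step cases via the returned frame's index.
    """
    bands = bands or OdxBands()
    usable = frame.dropna(subset=["amms", "odx_rs"]).copy()
    usable["amms_band"] = [bands.band(value) for value in usable["amms"]]
    usable["odx_band"] = [bands.band(value) for value in usable["odx_rs"]]
    steps = np.abs(
        np.array([bands.band_index(value) for value in usable["amms"]])
        - np.array([bands.band_index(value) for value in usable["odx_rs"]])
    )
    usable["steps"] = steps
    usable["discordance"] = np.select(
        [steps == 0, steps == 1], ["concordant", "one_step"], default="two_step"
    )
    return usable


def pearson_frequency_correlation(
    freq_a: Sequence[float], freq_b: Sequence[float]
) -> Tuple[float, float]:
    """Pearson r (with p-value) between two equal-length frequency vectors.

    Raises
    ------
    ValueError
        On length mismatch or a zero-variance vector (named).
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors must have equal length")
    for name, vec in (("first", a), ("second", b)):
        if np.ptp(vec) == 0:
            raise ValueError(f"{name} frequency vector has zero variance")
    result = stats.pearsonr(a, b)
    return float(result.statistic), float(result.pvalue)


def chi2_independence(
    table: Union[ContingencyTable2x2, np.ndarray, Sequence[Sequence[int]]],
    correction: bool = False,
) -> Tuple[float, int, float]:
    """Chi-squared test of independence on a count table: (chi2, df, p).

    Yates continuity correction is off by default (the uncorrected statistic
    is the conventional choice for the large tables used here).
    """
    if isinstance(table, ContingencyTable2x2):
        table = table.to_array()
    result = stats.chi2_contingency(np.asarray(table), correction=correction)
    return float(result.statistic), int(result.dof), float(result.pvalue)
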