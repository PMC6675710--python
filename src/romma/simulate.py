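"""Synthetic cohort generation.

Generates ER-positive breast cancer cohorts with the statistical structure
the downstream analyses assume, so every stage of the pipeline is testable
without patient data:

* RoMMa stratum frequencies are hit by construction: each case first draws
  a target stratum (low ~20.8%, high ~2.8%, the remainder intermediate,
  with a sub-fraction of low-risk cases qualifying only histologically),
  then pathology inputs are rejection-sampled from stratum-appropriate
  distributions until the resulting amMs (computed with the real equations
  on the equations actually computable for that case) lands in the stratum.
* The ODX recurrence score follows a linear-Gaussian link to the amMs,
  clipped to 0-100 and rounded to an integer.
* Recurrence is Bernoulli with a logistic model on Ki-67 (+), PR H-score
  (-), node positivity (+), and LVI (+).
* Ki-67 and tumor size are missing at the observed availability rates
  (5.9% and 0.3%); missingness is drawn before band acceptance so stratum
  frequencies are unaffected, and the two are never missing together
  (which would leave no computable equation).

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .classifier import RommaThresholds, _histologic
from .data_model import CaseRecord, FishResult, LviStatus, LymphNodeStatus
from .magee import EquationSpec, average_magee, load_equation_specs

__all__ = [
    "ScoreLink",
    "OutcomeModel",
    "StratumTargets",
    "CohortSpec",
    "LinkEstimate",
    "generate",
    "generate_frame",
    "recover_link",
]


class ScoreLink(BaseModel):
    """Linear-plus-noise map from amMs to ODXRS: odx = slope*amMs + intercept + N(0, sd)."""

    slope: float = 1.1
    intercept: float = 0.0
    noise_sd: float = Field(default=4.0, gt=0)


class OutcomeModel(BaseModel):
    """Logistic recurrence model: higher Ki-67, lower PR, LN+ and LVI raise risk."""

    intercept: float = -3.2
    ki67_coef: float = 0.04     # per Ki-67 percentage point
    pr_coef: float = -0.004     # per PR H-score unit
    ln_coef: float = 0.7        # node-positive indicator
    lvi_coef: float = 1.8       # LVI-identified indicator


class StratumTargets(BaseModel):
    """Target RoMMa stratum frequencies (remainder is intermediate)."""

    low: float = Field(default=0.208, ge=0, le=1)
    high: float = Field(default=0.028, ge=0, le=1)
    #: fraction of low-risk cases qualifying only via histologic criteria
    histologic_only_frac: float = Field(default=0.15, ge=0, le=1)

    @model_validator(mode="after")
    def _partition(self) -> "StratumTargets":
        if self.low + self.high > 1:
            raise ValueError("low + high must not exceed 1")
        return self


class CohortSpec(BaseModel):
    """Parameters of a synthetic cohort."""

    n_cases: int = Field(gt=0)
    seed: int = 0
    targets: StratumTargets = StratumTargets()
    score_link: ScoreLink = ScoreLink()
    outcome_model: OutcomeModel = OutcomeModel()
    ki67_missing_rate: float = Field(default=0.059, ge=0, le=1)
    size_missing_rate: float = Field(default=0.003, ge=0, le=1)


class LinkEstimate(BaseModel):
    """OLS recovery of the score link from a generated cohort."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    residual_sd: float
    n: int


_MAX_TRIES = 400


def _sample_low(rng: np.random.Generator) -> dict:
    return {
        "nottingham_score": int(rng.choice([3, 4, 5], p=[0.3, 0.45, 0.25])),
        "er_h_score": int(rng.integers(200, 301)),
        "pr_h_score": int(rng.integers(150, 301)),
        "ki67_pct": float(np.round(rng.uniform(1, 12), 1)),
        "tumor_size_cm": float(np.round(rng.lognormal(0.2, 0.4), 1) or 0.1),
        "her2_ihc": int(rng.choice([0, 1, 2], p=[0.3, 0.55, 0.15])),
    }


def _sample_histologic_only(rng: np.random.Generator) -> dict:
    return {
        "nottingham_score": int(rng.choice([4, 5], p=[0.35, 0.65])),
        "er_h_score": int(rng.integers(150, 240)),
        "pr_h_score": int(rng.integers(150, 220)),
        "ki67_pct": float(np.round(rng.uniform(3, 9.9), 1)),
        "tumor_size_cm": float(np.round(rng.lognormal(0.5, 0.35), 1) or 0.1),
        "her2_ihc": int(rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25])),
    }


def _sample_intermediate(rng: np.random.Generator) -> dict:
    return {
        "nottingham_score": int(rng.choice([5, 6, 7, 8], p=[0.2, 0.35, 0.3, 0.15])),
        "er_h_score": int(rng.integers(80, 301)),
        "pr_h_score": int(rng.integers(0, 301)),
        "ki67_pct": float(np.round(rng.uniform(5, 45), 1)),
        "tumor_size_cm": float(np.round(rng.lognormal(0.5, 0.45), 1) or 0.1),
        "her2_ihc": int(rng.choice([0, 1, 2], p=[0.28, 0.45, 0.27])),
    }


def _sample_high(rng: np.random.Generator) -> dict:
    return {
        "nottingham_score": int(rng.choice([7, 8, 9], p=[0.2, 0.45, 0.35])),
        "er_h_score": int(rng.integers(10, 180)),
        "pr_h_score": int(rng.integers(0, 80)),
        "ki67_pct": float(np.round(rng.uniform(30, 85), 1)),
        "tumor_size_cm": float(np.round(rng.lognormal(0.8, 0.4), 1) or 0.1),
        "her2_ihc": int(rng.choice([1, 2, 3], p=[0.45, 0.3, 0.25])),
    }


_SAMPLERS = {
    "low_scored": _sample_low,
    "low_histologic": _sample_histologic_only,
    "intermediate": _sample_intermediate,
    "high": _sample_high,
}


def _finish_her2(inputs: dict, rng: np.random.Generator, amplified_p: float) -> dict:
    # reflex FISH on every equivocal IHC, as in routine practice
    if inputs["her2_ihc"] == 2:
        inputs["her2_fish"] = (
            FishResult.AMPLIFIED if rng.random() < amplified_p else FishResult.NOT_AMPLIFIED
        )
    return inputs


def _in_stratum(
    stratum: str,
    amms: float,
    record: CaseRecord,
    thresholds: RommaThresholds,
) -> bool:
    hist, _ = _histologic(record, thresholds)
    if stratum == "low_scored":
        return amms <= thresholds.low_cutoff
    if stratum == "low_histologic":
        return hist and amms > thresholds.low_cutoff and amms <= thresholds.high_cutoff
    if stratum == "intermediate":
        return (
            thresholds.low_cutoff < amms <= thresholds.high_cutoff and not hist
        )
    return amms > thresholds.high_cutoff


def _draw_case(
    index: int,
    stratum: str,
    spec: CohortSpec,
    specs: Sequence[EquationSpec],
    thresholds: RommaThresholds,
    rng: np.random.Generator,
) -> Tuple[CaseRecord, float]:
    ki67_missing = rng.random() < spec.ki67_missing_rate
    size_missing = (not ki67_missing) and rng.random() < spec.size_missing_rate
    amplified_p = 0.35 if stratum == "high" else 0.05
    sampler = _SAMPLERS[stratum]
    best: Optional[Tuple[CaseRecord, float]] = None
    for _ in range(_MAX_TRIES):
        inputs = _finish_her2(sampler(rng), rng, amplified_p)
        if ki67_missing:
            inputs.pop("ki67_pct")
        if size_missing:
            inputs.pop("tumor_size_cm")
        record = CaseRecord(
            case_id=f"SYN-{index:05d}", patient_id=f"PT-{index:05d}", **inputs
        )
        amms = average_magee(record, specs).average_score
        if _in_stratum(stratum, amms, record, thresholds):
            return record, amms
        if best is None:
            best = (record, amms)
    # Rejection budget exhausted (essentially unreachable with the default
    # samplers); fall back to the first draw rather than looping forever.
    assert best is not None
    return best


def _outcome_probability(record: CaseRecord, model: OutcomeModel) -> float:
    ki67 = record.ki67_pct if record.ki67_pct is not None else 15.0
    logit = (
        model.intercept
        + model.ki67_coef * ki67
        + model.pr_coef * record.pr_h_score
        + model.ln_coef * (record.ln_status is LymphNodeStatus.POSITIVE)
        + model.lvi_coef * (record.lvi_status is LviStatus.IDENTIFIED)
    )
    return 1.0 / (1.0 + math.exp(-logit))


_LN_POSITIVE_P = {"low_scored": 0.08, "low_histologic": 0.08, "intermediate": 0.16, "high": 0.30}
_LVI_P = {"low_scored": 0.04, "low_histologic": 0.04, "intermediate": 0.12, "high": 0.30}
_CHEMO_P = {"low_scored": 0.05, "low_histologic": 0.05, "intermediate": 0.20, "high": 0.70}


def generate(spec: CohortSpec) -> List[CaseRecord]:
    """Generate a cohort of complete case records (with ODXRS and outcomes)."""
    rng = np.random.default_rng(spec.seed)
    equation_specs = load_equation_specs()
    thresholds = RommaThresholds()
    t = spec.targets
    probabilities = [
        t.low * (1 - t.histologic_only_frac),
        t.low * t.histologic_only_frac,
        1 - t.low - t.high,
        t.high,
    ]
    strata = rng.choice(
        ["low_scored", "low_histologic", "intermediate", "high"],
        size=spec.n_cases,
        p=probabilities,
    )
    records = []
    for index, stratum in enumerate(strata):
        record, amms = _draw_case(
            index, str(stratum), spec, equation_specs, thresholds, rng
        )
        odx = spec.score_link.slope * amms + spec.score_link.intercept
        odx += rng.normal(0.0, spec.score_link.noise_sd)
        record.odx_rs = int(np.clip(round(odx), 0, 100))

        ln_roll = rng.random()
        if ln_roll < _LN_POSITIVE_P[str(stratum)]:
            record.ln_status = LymphNodeStatus.POSITIVE
        elif ln_roll < _LN_POSITIVE_P[str(stratum)] + 0.05:
            record.ln_status = LymphNodeStatus.UNKNOWN
        else:
            record.ln_status = LymphNodeStatus.NEGATIVE
        lvi_roll = rng.random()
        if lvi_roll < _LVI_P[str(stratum)]:
            record.lvi_status = LviStatus.IDENTIFIED
        elif lvi_roll < _LVI_P[str(stratum)] + 0.01:
            record.lvi_status = LviStatus.SUSPICIOUS
        elif lvi_roll < _LVI_P[str(stratum)] + 0.03:
            record.lvi_status = LviStatus.UNKNOWN
        else:
            record.lvi_status = LviStatus.NOT_IDENTIFIED

        record.age_years = int(np.clip(round(rng.normal(59, 12)), 25, 90))
        record.followup_years = float(np.round(rng.uniform(5, 11), 1))
        record.hormonal_therapy = bool(rng.random() < 0.8)
        record.chemotherapy = bool(rng.random() < _CHEMO_P[str(stratum)])
        record.radiation = bool(rng.random() < 0.5)
        record.recurred = bool(
            rng.random() < _outcome_probability(record, spec.outcome_model)
        )
        records.append(record)
    return records


def generate_frame(spec: CohortSpec) -> pd.DataFrame:
    """Generated cohort as a DataFrame with the amMs attached."""
    from .data_model import records_to_frame
    from .magee import score_cohort

    records = generate(spec)
    frame = records_to_frame(records)
    results = score_cohort(records)
    frame["amms"] = [result.average_score for result in results]
    frame["n_equations_used"] = [result.n_equations_used for result in results]
    return frame


def recover_link(amms: Sequence[float], odx_rs: Sequence[float]) -> LinkEstimate:
    """Least-squares recovery of the score link's slope and intercept.

    Raises
    ------
    ValueError
        With fewer than three paired observations.
    """
    x = np.asarray(amms, dtype=float)
    y = np.asarray(odx_rs, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    fit = stats.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    return LinkEstimate(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        residual_sd=float(np.std(residuals, ddof=2)),
        n=int(x.size),
    )
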