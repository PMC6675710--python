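"""Avoided-test cost modeling.

Cases triaged as low or high risk by RoMMa do not need send-out Oncotype DX
testing; the avoided tests translate into dollar savings at the list price
of the assay. The institutional computation is exact integer-cent
arithmetic; the national extrapolation scales the institutional low- and
high-risk fractions to the annual volume of ODX breast-cancer reports,
keeping the unrounded avoidable-case count in the dollar computation and
rounding only the final figure.
"""

from __future__ import annotations

from decimal import Decimal
from typing import Union

from pydantic import BaseModel, Field, model_validator

__all__ = ["CostScenario", "NationalSavings", "institutional_savings", "national_extrapolation"]


class CostScenario(BaseModel):
    """Parameters of the cost-avoidance calculation.

    Defaults: assay list price $4,620 (2017 annual-report figure), 126,740
    annual test reports of which ~85% are invasive breast carcinoma, and the
    triage fractions 20.8% low risk / 2.8% high risk.
    """

    list_price_usd: float = Field(default=4620.0, gt=0)
    cohort_n: int = Field(default=903, ge=0)
    frac_low: float = Field(default=0.208, ge=0, le=1)
    frac_high: float = Field(default=0.028, ge=0, le=1)
    national_reports: int = Field(default=126740, ge=0)
    breast_fraction: float = Field(default=0.85, ge=0, le=1)

    @model_validator(mode="after")
    def _fractions(self) -> "CostScenario":
        if self.frac_low + self.frac_high > 1:
            raise ValueError("frac_low + frac_high must not exceed 1")
        return self


class NationalSavings(BaseModel):
    candidate_pool: int
    n_avoidable: int
    savings_usd: int


def institutional_savings(
    n_avoided: int, list_price_usd: Union[float, Decimal] = 4620.0
) -> float:
    """Dollar savings from ``n_avoided`` tests at list price (exact to the cent)."""
    if n_avoided < 0:
        raise ValueError("n_avoided must be non-negative")
    cents = int((Decimal(str(list_price_usd)) * 100).to_integral_value())
    return (cents * n_avoided) / 100.0


def national_extrapolation(scenario: CostScenario) -> NationalSavings:
    """Extrapolate institutional triage fractions to national test volume.

    candidate_pool = round(national_reports * breast_fraction);
    n_avoidable = round(candidate_pool * (frac_low + frac_high));
    savings keeps the unrounded avoidable count in the product and rounds
    the final dollar amount.
    """
    candidate_pool = round(scenario.national_reports * scenario.breast_fraction)
    frac = scenario.frac_low + scenario.frac_high
    avoidable_exact = candidate_pool * frac
    return NationalSavings(
        candidate_pool=candidate_pool,
        n_avoidable=round(avoidable_exact),
        savings_usd=round(avoidable_exact * scenario.list_price_usd),
    )
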