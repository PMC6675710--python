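"""Modified Magee equation scoring.

The Magee equations are published linear regressions that predict the
Oncotype DX recurrence score from routine pathology variables: Nottingham
score, ER and PR H-scores, HER-2 status, Ki-67 percentage, and tumor size.
Each equation uses a different subset of predictors, so a case with a
missing Ki-67 or tumor size can still be scored by the equations that do
not require it. The average of the computable equation scores (the amMs,
average modified Magee score) is the central statistic of the RoMMa
triage algorithm.

Coefficients are never hard-coded: they live in a YAML config
(``romma/data/magee_equations.yaml`` by default, transcribed from the
public Magee-equation calculator) so the arithmetic stays auditable and
upgradable.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .data_model import CaseRecord, Her2Status, MissingFieldError, normalize_her2

__all__ = [
    "PREDICTOR_NAMES",
    "EquationSpec",
    "MageeResult",
    "UnscorableCaseError",
    "score_equation",
    "average_magee",
    "load_equation_specs",
    "save_equation_specs",
    "score_cohort",
]

#: Predictors an equation may reference. ``her2_term`` is the status-mapped
#: HER-2 contribution; the others are read directly off the case record.
PREDICTOR_NAMES = frozenset(
    {
        "nottingham_score",
        "er_h_score",
        "pr_h_score",
        "her2_term",
        "tumor_size_cm",
        "ki67_pct",
    }
)

EQUATION_IDS = ("eq1", "eq2", "eq3")


class UnscorableCaseError(ValueError):
    """No Magee equation is computable for a case."""


class EquationSpec(BaseModel):
    """One linear equation: intercept + sum(coefficient * predictor).

    ``her2_term_values`` maps the resolved HER-2 status to the additive term
    the equation uses for it; the ``her2_term`` coefficient (conventionally
    1.0) multiplies that value.
    """

    equation_id: str
    intercept: float
    coefficients: Dict[str, float]
    her2_term_values: Optional[Dict[Her2Status, float]] = None
    required_predictors: Set[str]

    @field_validator("equation_id")
    @classmethod
    def _known_id(cls, value: str) -> str:
        if value not in EQUATION_IDS:
            raise ValueError(f"equation_id must be one of {EQUATION_IDS}, got {value!r}")
        return value

    @model_validator(mode="after")
    def _check_predictors(self) -> "EquationSpec":
        unknown = set(self.coefficients) - PREDICTOR_NAMES
        if unknown:
            raise ValueError(f"unknown predictors in coefficients: {sorted(unknown)}")
        stray = self.required_predictors - set(self.coefficients)
        if stray:
            raise ValueError(
                f"required_predictors not among coefficients: {sorted(stray)}"
            )
        if "her2_term" in self.coefficients:
            if self.her2_term_values is None or set(self.her2_term_values) != set(
                Her2Status
            ):
                raise ValueError(
                    "her2_term_values must be defined for all three HER-2 statuses"
                )
        return self


class MageeResult(BaseModel):
    """Per-equation scores and their average (amMs) for one case.

    ``per_equation_scores`` holds ``None`` for equations that were not
    computable; ``average_score`` is the arithmetic mean of the computable
    scores, carried unrounded (display rounds to one decimal).
    """

    case_id: str
    per_equation_scores: Dict[str, Optional[float]]
    average_score: float
    n_equations_used: int = Field(ge=1)
    missing_inputs: Set[str] = set()


def _predictor_value(record: CaseRecord, name: str, spec: EquationSpec) -> Optional[float]:
    if name == "her2_term":
        try:
            status = record.her2_status()
        except MissingFieldError:
            return None
        if status is Her2Status.EQUIVOCAL:
            # unresolved equivocal (IHC 2+ without FISH): not scorable
            return None
        return spec.her2_term_values[status]
    value = getattr(record, name)
    return None if value is None else float(value)


def score_equation(record: CaseRecord, spec: EquationSpec) -> Optional[float]:
    """Evaluate one equation for one case.

    Returns ``None`` ("not computable") iff a required predictor is missing
    or the HER-2 status is an unresolved equivocal. Optional predictors that
    are missing simply contribute nothing.
    """
    total = spec.intercept
    for name, coefficient in spec.coefficients.items():
        value = _predictor_value(record, name, spec)
        if value is None:
            if name in spec.required_predictors:
                return None
            continue
        total += coefficient * value
    return total


def _missing_required(record: CaseRecord, spec: EquationSpec) -> Set[str]:
    return {
        name
        for name in spec.required_predictors
        if _predictor_value(record, name, spec) is None
    }


def average_magee(record: CaseRecord, specs: Sequence[EquationSpec]) -> MageeResult:
    """Average modified Magee score: mean over the computable equations.

    Raises
    ------
    UnscorableCaseError
        If no equation is computable, naming the missing inputs.
    """
    per_equation = {spec.equation_id: score_equation(record, spec) for spec in specs}
    computable = [score for score in per_equation.values() if score is not None]
    missing = set()
    for spec in specs:
        if per_equation[spec.equation_id] is None:
            missing |= _missing_required(record, spec)
    if not computable:
        raise UnscorableCaseError(
            f"case {record.case_id}: no Magee equation computable "
            f"(missing inputs: {sorted(missing)})"
        )
    return MageeResult(
        case_id=record.case_id,
        per_equation_scores=per_equation,
        average_score=sum(computable) / len(computable),
        n_equations_used=len(computable),
        missing_inputs=missing,
    )


def _spec_from_mapping(entry: dict) -> EquationSpec:
    entry = dict(entry)
    h2 = entry.get("her2_term_values")
    if h2 is not None:
        entry["her2_term_values"] = {Her2Status(k): float(v) for k, v in h2.items()}
    entry["required_predictors"] = set(entry.get("required_predictors", []))
    return EquationSpec.model_validate(entry)


def load_equation_specs(
    path: Optional[Union[str, Path]] = None,
) -> Tuple[EquationSpec, EquationSpec, EquationSpec]:
    """Load the three equation specs from YAML (the packaged default if no path).

    The config must define exactly the equations eq1, eq2, eq3; they are
    returned in that order.
    """
    if path is None:
        text = (resources.files("romma.data") / "magee_equations.yaml").read_text()
    else:
        text = Path(path).read_text()
    config = yaml.safe_load(text)
    if not isinstance(config, dict) or "equations" not in config:
        raise ValueError("equation config must be a mapping with an 'equations' list")
    specs = {}
    for entry in config["equations"]:
        spec = _spec_from_mapping(entry)
        if spec.equation_id in specs:
            raise ValueError(f"duplicate equation_id {spec.equation_id!r}")
        specs[spec.equation_id] = spec
    if set(specs) != set(EQUATION_IDS):
        raise ValueError(f"config must define exactly {EQUATION_IDS}, got {sorted(specs)}")
    return tuple(specs[eq] for eq in EQUATION_IDS)  # type: ignore[return-value]


def save_equation_specs(
    specs: Sequence[EquationSpec], path: Union[str, Path], version: str = "custom"
) -> None:
    """Serialize equation specs to YAML so they round-trip via ``load_equation_specs``."""
    entries = []
    for spec in specs:
        entry = {
            "equation_id": spec.equation_id,
            "intercept": spec.intercept,
            "coefficients": dict(spec.coefficients),
            "required_predictors": sorted(spec.required_predictors),
        }
        if spec.her2_term_values is not None:
            entry["her2_term_values"] = {
                status.value: value for status, value in spec.her2_term_values.items()
            }
        entries.append(entry)
    Path(path).write_text(
        yaml.safe_dump({"version": version, "equations": entries}, sort_keys=False)
    )


def score_cohort(
    records: Sequence[CaseRecord],
    specs: Optional[Sequence[EquationSpec]] = None,
    on_unscorable: str = "raise",
) -> List[MageeResult]:
    """Score every case in a cohort (order-independent, deterministic).

    ``on_unscorable`` is ``"raise"`` or ``"skip"``.
    """
    if on_unscorable not in ("raise", "skip"):
        raise ValueError("on_unscorable must be 'raise' or 'skip'")
    if specs is None:
        specs = load_equation_specs()
    results = []
    for record in records:
        try:
            results.append(average_magee(record, specs))
        except UnscorableCaseError:
            if on_unscorable == "raise":
                raise
    return results
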