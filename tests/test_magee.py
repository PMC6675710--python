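"""Magee equation evaluation, averaging, and config handling."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from romma.data_model import Her2Status
from romma.magee import (
    EquationSpec,
    UnscorableCaseError,
    average_magee,
    load_equation_specs,
    save_equation_specs,
    score_cohort,
    score_equation,
)
from .conftest import make_record

ZERO_HER2 = {
    Her2Status.NEGATIVE: 0.0,
    Her2Status.EQUIVOCAL: 0.0,
    Her2Status.POSITIVE: 0.0,
}


def flat_spec(equation_id="eq1", intercept=0.0, coefficient=1.0, required=None):
    names = ["nottingham_score", "er_h_score", "pr_h_score", "her2_term",
             "tumor_size_cm", "ki67_pct"]
    return EquationSpec(
        equation_id=equation_id,
        intercept=intercept,
        coefficients={name: coefficient for name in names},
        her2_term_values=ZERO_HER2,
        required_predictors=set(required if required is not None else names),
    )


class TestScoreEquation:
    def test_constant_equation(self):
        spec = flat_spec(intercept=17.5, coefficient=0.0)
        assert score_equation(make_record(), spec) == 17.5

    def test_unit_coefficients_sum_the_predictors(self):
        record = make_record(nottingham_score=7, er_h_score=200, pr_h_score=100,
                             her2_ihc=1, ki67_pct=20.0, tumor_size_cm=2.0)
        assert score_equation(record, flat_spec()) == pytest.approx(329.0)

    def test_missing_required_predictor_not_computable(self):
        assert score_equation(make_record(ki67_pct=None), flat_spec()) is None

    def test_missing_optional_predictor_contributes_nothing(self):
        spec = flat_spec(required=["nottingham_score"])
        record = make_record(nottingham_score=7, ki67_pct=None)
        assert score_equation(record, spec) == pytest.approx(329.0 - 20.0)

    def test_unresolved_equivocal_her2_not_computable(self):
        assert score_equation(make_record(her2_ihc=2), flat_spec()) is None

    @given(
        delta=st.floats(min_value=-50, max_value=50),
        predictor=st.sampled_from(["ki67_pct", "tumor_size_cm", "er_h_score"]),
    )
    def test_linearity_in_each_predictor(self, specs, delta, predictor):
        spec = specs[0]
        base = {"ki67_pct": 50.0, "tumor_size_cm": 60.0, "er_h_score": 150}
        record_a = make_record(**base)
        shifted = dict(base)
        shifted[predictor] = base[predictor] + delta
        if predictor == "er_h_score":
            shifted[predictor] = int(shifted[predictor])
            delta = shifted[predictor] - base[predictor]
        record_b = make_record(**shifted)
        if shifted["tumor_size_cm"] <= 0:
            return
        observed = score_equation(record_b, spec) - score_equation(record_a, spec)
        assert observed == pytest.approx(spec.coefficients[predictor] * delta, abs=1e-9)


class TestAverageMagee:
    def scores_record(self, specs, record):
        return average_magee(record, specs)

    def test_mean_of_three(self):
        specs = [flat_spec("eq1", 10, 0.0), flat_spec("eq2", 14, 0.0),
                 flat_spec("eq3", 18, 0.0)]
        result = average_magee(make_record(), specs)
        assert result.average_score == pytest.approx(14.0)
        assert result.n_equations_used == 3

    def test_mean_over_computable_subset(self):
        specs = [flat_spec("eq1", 0, 1.0, required=["ki67_pct"]),
                 flat_spec("eq2", 20, 0.0, required=[]),
                 flat_spec("eq3", 22, 0.0, required=[])]
        result = average_magee(make_record(ki67_pct=None), specs)
        assert result.average_score == pytest.approx(21.0)
        assert result.n_equations_used == 2
        assert result.per_equation_scores["eq1"] is None
        assert "ki67_pct" in result.missing_inputs

    def test_idempotent_mean(self):
        specs = [flat_spec(eq, 9, 0.0) for eq in ("eq1", "eq2", "eq3")]
        assert average_magee(make_record(), specs).average_score == 9.0

    def test_average_within_min_max_of_equations(self, specs):
        result = average_magee(make_record(), specs)
        computable = [s for s in result.per_equation_scores.values() if s is not None]
        assert min(computable) <= result.average_score <= max(computable)

    def test_unscorable_case_names_missing_inputs(self, specs):
        record = make_record(ki67_pct=None, tumor_size_cm=None)
        with pytest.raises(UnscorableCaseError, match="ki67_pct"):
            average_magee(record, specs)

    def test_missing_size_disqualifies_only_size_equations(self, specs):
        result = average_magee(make_record(tumor_size_cm=None), specs)
        assert result.per_equation_scores["eq1"] is None
        assert result.per_equation_scores["eq2"] is None
        assert result.per_equation_scores["eq3"] is not None
        assert result.n_equations_used == 1


class TestEquationConfig:
    def test_default_config_ships_three_full_specs(self, specs):
        assert tuple(s.equation_id for s in specs) == ("eq1", "eq2", "eq3")
        for spec in specs:
            assert len(spec.coefficients) >= 4
            assert set(spec.her2_term_values) == set(Her2Status)

    def test_unknown_predictor_is_a_schema_error(self):
        with pytest.raises(ValueError, match="grade4"):
            EquationSpec(
                equation_id="eq1",
                intercept=0.0,
                coefficients={"grade4": 1.0},
                required_predictors=set(),
            )

    def test_her2_term_requires_status_map(self):
        with pytest.raises(ValueError, match="her2_term_values"):
            EquationSpec(
                equation_id="eq1",
                intercept=0.0,
                coefficients={"her2_term": 1.0},
                required_predictors={"her2_term"},
            )

    def test_round_trip(self, specs, tmp_path):
        path = tmp_path / "eqs.yaml"
        save_equation_specs(specs, path)
        assert load_equation_specs(path) == specs

    def test_malformed_config_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("equations:\n  - equation_id: eq9\n    intercept: 0\n")
        with pytest.raises(ValueError):
            load_equation_specs(path)


def test_cohort_scoring_is_order_independent(specs):
    records = [
        make_record(case_id=f"c{i}", ki67_pct=float(5 + 7 * i), er_h_score=30 * i)
        for i in range(8)
    ]
    forward = {r.case_id: r.average_score for r in score_cohort(records, specs)}
    shuffled = list(records)
    random.Random(3).shuffle(shuffled)
    backward = {r.case_id: r.average_score for r in score_cohort(shuffled, specs)}
    assert forward == backward
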