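"""Band agreement, 2x2 diagnostic accuracy, discordance, distribution tests."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from romma.concordance import (
    ContingencyTable2x2,
    OdxBands,
    band_agreement_from_counts,
    band_agreement_table,
    chi2_independence,
    diagnostic_metrics,
    discordance_report,
    pearson_frequency_correlation,
    two_by_two,
)
from romma.reference_data import (
    ORIGINAL_BAND_COUNTS,
    TOTAL_POPULATION_2X2,
    VALIDATION_BAND_COUNTS,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denominator = math.comb(n, c1)

    def probability(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denominator

    observed = probability(a)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    return sum(p for p in (probability(x) for x in support) if p <= observed * (1 + 1e-9))


class TestDiagnosticMetrics:
    def test_published_total_population_table(self):
        metrics = diagnostic_metrics(ContingencyTable2x2(**TOTAL_POPULATION_2X2))
        assert round(metrics.ppv, 3) == 0.976
        assert round(metrics.npv, 3) == 0.363
        assert round(metrics.sensitivity, 3) == 0.692
        assert round(metrics.specificity, 3) == 0.911
        assert round(metrics.odds_ratio, 1) == 23.0
        assert metrics.p_value < 0.0001
        lo, hi = metrics.or_ci95
        assert lo < 23.0 < hi

    def test_symmetric_table(self):
        metrics = diagnostic_metrics(ContingencyTable2x2(tp=4, fp=4, fn=4, tn=4))
        assert metrics.odds_ratio == 1.0
        assert (metrics.sensitivity, metrics.specificity, metrics.ppv, metrics.npv) == (
            0.5, 0.5, 0.5, 0.5,
        )

    def test_zero_off_diagonal_reports_infinite_or(self):
        metrics = diagnostic_metrics(ContingencyTable2x2(tp=5, fp=0, fn=3, tn=2))
        assert metrics.odds_ratio == math.inf
        assert metrics.or_ci95 == (0.0, math.inf)

    def test_all_zero_table_is_an_error(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(ContingencyTable2x2(tp=0, fp=0, fn=0, tn=0))

    def test_rate_identities_are_exact(self):
        table = ContingencyTable2x2(tp=17, fp=5, fn=9, tn=13)
        metrics = diagnostic_metrics(table)
        assert metrics.ppv * (table.tp + table.fp) == pytest.approx(table.tp)
        assert metrics.npv * (table.fn + table.tn) == pytest.approx(table.tn)

    def test_metrics_invariant_under_cell_scaling(self):
        small = diagnostic_metrics(ContingencyTable2x2(tp=3, fp=2, fn=1, tn=4))
        big = diagnostic_metrics(ContingencyTable2x2(tp=9, fp=6, fn=3, tn=12))
        for field in ("sensitivity", "specificity", "ppv", "npv", "odds_ratio"):
            assert getattr(small, field) == pytest.approx(getattr(big, field))

    def test_fisher_and_or_match_enumeration_oracle(self):
        for a, b, c, d in product(range(5), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            metrics = diagnostic_metrics(ContingencyTable2x2(tp=a, fp=b, fn=c, tn=d))
            if b * c > 0:
                assert metrics.odds_ratio == pytest.approx(a * d / (b * c))
            assert metrics.p_value == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-8)


class TestTwoByTwo:
    def test_single_concordant_case(self):
        table = two_by_two([10.0], [12.0])
        assert (table.tp, table.fp, table.fn, table.tn) == (1, 0, 0, 0)

    def test_cell_totals_preserve_pair_count(self):
        rng = np.random.default_rng(4)
        amms = rng.uniform(0, 40, size=200)
        odx = rng.uniform(0, 60, size=200)
        for cutoff in (10.0, 18.0, 25.0):
            assert two_by_two(amms, odx, amms_cutoff=cutoff).total == 200

    def test_row_margins_count_the_test_rule(self):
        amms = np.array([5.0, 17.9, 18.0, 18.1, 40.0])
        odx = np.array([10, 30, 10, 10, 50])
        table = two_by_two(amms, odx)
        assert table.tp + table.fp == int(np.sum(amms <= 18))
        assert table.fn + table.tn == int(np.sum(amms > 18))

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            two_by_two([], [])


class TestBandAgreement:
    @pytest.mark.parametrize(
        "rows, printed",
        [
            (VALIDATION_BAND_COUNTS,
             [100.0, 91.7, 86.5, 86.6, 85.0, 84.8, 80.3, 83.6, 100.0]),
            (ORIGINAL_BAND_COUNTS,
             [100.0, 91.3, 86.1, 82.7, 83.6, 78.7, 73.4, 89.5, 100.0]),
        ],
        ids=["validation_population", "original_population"],
    )
    def test_percent_agreement_matches_published_tables(self, rows, printed):
        table = band_agreement_from_counts(rows)
        assert [round(p, 1) for p in table["percent_concordant"]] == printed

    def test_per_case_table_reproduces_validation_counts(self, validation_cohort):
        table = band_agreement_table(validation_cohort).set_index("group")
        expected = {
            label: counts
            for label, *counts in VALIDATION_BAND_COUNTS
            if label != "histologic low risk"
        }
        for label, (n_high, n_int, n_low) in expected.items():
            row = table.loc[label]
            assert (row["n_high"], row["n_intermediate"], row["n_low"]) == (
                n_high, n_int, n_low,
            )
        assert round(table.loc["amMs <=12", "percent_concordant"], 1) == 86.6
        assert round(table.loc["amMs >30", "percent_concordant"], 1) == 100.0

    def test_all_low_cohort_agrees_everywhere(self):
        frame = pd.DataFrame({"amms": [5.0] * 8, "odx_rs": [5] * 8})
        table = band_agreement_table(frame)
        low_groups = table[table["concordant_band"] == "low"]
        assert (low_groups["percent_concordant"] == 100.0).all()

    def test_groups_are_cumulative(self, validation_cohort):
        table = band_agreement_table(validation_cohort).set_index("group")
        for narrow, wide in [("amMs <=11", "amMs <=12"), ("amMs <=14", "amMs <=15")]:
            for column in ("n_high", "n_intermediate", "n_low"):
                assert table.loc[narrow, column] <= table.loc[wide, column]

    def test_missing_odx_cases_are_excluded_and_counted(self):
        frame = pd.DataFrame({"amms": [5.0, 6.0, 7.0], "odx_rs": [5.0, None, 8.0]})
        table = band_agreement_table(frame)
        assert table.attrs["n_excluded"] == 1


class TestDiscordance:
    def test_two_step_case(self):
        frame = pd.DataFrame({"case_id": ["x"], "amms": [15.4], "odx_rs": [31]})
        report = discordance_report(frame)
        assert report["discordance"].tolist() == ["two_step"]

    def test_concordant_case(self):
        frame = pd.DataFrame({"case_id": ["x"], "amms": [20.0], "odx_rs": [20]})
        assert discordance_report(frame)["discordance"].tolist() == ["concordant"]

    def test_validation_cohort_has_exactly_one_two_step_case(self, validation_cohort):
        report = discordance_report(validation_cohort)
        assert (report["discordance"] == "two_step").sum() == 1


class TestDistributionTests:
    def test_identical_vectors_correlate_perfectly(self):
        r, p = pearson_frequency_correlation([1, 4, 9, 2], [1, 4, 9, 2])
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_zero_variance_vector_is_an_error(self):
        with pytest.raises(ValueError, match="second"):
            pearson_frequency_correlation([1, 2, 3], [4, 4, 4])

    def test_identical_row_proportions_give_p_near_one(self):
        chi2, dof, p = chi2_independence([[40, 60], [20, 30]])
        assert dof == 1
        assert p > 0.9

    def test_chi2_p_matches_permutation_oracle(self):
        # Permuting column labels conditional on the margins makes the a-cell
        # hypergeometric; at n = 2000 the asymptotic p should sit close to
        # this exact permutation null.
        table = np.array([[511, 489], [489, 511]])
        chi2, _, p = chi2_independence(table)
        n, r1, c1 = table.sum(), table[0].sum(), table[:, 0].sum()
        rng = np.random.default_rng(17)
        a = rng.hypergeometric(c1, n - c1, r1, size=50_000)
        b, c = r1 - a, c1 - a
        d = n - r1 - c1 + a
        stat = n * (a * d - b * c) ** 2 / (r1 * (n - r1) * c1 * (n - c1))
        assert p == pytest.approx(np.mean(stat >= chi2 - 1e-12), abs=0.05)


def test_fixture_csvs_match_reference_counts():
    """The transcribed count CSVs in tests/data stay in sync with the
    constants the analyses consume."""
    from pathlib import Path

    data_dir = Path(__file__).parent / "data"
    bands = pd.read_csv(data_dir / "band_agreement_counts.csv")
    for population, reference in (
        ("validation", VALIDATION_BAND_COUNTS),
        ("original", ORIGINAL_BAND_COUNTS),
    ):
        rows = bands[bands["population"] == population]
        assert [tuple(r) for r in rows[["group", "n_high", "n_intermediate", "n_low"]]
                .itertuples(index=False)] == reference
    table = pd.read_csv(data_dir / "two_by_two_total_population.csv")
    assert dict(zip(table["cell"], table["count"])) == TOTAL_POPULATION_2X2


def test_odx_bands_partition_scores():
    bands = OdxBands()
    for score in range(0, 101):
        assert bands.band(score) in {"low", "intermediate", "high"}
    assert bands.band(17) == "low"
    assert bands.band(18) == "intermediate"
    assert bands.band(30) == "intermediate"
    assert bands.band(31) == "high"
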