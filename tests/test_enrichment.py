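"""Exact Fisher engine, gene-level aggregation, case-control tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hboc import (
    ContingencyTable,
    PopulationDBRecord,
    aggregate_gene_allele_counts,
    build_case_control_tables,
    classify_variants,
    compare_cohort_prevalence,
    fisher_exact_2x2,
)

from oracles import conditional_mean_exact, fisher_enumeration


class TestFisherEngine:
    def test_symmetric_table(self):
        res = fisher_exact_2x2(ContingencyTable(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_boundary_table_infinite_or(self):
        res = fisher_exact_2x2(ContingencyTable(4, 0, 0, 17))
        p_oracle, or_oracle = fisher_enumeration(4, 0, 0, 17)
        assert math.isinf(res.odds_ratio) and math.isinf(or_oracle)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)
        assert math.isinf(res.ci_high) and res.ci_low > 1

    def test_zero_cell_or_is_zero(self):
        res = fisher_exact_2x2(ContingencyTable(0, 10, 5, 15))
        assert res.odds_ratio == 0.0 and res.ci_low == 0.0

    # frozen from R 4.3.3 fisher.test (conditional MLE, minlike p, exact CI)
    @pytest.mark.parametrize(
        "table,or_,p,lo,hi",
        [
            ((7, 1129, 10, 17380), 10.7726, 3.60896e-05, 3.47351, 31.4182),
            ((3, 7, 12, 4), 0.156041, 0.0426168, 0.0167797, 1.08394),
            ((10, 2, 3, 15), 21.3053, 0.000536724, 2.75344, 300.683),
            ((6, 1130, 35, 45000), 6.82599, 0.00047151, 2.34192, 16.4496),
        ],
    )
    def test_matches_r_fisher_test(self, table, or_, p, lo, hi):
        res = fisher_exact_2x2(ContingencyTable(*table))
        assert res.odds_ratio == pytest.approx(or_, rel=1e-4)
        assert res.p_value == pytest.approx(p, rel=1e-5)
        assert res.ci_low == pytest.approx(lo, rel=1e-3)
        assert res.ci_high == pytest.approx(hi, rel=1e-2)

    def test_all_zero_table_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(ContingencyTable(0, 0, 0, 0))

    def test_degenerate_margins(self):
        res = fisher_exact_2x2(ContingencyTable(0, 5, 0, 7))
        assert res.p_value == 1.0 and math.isnan(res.odds_ratio)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_agrees_with_enumeration_oracle(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        res = fisher_exact_2x2(ContingencyTable(a, b, c, d), )
        p_oracle, or_oracle = fisher_enumeration(a, b, c, d)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-8, abs=1e-12)
        if or_oracle is None:
            assert math.isnan(res.odds_ratio)
        elif math.isinf(or_oracle):
            assert math.isinf(res.odds_ratio)
        elif or_oracle == 0.0:
            assert res.odds_ratio == 0.0
        else:
            assert res.odds_ratio == pytest.approx(or_oracle, rel=1e-5)
            # MLE verifies the conditional-mean stationarity equation
            assert conditional_mean_exact(a, b, c, d, res.odds_ratio) == pytest.approx(a, abs=1e-6)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_transposition_maps_or_to_reciprocal(self, cells):
        a, b, c, d = cells
        t = ContingencyTable(a, b, c, d)
        if t.total == 0:
            return
        res = fisher_exact_2x2(t)
        swapped = fisher_exact_2x2(t.transposed())
        assert swapped.p_value == pytest.approx(res.p_value, rel=1e-9, abs=1e-12)
        if math.isnan(res.odds_ratio):
            assert math.isnan(swapped.odds_ratio)
        elif res.odds_ratio == 0.0:
            assert math.isinf(swapped.odds_ratio)
        elif math.isinf(res.odds_ratio):
            assert swapped.odds_ratio == 0.0
        else:
            assert swapped.odds_ratio == pytest.approx(1.0 / res.odds_ratio, rel=1e-6)


class TestAggregation:
    def test_fixture_gene_counts_exclude_cnv(self, carrier_variants, engine_config):
        results = classify_variants(carrier_variants, engine_config)
        counts = aggregate_gene_allele_counts(results, include_cnv=False)
        assert counts["PALB2"] == 7
        assert counts["BARD1"] == 4
        assert counts["ATM"] == 6
        assert counts["BLM"] == 4
        assert "cnv" not in counts
        # total equals the number of pathogenic SNV/indel observations
        assert sum(counts.values()) == 35

    def test_cnv_flag_restores_deletions(self, carrier_variants, engine_config):
        results = classify_variants(carrier_variants, engine_config)
        counts = aggregate_gene_allele_counts(results, include_cnv=True)
        assert counts["BARD1"] == 5 and counts["RAD51C"] == 3
        assert sum(counts.values()) == 38

    def test_empty_input(self):
        assert aggregate_gene_allele_counts([]) == {}


class TestCaseControlTables:
    def _db(self, name, alt, total):
        return PopulationDBRecord(db_name=name, alt_counts={"PALB2": alt},
                                  total_alleles={"PALB2": total})

    def test_single_control_arithmetic(self):
        tables = build_case_control_tables({"PALB2": 7}, 568, [self._db("x", 10, 17390)])
        assert tables["PALB2"] == ContingencyTable(7, 1129, 10, 17380)

    def test_zero_case_count_kept(self):
        tables = build_case_control_tables({"PALB2": 0}, 568, [self._db("x", 10, 17390)])
        assert tables["PALB2"].a == 0 and tables["PALB2"].b == 1136
        assert fisher_exact_2x2(tables["PALB2"]).odds_ratio == 0.0

    def test_database_trio_sums(self):
        trio = [self._db("HGVD", 1, 2416), self._db("TMM", 2, 7108), self._db("EAS", 3, 7866)]
        tab = build_case_control_tables({"PALB2": 7}, 568, trio)["PALB2"]
        assert tab.c == 6 and tab.c + tab.d == 2416 + 7108 + 7866


class TestCohortPrevalence:
    def test_deficit_gives_or_below_one(self):
        results, _ = compare_cohort_prevalence({"CHEK2": 1}, 568, {"CHEK2": 30}, 1000)
        assert results["CHEK2"].odds_ratio < 1

    def test_equal_prevalence(self):
        results, _ = compare_cohort_prevalence({"G": 10}, 100, {"G": 10}, 100)
        assert results["G"].odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_unshared_gene_excluded(self):
        results, excluded = compare_cohort_prevalence(
            {"BARD1": 4}, 568, {"CHEK2": 30}, 1000,
            panel_a={"BARD1"}, panel_b={"CHEK2"},
        )
        assert results == {} and set(excluded) == {"BARD1", "CHEK2"}


def test_ci_coverage_of_planted_relative_risk():
    """Exact CI covers a planted allele-level odds ratio at (at least) the
    nominal rate over 200 seeded replicates."""
    rng = np.random.default_rng(20240917)
    rr, af = 6.0, 1.5e-3
    n_case_alleles, n_ctrl_alleles = 2 * 568, 17390
    case_or = rr * af / (1 - af) / (1 + rr * af / (1 - af))  # case allele prob with odds rr*odds0
    covered = 0
    n_rep = 200
    for _ in range(n_rep):
        a = rng.binomial(n_case_alleles, case_or)
        c = rng.binomial(n_ctrl_alleles, af)
        res = fisher_exact_2x2(
            ContingencyTable(int(a), n_case_alleles - int(a), int(c), n_ctrl_alleles - int(c))
        )
        if res.ci_low <= rr <= res.ci_high:
            covered += 1
    assert covered / n_rep >= 0.93
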