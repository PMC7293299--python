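"""SNV-VAF LOH, exon log2-ratio CNV LOH, AST detection, Table-style summary."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hboc import (
    GermlineVariant,
    TumorObservation,
    WildtypeLossCall,
    call_cnv_loh,
    call_snv_loh,
    call_wildtype_loss,
    detect_ast,
    load_fixture,
    summarize_wildtype_loss,
)


class TestSnvLoh:
    @pytest.mark.parametrize(
        "germ,tumor,expected",
        [
            (0.50, 0.75, "LOH"),
            (0.50, 0.60, "ND"),  # tumor threshold is strict
            (0.50, 0.601, "LOH"),
            (0.65, 0.90, "not_evaluable"),  # germline outside the window
            (0.19, 0.90, "not_evaluable"),
            (0.20, 0.90, "LOH"),  # germline window closed at 0.2
            (0.60, 0.90, "LOH"),  # ... and at 0.6
        ],
    )
    def test_window_semantics(self, germ, tumor, expected):
        assert call_snv_loh(germ, tumor) == expected

    def test_vaf_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            call_snv_loh(0.5, 1.2)

    @settings(max_examples=300, derandomize=True)
    @given(st.integers(0, 100), st.integers(0, 100))
    def test_boundary_grid(self, g_pct, t_pct):
        g, t = g_pct / 100, t_pct / 100
        verdict = call_snv_loh(g, t)
        if not 0.2 <= g <= 0.6:
            assert verdict == "not_evaluable"
        elif t > 0.6:
            assert verdict == "LOH"
        else:
            assert verdict == "ND"


class TestCnvLoh:
    def _profiles(self, n=30, affected=range(12, 18), drop=0.5,
                  lam_germ=366.0, lam_tumor=790.0, rng=None):
        # germline and tumor panels at their respective median coverages;
        # the affected span starts at one germline copy
        germ = np.full(n, lam_germ)
        germ[list(affected)] /= 2
        tumor = np.full(n, lam_tumor)
        tumor[list(affected)] *= drop / 2
        if rng is not None:
            germ = rng.poisson(germ).astype(float)
            tumor = rng.poisson(tumor).astype(float)
        return tumor, germ

    def test_halved_counts_called_loh(self):
        tumor, germ = self._profiles(drop=0.5)
        assert call_cnv_loh(tumor, germ, list(range(12, 18))) == "LOH"

    def test_identical_profiles_nd(self):
        tumor, germ = self._profiles(drop=1.0)
        assert call_cnv_loh(tumor, germ, list(range(12, 18))) == "ND"

    def test_zero_count_exons_dropped_with_warning(self):
        tumor, germ = self._profiles(drop=0.5)
        germ[12] = 0.0
        with pytest.warns(UserWarning):
            assert call_cnv_loh(tumor, germ, list(range(12, 18))) == "LOH"

    def test_too_few_informative_exons_is_nd(self):
        tumor, germ = self._profiles()
        germ[[12, 13, 14, 15]] = 0.0
        with pytest.warns(UserWarning):
            assert call_cnv_loh(tumor, germ, list(range(12, 18))) == "ND"

    def test_forty_percent_purity_detected(self):
        """Planted one-copy tumor loss at 40% purity over 6 exons with
        Poisson noise is recovered in at least 95 of 100 replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            tumor, germ = self._profiles(drop=0.6, rng=rng)  # 1 - purity = 0.6
            hits += call_cnv_loh(tumor, germ, list(range(12, 18))) == "LOH"
        assert hits >= 95

    def test_neutral_noise_specificity(self):
        rng = np.random.default_rng(8)
        false_calls = 0
        for _ in range(100):
            tumor, germ = self._profiles(drop=1.0, rng=rng)
            false_calls += call_cnv_loh(tumor, germ, list(range(12, 18))) == "LOH"
        assert false_calls <= 2


def somatic(gene="PALB2", pos=1365, vclass="frameshift_indel"):
    return GermlineVariant(case_id="tumor", gene=gene, chrom="16", pos=pos,
                           ref="CT", alt="C", variant_class=vclass)


class TestAst:
    def setup_method(self):
        self.germline = GermlineVariant(
            case_id="A0139", gene="PALB2", chrom="16", pos=3256,
            ref="C", alt="T", variant_class="stopgain", hgvs_p="p.R1086*",
        )

    def test_second_truncation_in_gene(self):
        assert detect_ast(self.germline, [somatic(pos=1365)]) == "AST"

    def test_same_site_excluded(self):
        assert detect_ast(self.germline, [somatic(pos=3256)]) == "ND"

    def test_missense_not_ast(self):
        assert detect_ast(self.germline, [somatic(vclass="missense")]) == "ND"

    def test_other_gene_ignored(self):
        assert detect_ast(self.germline, [somatic(gene="ATM")]) == "ND"


class TestCombinedVerdict:
    def test_assay_unavailable_is_na(self):
        obs = TumorObservation(case_id="C", tumor_id="T1", gene="PALB2", assay_available=False)
        germ = GermlineVariant(case_id="C", gene="PALB2")
        assert call_wildtype_loss(obs, germ).verdict == "NA"

    def test_ast_takes_precedence_over_loh(self):
        germ = GermlineVariant(case_id="C", gene="PALB2", chrom="16", pos=100,
                               ref="C", alt="T", variant_class="stopgain")
        obs = TumorObservation(
            case_id="C", tumor_id="T1", gene="PALB2",
            germline_vaf=0.5, tumor_vaf=0.9,
            somatic_calls={"a": [somatic()], "b": [somatic()], "c": []},
        )
        assert call_wildtype_loss(obs, germ).verdict == "AST"

    def test_consensus_filter_applied_before_ast(self):
        germ = GermlineVariant(case_id="C", gene="PALB2", chrom="16", pos=100,
                               ref="C", alt="T", variant_class="stopgain")
        obs = TumorObservation(
            case_id="C", tumor_id="T1", gene="PALB2",
            germline_vaf=0.5, tumor_vaf=0.5,
            somatic_calls={"a": [somatic()], "b": [], "c": []},  # single-caller artifact
        )
        assert call_wildtype_loss(obs, germ).verdict == "ND"


class TestSummary:
    def test_fixture_reproduces_published_totals(self, tumors_df):
        calls = [
            WildtypeLossCall(r.case_id, r.tumor_id, r.gene, r.wildtype_loss)
            for r in tumors_df.itertuples()
        ]
        summary = summarize_wildtype_loss(calls).set_index("gene")
        total = summary.loc["Total"]
        assert (total["analyzed"], total["LOH"], total["AST"], total["ND"]) == (22, 8, 4, 10)
        assert total["ratio"] == pytest.approx(12 / 22)
        palb2 = summary.loc["PALB2"]
        assert palb2["analyzed"] == 5 and palb2["ratio"] == pytest.approx(1.0)
        atm = summary.loc["ATM"]
        assert (atm["LOH"], atm["AST"], atm["ND"]) == (2, 0, 1)
        rad51d = summary.loc["RAD51D"]
        assert rad51d["analyzed"] == 3 and rad51d["ratio"] == pytest.approx(1 / 3)

    def test_empty_input(self):
        summary = summarize_wildtype_loss([])
        assert list(summary["gene"]) == ["Total"]
        assert summary.iloc[0]["analyzed"] == 0
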