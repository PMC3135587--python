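"""Genotype QC: filters, collapsing, HWE, LD pruning, coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sysgene as sg
from sysgene.genotypes import GenotypeTable
from sysgene.loci import LocusSpec
from sysgene.qc import (
    DRD4_RULE,
    additive_codes,
    class_codes,
    code_loci,
    collapse_rare_genotypes,
    filter_subjects_by_missingness,
    hwe_chi2,
    ld_prune,
    mask_low_quality_calls,
    run_qc,
)
from conftest import make_snp_table


class TestSubjectMissingness:
    def test_two_of_480_subjects_above_threshold_dropped(self, study_cohort):
        g = study_cohort.genotypes
        calls = g.calls.copy()
        # plant >10% missing on two subjects (11 of 98 calls: 11/98 > 0.10)
        for subj in g.subjects[:2]:
            calls.loc[subj, calls.columns[:11]] = np.nan
        planted = GenotypeTable(loci=g.loci, calls=calls, sex=g.sex)
        out, report = filter_subjects_by_missingness(planted, 0.10)
        assert out.n_subjects == 478
        assert len(report.subjects_dropped) == 2

    def test_no_missing_is_identity(self, small_panel):
        g = sg.simulate_genotypes(small_panel, 40, seed=1)
        out, report = filter_subjects_by_missingness(g, 0.10)
        assert out.calls.equals(g.calls)
        assert report.subjects_dropped == []

    def test_fraction_oracle_11_of_98(self):
        # 11/98 = 0.112 > 0.10 while 10/98 = 0.102 > 0.10 and 9/98 < 0.10
        assert 11 / 98 > 0.10
        assert 9 / 98 < 0.10


class TestCallQuality:
    def test_uniform_scores_mask_expected_fraction(self, small_panel):
        g = sg.simulate_genotypes(small_panel, 500, seed=2)
        rng = np.random.default_rng(0)
        quality = pd.DataFrame(
            rng.uniform(0, 1, g.calls.shape), index=g.subjects, columns=g.calls.columns
        )
        g = GenotypeTable(loci=g.loci, calls=g.calls, sex=g.sex, quality=quality)
        out, report = mask_low_quality_calls(g, 0.25)
        frac = report.calls_masked / g.calls.size
        assert frac == pytest.approx(0.25, abs=0.02)
        assert out.calls.isna().sum().sum() == report.calls_masked

    def test_zero_threshold_masks_nothing(self, small_panel):
        g = sg.simulate_genotypes(small_panel, 50, seed=3, with_quality=True)
        out, report = mask_low_quality_calls(g, 0.0)
        assert report.calls_masked == 0
        assert out.calls.equals(g.calls)

    def test_missing_quality_layer_is_noop(self, small_panel):
        g = sg.simulate_genotypes(small_panel, 30, seed=4)
        out, report = mask_low_quality_calls(g, 0.25)
        assert report.calls_masked == 0


class TestCollapse:
    def test_absent_minor_hom_class_not_merged(self):
        g = make_snp_table((447, 31, 0), major="G", minor="C")
        out, report = collapse_rare_genotypes(g, 10)
        assert report.loci_collapsed == {}
        assert "L1" in out.locus_ids

    def test_rare_minor_hom_merged_into_18(self):
        g = make_snp_table((460, 12, 6))
        out, report = collapse_rare_genotypes(g, 10)
        assert "L1" in report.loci_collapsed
        codes, labels = class_codes(out)
        assert labels["L1"] == ["AA", "others"]
        assert (codes["L1"] == 1).sum() == 18

    def test_monomorphic_locus_dropped(self):
        g = make_snp_table((478, 0, 0))
        out, report = collapse_rare_genotypes(g, 10)
        assert report.loci_dropped == [("L1", "monomorphic")]
        assert out.locus_ids == []

    def test_still_rare_locus_dropped(self):
        g = make_snp_table((470, 5, 3))
        out, report = collapse_rare_genotypes(g, 10)
        assert ("L1", "still_rare") in report.loci_dropped


class TestHwe:
    def test_exact_hwe_proportions_give_zero_chi2(self):
        g = make_snp_table((25, 50, 25))
        res = hwe_chi2(g, "L1")
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)
        assert res["df"] == 1

    def test_hand_arithmetic_30_40_30(self):
        # allele freq 0.5: expected 25/50/25; chi2 = 25/25 + 100/50 + 25/25 = 4
        g = make_snp_table((30, 40, 30))
        res = hwe_chi2(g, "L1")
        assert res["chi2"] == pytest.approx(4.0, abs=1e-12)

    def test_x_linked_uses_females_only(self):
        spec = LocusSpec("x1", "MAOA", "degradation_transport",
                         chromosome_class="x_linked", allele_labels=("A", "G"))
        females = ["A/A"] * 25 + ["A/G"] * 50 + ["G/G"] * 25
        males = ["A"] * 40 + ["G"] * 20
        subjects = pd.Index([f"S{i}" for i in range(160)])
        calls = pd.DataFrame({"x1": females + males}, index=subjects)
        sex = pd.Series(["female"] * 100 + ["male"] * 60, index=subjects)
        g = GenotypeTable(loci=[spec], calls=calls, sex=sex)
        res = hwe_chi2(g, "x1")
        # perfect HWE among females regardless of the skewed male calls
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_locus_rejected(self):
        g = make_snp_table((50, 0, 0))
        with pytest.raises(ValueError, match="<2 alleles"):
            hwe_chi2(g, "L1")

    @pytest.mark.parametrize("n", [6, 10, 17])
    def test_matches_brute_force_expected_counts(self, n):
        # exhaustive over all genotype tables of size n with both alleles seen
        for a in range(n + 1):
            for b in range(n + 1 - a):
                c = n - a - b
                n_minor = b + 2 * c
                if n_minor == 0 or n_minor == 2 * n:
                    continue
                g = make_snp_table((a, b, c))
                res = hwe_chi2(g, "L1")
                # independent multinomial expected-count oracle
                counts = sorted([(a, "A"), (c, "G")], reverse=True)
                p = (2 * counts[0][0] + b) / (2 * n)
                exp = [n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2]
                obs = [counts[0][0], b, counts[1][0]]
                chi2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
                assert res["chi2"] == pytest.approx(chi2, abs=1e-9)


class TestLdPrune:
    def test_identical_columns_prunes_second(self):
        spec2 = LocusSpec("L2", "GENE", "receptor", allele_labels=("A", "G"))
        g = make_snp_table((30, 40, 30))
        col = g.calls["L1"].tolist()
        g = make_snp_table((30, 40, 30), extra_loci=[(spec2, col)])
        out, report = ld_prune(g, 0.8)
        assert out.locus_ids == ["L1"]
        assert report.loci_dropped == [("L2", "ld_pruned:L1")]
        assert report.ld_pairs[("L1", "L2")] == pytest.approx(1.0)

    def test_default_panel_prunes_planted_redundancy(self, study_cohort_qc):
        _, g_qc, report = study_cohort_qc
        pruned = [l for l, r in report.loci_dropped if r.startswith("ld_pruned")]
        assert len(pruned) == 11
        assert len(g_qc.loci) == 87

    def test_independent_loci_survive(self, small_panel):
        g = sg.simulate_genotypes(small_panel, 480, seed=7)
        out, report = ld_prune(g, 0.8)
        assert out.locus_ids == [s.locus_id for s in small_panel]

    def test_different_genes_never_pruned(self):
        spec2 = LocusSpec("L2", "OTHER", "receptor", allele_labels=("A", "G"))
        g = make_snp_table((30, 40, 30))
        col = g.calls["L1"].tolist()
        g = make_snp_table((30, 40, 30), extra_loci=[(spec2, col)])
        out, _ = ld_prune(g, 0.8)
        assert out.locus_ids == ["L1", "L2"]


class TestCoding:
    def test_major_allele_by_count(self):
        # 600 G vs 356 A alleles: G major; GG->1, AG->2, AA->3
        g = make_snp_table((250, 100, 128), major="G", minor="A")
        design = code_loci(g)
        x = design.values["L1"]
        calls = g.calls["L1"]
        assert (x[calls == "G/G"] == 1).all()
        assert (x[calls == "A/G"] == 2).all()
        assert (x[calls == "A/A"] == 3).all()
        counts = g.allele_counts("L1")
        assert counts["G"] == 600 and counts["A"] == 356

    def test_drd4_grouping(self):
        assert DRD4_RULE.assign("4R/4R") == "4R/4R"
        assert DRD4_RULE.assign("2R/4R") == "2R+"
        assert DRD4_RULE.assign("2R/7R") == "2R+"
        assert DRD4_RULE.assign("3R/5R") == "others"

    def test_vntr_dummy_columns(self):
        panel = sg.default_panel()
        g = sg.simulate_genotypes(panel, 480, seed=9)
        design = code_loci(g)
        cols = design.locus_columns["DRD4_VNTR"]
        assert cols == ["DRD4_VNTR[4R/4R]", "DRD4_VNTR[2R+]"]
        vals = design.values[cols]
        assert set(np.unique(vals.to_numpy())) <= {0.0, 1.0}
        # reference group: both dummies zero
        ref = g.calls["DRD4_VNTR"].map(DRD4_RULE.assign) == "others"
        assert (vals[ref].sum(axis=1) == 0).all()

    def test_x_locus_two_group_coding_pools_sexes(self):
        spec = LocusSpec("x1", "MAOB", "degradation_transport",
                         chromosome_class="x_linked", target_maf=0.4)
        g = sg.simulate_genotypes([spec], 400, seed=10)
        x = code_loci(g).values["x1"]
        assert set(np.unique(x.dropna())) <= {1.0, 2.0}
        major, _ = g.major_minor("x1")
        male = g.sex == "male"
        assert (x[male & (g.calls["x1"] == major)] == 1).all()
        assert (x[~male & (g.calls["x1"] == f"{major}/{major}")] == 1).all()

    def test_missing_vntr_rule_raises(self):
        panel = [s for s in sg.default_panel() if s.locus_id in ("DRD4_VNTR", "rsDRD401")]
        g = sg.simulate_genotypes(panel, 100, seed=11)
        with pytest.raises(KeyError, match="DRD4_VNTR"):
            code_loci(g, vntr_rules={})

    def test_coding_partition_roundtrip(self, study_cohort_qc):
        # grouping subjects by coded value reproduces the class partition
        _, g_qc, _ = study_cohort_qc
        design = code_loci(g_qc)
        codes, labels = class_codes(g_qc)
        for lid, cols in design.locus_columns.items():
            cls = codes[lid]
            if len(cols) == 1:
                x = design.values[cols[0]]
                for c in range(len(labels[lid])):
                    members = cls == c
                    if members.any():
                        assert set(x[members].dropna()) == {float(c + 1)}
            else:
                vals = design.values[cols].to_numpy()
                for c in range(len(labels[lid])):
                    members = (cls == c).to_numpy()
                    if members.any():
                        block = vals[members]
                        assert len(np.unique(block, axis=0)) == 1


class TestChain:
    def test_accounting_identity(self, study_cohort_qc):
        _, g_qc, report = study_cohort_qc
        retained = set(g_qc.locus_ids)
        dropped = set(report.dropped_locus_ids)
        assert retained | dropped == {s.locus_id for s in sg.default_panel()}
        assert retained & dropped == set()

    def test_qc_is_idempotent(self, study_cohort_qc):
        _, g_qc, _ = study_cohort_qc
        g2, report2 = run_qc(g_qc)
        assert g2.locus_ids == g_qc.locus_ids
        assert g2.calls.equals(g_qc.calls)
        assert report2.calls_masked == 0
        assert report2.subjects_dropped == []
        assert report2.loci_dropped == []

    def test_planted_fixture_counts_exact(self):
        table, expected = sg.planted_qc_cohort()
        g_qc, report = run_qc(table)
        assert len(report.subjects_dropped) == expected["subjects_dropped"]
        assert report.calls_masked == expected["calls_masked"]
        assert sorted(report.loci_collapsed) == expected["collapsed"]
        assert [l for l, r in report.loci_dropped if r == "still_rare"] == expected["still_rare"]
        assert [l for l, r in report.loci_dropped if r == "monomorphic"] == expected["monomorphic"]
        pruned = {l: r.split(":")[1] for l, r in report.loci_dropped if r.startswith("ld_pruned")}
        assert pruned == expected["ld_pruned"]
        assert len(g_qc.loci) == expected["n_loci_retained"]


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=2, max_value=60), st.integers(min_value=2, max_value=60),
       st.integers(min_value=2, max_value=60))
def test_hwe_chi2_nonnegative_and_df1(a, b, c):
    g = make_snp_table((a, b, c))
    res = hwe_chi2(g, "L1")
    assert res["chi2"] >= 0
    assert 0 <= res["p"] <= 1
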