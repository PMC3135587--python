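"""OLS fits, stepwise selection, subsystem decomposition, model comparison."""

import numpy as np
import pandas as pd
import pytest

import sysgene as sg
from sysgene.regression import (
    add_environment,
    aic,
    bic,
    build_model1,
    build_model2,
    compare_models,
    comparison_table,
    fit_ols,
    fit_subsystems,
    forward_stepwise,
    gaussian_neg2ll,
    interaction_candidates,
    lrt_pvalue,
)


def random_design(seed, n=200, p=5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    return rng, X


class TestFitOls:
    def test_perfect_predictor_r2_one(self):
        _, X = random_design(0, p=1)
        y = pd.Series(X["x0"].to_numpy() * 2.0 + 1.0)
        fit = fit_ols(y, X)
        assert fit.R2 == pytest.approx(1.0)

    def test_coefficients_match_pseudo_inverse_oracle(self):
        rng, X = random_design(1)
        y = pd.Series(X.to_numpy() @ np.arange(1, 6) + rng.normal(size=200))
        fit = fit_ols(y, X)
        Xc = np.column_stack([np.ones(200), X.to_numpy()])
        beta = np.linalg.pinv(Xc) @ y.to_numpy()
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_overall_f_df_10_466_on_477_rows(self):
        rng, X = random_design(2, n=477, p=10)
        y = pd.Series(rng.normal(size=477))
        fit = fit_ols(y, X)
        assert (fit.df_model, fit.df_resid) == (10, 466)
        assert fit.n_rows == 477

    def test_neg2ll_matches_closed_form(self):
        rng, X = random_design(3)
        y = pd.Series(rng.normal(size=200))
        fit = fit_ols(y, X)
        Xc = np.column_stack([np.ones(200), X.to_numpy()])
        beta, *_ = np.linalg.lstsq(Xc, y.to_numpy(), rcond=None)
        rss = float(((y.to_numpy() - Xc @ beta) ** 2).sum())
        assert fit.neg2LL == pytest.approx(gaussian_neg2ll(rss, 200), rel=1e-10)
        assert fit.AIC == pytest.approx(fit.neg2LL + 2 * 5)
        assert fit.BIC == pytest.approx(fit.neg2LL + 5 * np.log(200))

    def test_rank_deficiency_names_column(self):
        _, X = random_design(4, p=3)
        X["dup"] = X["x0"] * 2.0
        y = pd.Series(np.arange(200, dtype=float))
        with pytest.raises(ValueError, match="dup"):
            fit_ols(y, X)

    def test_adjusted_r2_identity_and_bound(self):
        rng, X = random_design(5)
        y = pd.Series(X["x0"].to_numpy() + rng.normal(size=200))
        fit = fit_ols(y, X)
        n, p = fit.n_rows, fit.n_predictors
        assert fit.adjR2 == pytest.approx(1 - (1 - fit.R2) * (n - 1) / (n - p - 1), rel=1e-12)
        assert fit.adjR2 <= fit.R2


class TestInformationCriteria:
    def test_published_table_arithmetic(self):
        # printed comparison table: -2LL 3921 with 10 predictors on 477 rows
        assert aic(3921, 10) == 3941
        assert round(bic(3921, 10, 477)) == 3983
        assert aic(3902, 13) == 3928
        assert round(bic(3902, 13, 477)) == 3982
        assert aic(3910, 11) == 3932
        assert round(bic(3910, 11, 477)) == 3978
        assert aic(3889, 14) == 3917
        # printed -2LL 3889 is itself rounded; BIC matches to +/-1
        assert abs(bic(3889, 14, 477) - 3976) <= 1

    def test_published_lrt_probabilities(self):
        assert lrt_pvalue(19, 3) == pytest.approx(2.7e-4, rel=0.02)
        assert lrt_pvalue(11, 1) == pytest.approx(9.1e-4, rel=0.02)
        assert lrt_pvalue(32, 4) == pytest.approx(1.9e-6, rel=0.03)


class TestForwardStepwise:
    def test_candidate_identical_to_base_never_enters(self):
        rng, X = random_design(6, p=2)
        y = pd.Series(X["x0"].to_numpy() + rng.normal(size=200))
        cands = [("copy", X[["x0"]].rename(columns={"x0": "copy"}))]
        fit = forward_stepwise(y, X, cands)
        assert fit.entered == []

    def test_strong_partial_effect_enters_first(self):
        rng, X = random_design(7, p=2)
        strong = pd.DataFrame({"s": rng.normal(size=200)})
        weak = pd.DataFrame({"w": rng.normal(size=200)})
        y = pd.Series(X["x0"].to_numpy() + 2.0 * strong["s"].to_numpy() + rng.normal(size=200))
        fit = forward_stepwise(y, X, [("w", weak), ("s", strong)])
        assert fit.entered[0] == "s"

    def test_no_entering_candidate_returns_base_fit(self):
        rng, X = random_design(8, p=2)
        y = pd.Series(rng.normal(size=200))
        noise = pd.DataFrame({"z": rng.normal(size=200) * 0 + 1e-9 * rng.normal(size=200)})
        fit = forward_stepwise(y, X, [("z", noise)], alpha_enter=1e-12)
        assert fit.entered == []
        assert fit.predictors == ["x0", "x1"]

    def test_determinism_and_tie_break_by_order(self):
        rng, X = random_design(9, p=1)
        z = rng.normal(size=200)
        same1 = pd.DataFrame({"a": z})
        same2 = pd.DataFrame({"b": z + 1e-14})
        y = pd.Series(2.0 * z + rng.normal(size=200))
        fit1 = forward_stepwise(y, X, [("a", same1), ("b", same2)])
        fit2 = forward_stepwise(y, X, [("a", same1), ("b", same2)])
        assert fit1.entered == fit2.entered
        assert fit1.entered[0] == "a"


class TestPipelineModels:
    def test_model1_enters_all_selected(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        results = sg.screen_panel(g_qc, cohort.phenotype)
        selected = [r.locus for r in results if r.selected]
        design = sg.code_loci(g_qc)
        m1 = build_model1(design, selected, cohort.phenotype)
        n_cols = sum(len(design.locus_columns[l]) for l in selected)
        assert m1.n_predictors == n_cols

    def test_empty_selection_rejected(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        with pytest.raises(ValueError, match="no loci passed screening"):
            build_model1(sg.code_loci(g_qc), [], cohort.phenotype)

    def test_single_locus_r2_is_squared_correlation(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        design = sg.code_loci(g_qc)
        lid = "rsTH01"
        m = build_model1(design, [lid], cohort.phenotype)
        x = design.values[lid].loc[m.row_index]
        r = np.corrcoef(x, cohort.phenotype.loc[m.row_index])[0, 1]
        assert m.R2 == pytest.approx(r**2, rel=1e-10)

    def test_interaction_candidate_count_is_45_for_10_loci(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        design = sg.code_loci(g_qc)
        loci = [l for l in design.locus_columns if len(design.locus_columns[l]) == 1][:10]
        rows = design.values.index
        cands = interaction_candidates(design, loci, rows)
        assert len(cands) == 45

    def test_interaction_terms_have_zero_mean_on_analysis_rows(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        design = sg.code_loci(g_qc)
        loci = list(cohort.truth.additive_effects)[:4]
        rows = design.values[
            [design.locus_columns[l][0] for l in loci]
        ].dropna().index
        for _, block in interaction_candidates(design, loci, rows):
            assert np.abs(block.mean(axis=0).to_numpy()).max() < 1e-12

    def test_planted_interaction_between_screened_loci_selected(self):
        # two strong main-effect loci plus a dR2~0.03 interaction at n=480
        from sysgene.loci import LocusSpec

        hits = 0
        for rep in range(8):
            loci = [
                LocusSpec("a", "G1", "receptor", target_maf=0.4),
                LocusSpec("b", "G2", "modulation", target_maf=0.4),
            ]
            g = sg.simulate_genotypes(loci, 480, seed=900 + rep)
            eff = sg.EffectSpec(
                additive_effects={"a": 4.0, "b": 4.0},
                interaction_effects={("a", "b"): 5.5},
                noise_sd=15.0,
            )
            y = sg.simulate_phenotype(g, eff, seed=900 + rep)
            design = sg.code_loci(g)
            m2 = build_model2(design, ["a", "b"], y)
            hits += int("a×b" in m2.entered)
        assert hits >= 6

    def test_subsystem_partition_and_empty_flag(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        results = sg.screen_panel(g_qc, cohort.phenotype)
        selected = [r.locus for r in results if r.selected]
        design = sg.code_loci(g_qc)
        subs = fit_subsystems(design, selected, cohort.phenotype)
        m1 = build_model1(design, selected, cohort.phenotype)
        union = sorted(p for fit in subs.values() for p in fit.predictors)
        assert union == sorted(m1.predictors)
        for subsystem, fit in subs.items():
            if not fit.predictors:
                assert fit.empty and fit.R2 == 0.0

    def test_truth_concentrated_subsystem_dominates(self, study_cohort_qc):
        # planted effects put most signal in the modulation subsystem
        cohort, g_qc, _ = study_cohort_qc
        results = sg.screen_panel(g_qc, cohort.phenotype)
        selected = [r.locus for r in results if r.selected]
        design = sg.code_loci(g_qc)
        subs = fit_subsystems(design, selected, cohort.phenotype)
        r2 = {k: v.R2 for k, v in subs.items()}
        assert max(r2, key=r2.get) == "modulation"


class TestEnvironment:
    def test_independent_env_rarely_enters(self, study_cohort_qc):
        # a pure-noise covariate enters at alpha=0.05 in ~5% of replicates
        cohort, g_qc, _ = study_cohort_qc
        design = sg.code_loci(g_qc)
        m1 = build_model1(design, list(cohort.truth.additive_effects), cohort.phenotype)
        entries = 0
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            fake_env = pd.DataFrame(
                {"noise_env": rng.normal(size=len(cohort.phenotype))},
                index=cohort.phenotype.index,
            )
            fit, comp = add_environment(cohort.phenotype, m1, fake_env)
            entries += len(fit.entered)
            if not fit.entered:
                assert comp.df_diff == 0 and comp.p == 1.0
        assert entries <= 3  # binomial(10, 0.05) upper tail

    def test_true_env_effect_enters(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        design = sg.code_loci(g_qc)
        m1 = build_model1(design, list(cohort.truth.additive_effects), cohort.phenotype)
        fit, comp = add_environment(cohort.phenotype, m1, cohort.environment)
        assert "events_college" in fit.entered
        assert comp.delta_R2 > 0

    def test_comparison_table_layout(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        design = sg.code_loci(g_qc)
        loci = list(cohort.truth.additive_effects)
        m1 = build_model1(design, loci, cohort.phenotype)
        m2 = build_model2(design, loci, cohort.phenotype, model1=m1)
        table = comparison_table([("model1", m1, None), ("model2", m2, compare_models(m1, m2))])
        assert list(table.columns) == ["model", "R2", "delta_R2", "neg2LL", "df", "p", "AIC", "BIC"]


class TestCompareModels:
    def test_identical_models_delta_zero_p_one(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        design = sg.code_loci(g_qc)
        m1 = build_model1(design, list(cohort.truth.additive_effects)[:3], cohort.phenotype)
        comp = compare_models(m1, m1)
        assert comp.delta_neg2LL == 0.0 and comp.p == 1.0

    def test_non_nested_rejected(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        design = sg.code_loci(g_qc)
        loci = list(cohort.truth.additive_effects)
        a = build_model1(design, loci[:2], cohort.phenotype)
        b = build_model1(design, loci[2:4], cohort.phenotype)
        with pytest.raises(ValueError, match="nested"):
            compare_models(a, b)

    def test_r2_monotone_under_nesting(self, study_cohort_qc):
        cohort, g_qc, _ = study_cohort_qc
        design = sg.code_loci(g_qc)
        loci = list(cohort.truth.additive_effects)
        m1 = build_model1(design, loci, cohort.phenotype)
        m2 = build_model2(design, loci, cohort.phenotype, model1=m1)
        assert m2.R2 >= m1.R2 - 1e-12
        assert m1.adjR2 <= m1.R2 and m2.adjR2 <= m2.R2
        comp = compare_models(m1, m2)
        assert comp.delta_neg2LL >= 0


def test_parameter_recovery_large_n():
    # known coefficients recovered within 3 SE at n=5000
    from sysgene.loci import LocusSpec

    loci = [LocusSpec(f"c{i}", f"G{i}", "receptor", target_maf=0.3) for i in range(3)]
    g = sg.simulate_genotypes(loci, 5000, seed=77)
    truth = {"c0": 1.5, "c1": -2.0, "c2": 0.7}
    y = sg.simulate_phenotype(g, sg.EffectSpec(additive_effects=truth, noise_sd=3.0), seed=77)
    design = sg.code_loci(g)
    fit = build_model1(design, list(truth), y)
    se = fit.params / fit.tvalues
    for lid, beta in truth.items():
        assert abs(fit.params[lid] - beta) < 3 * se[lid]
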