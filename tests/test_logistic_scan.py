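"""IRLS logistic fits, interaction scans, and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_fdr_oracle
from conftest import clean_config, flat_panel
from gxepi import bh_fdr, fit_logistic, scan_gxe, scan_gxg, simulate_cohort
from gxepi.config import OutcomeEffects
from gxepi.preprocess import exposure_quartiles
from gxepi.scan import covariate_design


def expand_2x2(exp_case, exp_ctrl, unexp_case, unexp_ctrl):
    y = np.r_[np.ones(exp_case), np.zeros(exp_ctrl),
              np.ones(unexp_case), np.zeros(unexp_ctrl)]
    x = np.r_[np.ones(exp_case + exp_ctrl), np.zeros(unexp_case + unexp_ctrl)]
    return y, np.column_stack([np.ones_like(x), x])


class TestFitLogistic:
    def test_two_by_two_odds_ratio_closed_form(self):
        # OR = (20*20)/(10*10) = 4, so beta = ln 4
        y, X = expand_2x2(20, 10, 10, 20)
        fit = fit_logistic(y, X)
        assert fit.beta[1] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_intercept_only_is_logit_of_mean(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(y, np.ones((100, 1)))
        assert fit.beta[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="variation"):
            fit_logistic(np.ones(10), np.ones((10, 1)))

    def test_separation_flagged_not_crashed(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        x = np.r_[np.zeros(10), np.ones(10)]
        fit = fit_logistic(y, np.column_stack([np.ones(20), x]))
        assert not fit.converged

    def test_matches_statsmodels_glm(self, rng):
        # independent oracle: same model fit by statsmodels
        import statsmodels.api as sm

        X = np.column_stack([np.ones(300), rng.normal(size=(300, 3))])
        eta = X @ np.array([-0.5, 0.8, 0.0, -0.3])
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, X)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)), ref.bse, atol=1e-6)

    def test_wald_close_to_likelihood_ratio_under_null(self, rng):
        from scipy import stats

        X = np.column_stack([np.ones(5000), rng.normal(size=5000)])
        y = (rng.random(5000) < 0.4).astype(float)
        fit = fit_logistic(y, X)
        null = fit_logistic(y, X[:, :1])
        lr_p = stats.chi2.sf(null.deviance - fit.deviance, 1)
        assert abs(fit.wald_p(1) - lr_p) < 0.01


class TestBhFdr:
    def test_textbook_example_all_flatten_to_005(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(bh_fdr(p), 0.05)

    @pytest.mark.parametrize("p, expected", [([0.2], [0.2]), ([1.0, 1.0], [1.0, 1.0])])
    def test_degenerate_inputs(self, p, expected):
        np.testing.assert_allclose(bh_fdr(np.array(p)), expected)

    def test_nan_p_stays_nan_and_shrinks_family(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_fdr_oracle([0.01, 0.04]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_and_dominates_p(self, p):
        q = bh_fdr(np.array(p))
        np.testing.assert_allclose(q, bh_fdr_oracle(p), atol=1e-12)
        assert (q >= np.array(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def scan_inputs(seed, n, snps, effects=None):
    cfg = clean_config(seed=seed, n_recruited=n, snps=snps,
                       bmi_effects=effects or OutcomeEffects(baseline_logit=-0.5))
    cohort, geno = simulate_cohort(cfg)
    return cohort, geno, cohort["bmi_case_latent"]


class TestScans:
    def panel_8_9_3(self):
        from gxepi import SnpSpec

        panel = flat_panel(8, gene="SOCS3")
        panel += [SnpSpec(rsid=f"rn{i}", gene="NFKB1", maf=0.3) for i in range(9)]
        panel += [SnpSpec(rsid=f"ri{i}", gene="IKBKB", maf=0.3) for i in range(3)]
        return panel

    def test_cross_gene_pair_count(self):
        panel = self.panel_8_9_3()
        cohort, geno, y = scan_inputs(21, 400, panel)
        genes = {s.rsid: s.gene for s in panel}
        res = scan_gxg(y, geno, cohort, genes)
        assert len(res) == 8 * 9 + 8 * 3 + 9 * 3  # 123 cross-gene models

    def test_all_pairs_flag(self):
        panel = flat_panel(4)
        cohort, geno, y = scan_inputs(22, 400, panel)
        genes = {s.rsid: s.gene for s in panel}
        res = scan_gxg(y, geno, cohort, genes, cross_gene_only=False)
        assert len(res) == 6

    def test_gxe_model_count_and_zero_variance_skip(self):
        panel = flat_panel(5)
        cohort, geno, y = scan_inputs(23, 400, panel)
        expo = exposure_quartiles(cohort)[["carb_resid", "fat_resid"]].copy()
        expo["flat"] = 0.0
        res = scan_gxe(y, geno, expo, cohort)
        assert len(res) == 5 * 2  # the all-zero exposure is skipped

    def test_planted_gxg_or_recovered(self):
        panel = flat_panel(3, maf=0.4)
        eff = OutcomeEffects(baseline_logit=-1.0,
                             interaction_or={("rs000", "rs001"): 2.0})
        cohort, geno, y = scan_inputs(24, 5000, panel, eff)
        genes = {s.rsid: s.gene for s in panel}
        res = scan_gxg(y, geno, cohort, genes, cross_gene_only=False)
        row = res[(res.term1 == "rs000") & (res.term2 == "rs001")].iloc[0]
        assert abs(row.beta - np.log(2.0)) < 3 * row.se

    def test_planted_gxe_slope_recovered(self):
        panel = flat_panel(2, maf=0.4)
        beta_per_kcal = 0.004  # OR 1.004 per kcal of centred fat intake
        eff = OutcomeEffects(baseline_logit=-0.8,
                             interaction_or={("rs000", "fat"): np.exp(beta_per_kcal)})
        cohort, geno, y = scan_inputs(25, 5000, panel, eff)
        expo = exposure_quartiles(cohort)[["fat_resid"]]
        res = scan_gxe(y, geno, expo, cohort)
        row = res[(res.term1 == "rs000") & (res.term2 == "fat_resid")].iloc[0]
        assert abs(row.beta - beta_per_kcal) < 3 * row.se

    def test_null_scan_p_values_uniform(self):
        from scipy import stats

        panel = self.panel_8_9_3()
        cohort, geno, y = scan_inputs(26, 1500, panel)
        genes = {s.rsid: s.gene for s in panel}
        res = scan_gxg(y, geno, cohort, genes)
        p = res["wald_p"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_invariant_to_snp_column_order(self):
        panel = flat_panel(4)
        cohort, geno, y = scan_inputs(27, 400, panel)
        genes = {s.rsid: s.gene for s in panel}
        a = scan_gxg(y, geno, cohort, genes, cross_gene_only=False)
        b = scan_gxg(y, geno[geno.columns[::-1]], cohort, genes, cross_gene_only=False)
        pd.testing.assert_frame_equal(a, b)

    def test_covariate_design_reference_levels(self, default_cohort):
        cohort, _ = default_cohort
        X = covariate_design(cohort.head(50), ("age", "sex", "group"))
        assert list(X.columns) == ["intercept", "age", "sex_M",
                                   "group_EastAsian", "group_SouthAsian", "group_Other"]
        assert (X["intercept"] == 1).all()
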