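"""MDR engine: cell labeling, cross-validation, exhaustive search, and
equivalence with an independent brute-force implementation."""

import numpy as np
import pandas as pd
import pytest

from _oracles import mdr_cvc_oracle, mdr_fold_oracle
from conftest import clean_config, flat_panel, random_discrete_dataset
from gxepi import SnpSpec, evaluate_model, label_cells, render_grid, search, simulate_cohort
from gxepi.config import OutcomeEffects
from gxepi.mdr import assign_folds
from gxepi.simulate import plant_xor_penetrance


class TestLabelCells:
    @pytest.mark.parametrize(
        "cases, controls, expected",
        [
            (3, 1, True),    # ratio 3 > 1: high risk
            (2, 2, False),   # exact tie: low
            (0, 0, False),   # empty cell: low by default policy
            (1, 0, True),    # cases with zero controls: high
            (0, 5, False),
        ],
    )
    def test_single_cells(self, cases, controls, expected):
        assert label_cells(np.array([cases]), np.array([controls]))[0] == expected

    def test_threshold_parameter(self):
        cases, controls = np.array([3]), np.array([1])
        assert label_cells(cases, controls, threshold=3.0)[0] == False  # noqa: E712
        assert label_cells(cases, controls, threshold=2.9)[0] == True  # noqa: E712


class TestEvaluateModel:
    def test_perfect_separator_has_accuracy_one(self):
        n = 60
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        data = pd.DataFrame({"f": y.astype(int), "g": np.tile([0, 1, 2], n // 3)})
        model = evaluate_model(("f", "g"), data, y, n_folds=5, seed=0)
        assert model.avg_test_accuracy == pytest.approx(1.0)

    def test_null_factor_accuracy_near_half(self):
        r = np.random.default_rng(0)
        n = 2000
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        data = pd.DataFrame({"a": r.integers(0, 3, n), "b": r.integers(0, 3, n)})
        model = evaluate_model(("a", "b"), data, y, seed=1)
        assert abs(model.avg_test_accuracy - 0.5) < 0.03

    def test_twenty_subject_toy_matches_hand_enumeration(self):
        data, y = random_discrete_dataset(seed=99, n_factors=2, max_n=20)
        folds = assign_folds(y, 5, seed=3)
        model = evaluate_model(("f0", "f1"), data, y, n_folds=5, fold_ids=folds)
        oracle, _ = mdr_fold_oracle(data, y, folds)
        np.testing.assert_allclose(model.per_fold, oracle, atol=1e-12)

    def test_training_beats_majority_rule(self):
        # per-cell majority labeling can never do worse than the global
        # majority class on the same training data
        for seed in range(10):
            data, y = random_discrete_dataset(seed, n_factors=2)
            folds = assign_folds(y, 5, seed=seed)
            model = evaluate_model(("f0", "f1"), data, y, n_folds=5, fold_ids=folds)
            for f in range(5):
                ytr = y[folds != f]
                majority = max(ytr.mean(), 1 - ytr.mean())
                assert model.per_fold[f][0] >= majority - 1e-12

    def test_case_counts_conserved(self):
        data, y = random_discrete_dataset(seed=5, n_factors=2)
        model = evaluate_model(("f0", "f1"), data, y, n_folds=5, seed=0)
        assert model.risk_map_full.cases.sum() == y.sum()
        assert model.risk_map_full.controls.sum() == (1 - y).sum()

    def test_invariant_to_factor_and_row_order(self):
        data, y = random_discrete_dataset(seed=7, n_factors=2)
        folds = assign_folds(y, 5, seed=2)
        a = evaluate_model(("f0", "f1"), data, y, n_folds=5, fold_ids=folds)
        b = evaluate_model(("f1", "f0"), data, y, n_folds=5, fold_ids=folds)
        assert a.avg_test_accuracy == pytest.approx(b.avg_test_accuracy)
        perm = np.random.default_rng(1).permutation(len(y))
        c = evaluate_model(("f0", "f1"), data.iloc[perm].reset_index(drop=True),
                           y[perm], n_folds=5, fold_ids=folds[perm])
        np.testing.assert_allclose(a.per_fold, c.per_fold, atol=1e-12)

    def test_distinct_factor_ids_required(self):
        data, y = random_discrete_dataset(seed=1)
        with pytest.raises(ValueError, match="distinct"):
            evaluate_model(("f0", "f0"), data, y)


class TestOracleEquivalence:
    def test_randomized_battery_matches_brute_force(self):
        """Labels, fold accuracies and CVC agree exactly with an independent
        dict-and-loop implementation on small random datasets."""
        for seed in range(40):
            data, y = random_discrete_dataset(seed, n_factors=3, max_n=30)
            folds = assign_folds(y, 5, seed=seed)
            model = evaluate_model(("f0", "f1"), data, y, n_folds=5, fold_ids=folds)
            oracle, _ = mdr_fold_oracle(data[["f0", "f1"]], y, folds)
            np.testing.assert_allclose(model.per_fold, oracle, atol=1e-12)
            res = search(data, y, pool=["f0", "f1", "f2"], orders=(2,),
                         n_folds=5, seed=seed)
            cvc = mdr_cvc_oracle(data, y, ["f0", "f1", "f2"], 2, folds)
            best_oracle = sorted(
                cvc, key=lambda s: (-cvc[s],
                                    -np.mean([a[1] for a in
                                              mdr_fold_oracle(data[list(s)], y, folds)[0]]),
                                    s))[0]
            assert res[2].factors == best_oracle
            assert res[2].cv_consistency == cvc[best_oracle]


class TestSearch:
    def xor_dataset(self, seed, n=1600, noise_snps=10):
        panel = [SnpSpec(rsid="rsA", gene="SOCS3", maf=0.5),
                 SnpSpec(rsid="rsB", gene="NFKB1", maf=0.5)]
        panel += flat_panel(noise_snps, gene="IKBKB")
        eff = OutcomeEffects(penetrance={("rsA", "rsB"): plant_xor_penetrance(0.8, 0.2)})
        cfg = clean_config(seed=seed, n_recruited=n, snps=panel, bmi_effects=eff)
        cohort, geno = simulate_cohort(cfg)
        return geno, cohort["bmi_case_latent"].to_numpy()

    def test_planted_xor_pair_selected(self):
        geno, y = self.xor_dataset(seed=31)
        res = search(geno, y, pool=list(geno.columns), orders=(2,), seed=8)
        model = res[2]
        assert model.factors == ("rsA", "rsB")
        assert model.cv_consistency >= 9
        assert model.avg_test_accuracy >= 0.55
        assert model.valid

    def test_two_factor_pool_trivially_consistent(self):
        data, y = random_discrete_dataset(seed=13, n_factors=2)
        res = search(data, y, pool=["f0", "f1"], orders=(2,), n_folds=5, seed=0)
        assert res[2].cv_consistency == 5

    def test_pool_smaller_than_order_rejected(self):
        data, y = random_discrete_dataset(seed=13, n_factors=2)
        with pytest.raises(ValueError, match="cannot support"):
            search(data, y, pool=["f0", "f1"], orders=(3,))

    def test_must_include_any_restricts_candidates(self):
        data, y = random_discrete_dataset(seed=17, n_factors=3)
        res = search(data, y, pool=["f0", "f1", "f2"], orders=(2,), n_folds=5,
                     seed=0, must_include_any=["f2"])
        assert "f2" in res[2].factors
        assert res[2].extras["n_candidate_sets"] == 2

    def test_null_pool_rarely_valid(self):
        # small replicate count here; the full calibration lives in the
        # acceptance suite
        valid = 0
        for seed in range(10):
            cfg = clean_config(seed=400 + seed, n_recruited=600,
                               snps=flat_panel(8),
                               bmi_effects=OutcomeEffects(baseline_logit=0.0))
            cohort, geno = simulate_cohort(cfg)
            res = search(geno, cohort["bmi_case_latent"].to_numpy(),
                         pool=list(geno.columns), orders=(2,), seed=seed)
            valid += res[2].valid
        assert valid <= 3


class TestRenderGrid:
    def test_two_snp_grid_shape(self):
        data, yv = random_discrete_dataset(seed=23, n_factors=2)
        model = evaluate_model(("f0", "f1"), data, yv, n_folds=5, seed=0)
        text = render_grid(model)
        # one header plus one row per level of the first factor
        rm = model.risk_map_full
        assert text.count("f0=") == len(rm.levels[0])

    def test_three_factor_panels(self):
        r = np.random.default_rng(3)
        n = 300
        data = pd.DataFrame({f"s{i}": r.integers(0, 3, n) for i in range(3)})
        y = r.integers(0, 2, n)
        model = evaluate_model(("s0", "s1", "s2"), data, y, n_folds=5, seed=0)
        text = render_grid(model)
        assert text.count("[s2 = ") == len(model.risk_map_full.levels[2])

    def test_snp_by_quartile_grid(self):
        r = np.random.default_rng(4)
        n = 400
        data = pd.DataFrame({"snp": r.integers(0, 3, n),
                             "carb_q": r.integers(1, 5, n)})
        y = r.integers(0, 2, n)
        model = evaluate_model(("snp", "carb_q"), data, y, n_folds=5, seed=0)
        rm = model.risk_map_full
        assert rm.cases.shape == (3, 4)

    def test_figure_renders(self, tmp_path):
        data, y = random_discrete_dataset(seed=29, n_factors=2)
        model = evaluate_model(("f0", "f1"), data, y, n_folds=5, seed=0)
        from gxepi.mdr import render_grid_figure

        out = tmp_path / "grid.png"
        render_grid_figure(model, str(out))
        assert out.exists() and out.stat().st_size > 0
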