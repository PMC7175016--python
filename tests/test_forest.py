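"""Random-forest decoding: balance, OOB bookkeeping, importance, controls."""

import numpy as np
import pandas as pd
import pytest

import valsight as vs
from valsight import forest


def _noise_matrix(n_rows=400, n_features=5, informative=None, seed=0,
                  effect=1.5):
    """Synthetic beta table: pure noise except an optional informative column."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n_rows)
    df = pd.DataFrame(rng.normal(size=(n_rows, n_features)),
                      columns=[f"f{i}" for i in range(n_features)])
    if informative is not None:
        df[informative] += effect * (2 * y - 1)
    df["subject_id"] = [f"sub-{i % 4}" for i in range(n_rows)]
    df["trial_sign"] = ["+/-"] * n_rows
    df["label"] = np.where(y == 1, "optimal", "suboptimal")
    df["dvalue"] = rng.uniform(0, 0.8, size=n_rows)
    return df


class TestAssembleAndSplit:
    def test_concatenation_counts(self, planted_cohort_betas):
        mat = vs.assemble_matrix(planted_cohort_betas, seed=1)
        assert len(mat.data) == sum(len(t) for t in planted_cohort_betas)

    def test_shuffle_is_a_permutation(self, planted_cohort_betas):
        mat = vs.assemble_matrix(planted_cohort_betas, seed=2)
        pooled = pd.concat(planted_cohort_betas, ignore_index=True)
        assert sorted(mat.data["caudate"]) == pytest.approx(
            sorted(pooled["caudate"]))
        assert (mat.data["label"].value_counts()
                == pooled["label"].value_counts()).all()

    def test_mismatched_columns_rejected(self, planted_cohort_betas):
        bad = planted_cohort_betas[1].rename(columns={"caudate": "oops"})
        with pytest.raises(ValueError, match="columns differ"):
            vs.assemble_matrix([planted_cohort_betas[0], bad], seed=0)

    def test_split_sizes_and_disjointness(self):
        mat = vs.assemble_matrix([_noise_matrix(300)], seed=3)
        train, val = vs.split_train_validation(mat, seed=4)
        assert len(train.data) == 200 and len(val.data) == 100
        key = ["f0", "f1"]
        merged = train.data[key].merge(val.data[key], on=key)
        assert merged.empty  # continuous features: overlap means leakage

    def test_split_seed_stable(self):
        mat = vs.assemble_matrix([_noise_matrix(90)], seed=5)
        a, _ = vs.split_train_validation(mat, seed=6)
        b, _ = vs.split_train_validation(mat, seed=6)
        pd.testing.assert_frame_equal(a.data, b.data)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_bad_fraction_rejected(self, frac):
        mat = vs.assemble_matrix([_noise_matrix(60)], seed=7)
        with pytest.raises(ValueError, match="train_fraction"):
            vs.split_train_validation(mat, frac)


class TestForestTraining:
    def test_each_bootstrap_is_class_balanced(self):
        mat = vs.assemble_matrix([_noise_matrix(200, informative="f0")], seed=8)
        model = vs.train_forest(mat, n_trees=50, seed=9)
        for counts in model.bootstrap_counts_:
            assert counts[0] == counts[1]

    def test_oob_coverage_complete(self):
        mat = vs.assemble_matrix([_noise_matrix(300)], seed=10)
        model = vs.train_forest(mat, n_trees=500, seed=11)
        assert np.isfinite(model.oob_votes()).all()

    def test_separable_matrix_low_oob(self, separable_betas):
        mat = vs.assemble_matrix([separable_betas], seed=12)
        model = vs.train_forest(mat, n_trees=200, seed=13)
        assert model.oob_error_ < 0.05

    def test_single_class_rejected(self):
        df = _noise_matrix(50)
        df["label"] = "optimal"
        mat = vs.assemble_matrix([df], seed=14)
        with pytest.raises(ValueError, match="single class"):
            vs.train_forest(mat, n_trees=10)

    def test_shuffled_labels_at_chance(self):
        tables = [_noise_matrix(3000, informative="f0", seed=15)]
        mat = vs.assemble_matrix(tables, seed=16)
        report, _ = forest.decode(mat, n_trees=150, seed=17,
                                  shuffle_labels=True,
                                  n_importance_repeats=1)
        n_val = report.n_validation
        half_width = 1.96 * np.sqrt(0.25 / n_val)
        assert abs(report.validation_accuracy - 0.5) < half_width + 0.02

    def test_oob_tracks_validation_error(self):
        tables = [_noise_matrix(2000, informative="f0", seed=18, effect=1.0)]
        mat = vs.assemble_matrix(tables, seed=19)
        report, _ = forest.decode(mat, n_trees=300, seed=20,
                                  n_importance_repeats=1)
        assert abs(report.oob_error - (1 - report.validation_accuracy)) < 0.05


class TestMtry:
    def test_search_start_is_sqrt_p(self):
        # 11 features -> floor(sqrt(11)) = 3
        assert int(np.sqrt(11)) == 3

    def test_returned_mtry_in_bounds(self):
        mat = vs.assemble_matrix([_noise_matrix(200, informative="f0")], seed=21)
        m = vs.tune_mtry(mat, n_trees=50, seed=22)
        assert 1 <= m <= len(mat.feature_cols)

    def test_tuned_no_worse_than_default_on_correlated_features(self):
        rng = np.random.default_rng(23)
        n = 600
        y = rng.integers(0, 2, size=n)
        latent = 1.2 * (2 * y - 1)
        df = pd.DataFrame({f"f{i}": latent + rng.normal(size=n)
                           for i in range(5)})
        for i in range(5, 10):
            df[f"f{i}"] = rng.normal(size=n)
        df["subject_id"] = "sub-0"
        df["trial_sign"] = "+/-"
        df["label"] = np.where(y == 1, "optimal", "suboptimal")
        df["dvalue"] = 0.5
        mat = vs.assemble_matrix([df], seed=24)

        def oob(m, s):
            return forest.BalancedRandomForest(
                n_trees=120, mtry=m, seed=s).fit(mat.X, mat.y).oob_error_

        default = int(np.sqrt(len(mat.feature_cols)))
        wins = 0
        for s in range(10):
            tuned = vs.tune_mtry(mat, n_trees=120, seed=1000 + s)
            if oob(tuned, s) <= oob(default, s) + 1e-9:
                wins += 1
        assert wins >= 5


class TestPermutationImportance:
    def test_constant_feature_importance_zero(self):
        df = _noise_matrix(300, informative="f0", seed=25)
        df["f4"] = 1.0
        mat = vs.assemble_matrix([df], seed=26)
        model = vs.train_forest(mat, n_trees=100, seed=27)
        imp = vs.permutation_importance(model, mat.feature_cols,
                                        n_repeats=3, seed=28)
        assert imp.set_index("feature").loc["f4", "importance"] == 0.0

    def test_planted_feature_ranks_first(self):
        df = _noise_matrix(600, informative="f2", seed=29)
        mat = vs.assemble_matrix([df], seed=30)
        model = vs.train_forest(mat, n_trees=200, seed=31)
        imp = vs.permutation_importance(model, mat.feature_cols,
                                        n_repeats=5, seed=32)
        assert imp.iloc[0]["feature"] == "f2"

    def test_random_control_below_signal_with_nonpositive_importance(self):
        """Median over seeds: an appended noise feature ranks below the
        informative one with importance <= 0 within sampling noise."""
        below, imps = [], []
        for s in range(5):
            df = _noise_matrix(500, informative="f0", seed=40 + s)
            mat = vs.assemble_matrix([df], seed=50 + s)
            report, _ = forest.decode(mat, n_trees=150, seed=60 + s,
                                      add_random_control=True,
                                      n_importance_repeats=3)
            tab = report.importance.set_index("feature")
            below.append(tab.loc["random_control", "rank"]
                         > tab.loc["f0", "rank"])
            imps.append(tab.loc["random_control", "importance"])
        assert np.median(below) == 1.0
        assert np.median(imps) <= 0.005

    def test_zero_repeats_rejected(self):
        mat = vs.assemble_matrix([_noise_matrix(100)], seed=33)
        model = vs.train_forest(mat, n_trees=20, seed=34)
        with pytest.raises(ValueError, match="n_repeats"):
            vs.permutation_importance(model, mat.feature_cols, n_repeats=0)


class TestEvaluation:
    def test_votes_in_unit_interval_and_tie_rule(self):
        mat = vs.assemble_matrix([_noise_matrix(200, informative="f0")], seed=35)
        train, val = vs.split_train_validation(mat, seed=36)
        model = vs.train_forest(train, n_trees=40, seed=37)
        votes = model.votes(val.X)
        assert ((votes >= 0) & (votes <= 1)).all()
        pred = model.predict(val.X)
        assert ((votes > 0.5) == (pred == 1)).all()  # tie -> suboptimal (0)

    def test_accuracy_definition(self):
        mat = vs.assemble_matrix([_noise_matrix(150, informative="f0")], seed=38)
        train, val = vs.split_train_validation(mat, seed=39)
        model = vs.train_forest(train, n_trees=50, seed=40)
        ev = vs.evaluate(model, val)
        manual = 1 - np.mean(ev["predicted"] != val.y)
        assert ev["accuracy"] == pytest.approx(manual)

    def test_separable_data_auc_saturates(self, separable_betas):
        mat = vs.assemble_matrix([separable_betas], seed=41)
        train, val = vs.split_train_validation(mat, seed=42)
        model = vs.train_forest(train, n_trees=100, seed=43)
        ev = vs.evaluate(model, val)
        assert ev["auc"] > 0.95
        assert ev["auc"] >= ev["accuracy"] - 0.05


class TestUncertaintyRegression:
    def test_constant_dvalue_has_no_explainable_variance(self):
        votes = np.array([0.9, 0.2, 0.6, 0.7, 0.4])
        out = vs.uncertainty_dvalue_regression(votes, np.full(5, 0.3))
        assert out["adj_r2"] <= 0

    def test_uncertainty_bounded_by_half(self):
        rng = np.random.default_rng(44)
        votes = rng.uniform(0, 1, 200)
        out = vs.uncertainty_dvalue_regression(votes, rng.normal(size=200))
        assert ((out["uncertainty"] >= 0) & (out["uncertainty"] <= 0.5)).all()

    def test_zero_variance_votes_flagged(self):
        out = vs.uncertainty_dvalue_regression(np.full(10, 1.0),
                                               np.arange(10.0))
        assert np.isnan(out["adj_r2"])

    def test_negative_slope_when_signal_scales_with_dvalue(self):
        """Stronger betas on large-dValue trials -> less vote disagreement."""
        slopes = []
        for s in range(5):
            rng = np.random.default_rng(70 + s)
            n = 900
            y = rng.integers(0, 2, size=n)
            dv = rng.uniform(0.05, 0.9, size=n)
            df = pd.DataFrame({
                f"f{i}": 1.8 * (2 * y - 1) * dv + rng.normal(size=n)
                for i in range(4)})
            df["subject_id"] = "sub-0"
            df["trial_sign"] = "+/-"
            df["label"] = np.where(y == 1, "optimal", "suboptimal")
            df["dvalue"] = dv
            mat = vs.assemble_matrix([df], seed=80 + s)
            report, extras = forest.decode(mat, n_trees=150, seed=90 + s,
                                           n_importance_repeats=1)
            slopes.append(extras["uncertainty_regression"]["slope"])
        assert np.median(slopes) < 0


class TestAblationAndDifficulty:
    def _planted_mat(self, seed=0, n=900):
        """ROI-named matrix: signal only in striatal features."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=n)
        df = pd.DataFrame({roi: rng.normal(size=n) for roi in vs.ROI_NAMES})
        for roi in ("caudate", "putamen", "accumbens"):
            df[roi] += 1.2 * (2 * y - 1)
        df["subject_id"] = "sub-0"
        df["trial_sign"] = "+/-"
        df["label"] = np.where(y == 1, "optimal", "suboptimal")
        df["dvalue"] = rng.uniform(0, 1, size=n)
        return vs.assemble_matrix([df], seed=seed + 1)

    def test_isolated_empty_group_at_chance_and_full_at_top(self):
        mat = self._planted_mat(seed=45)
        train, val = vs.split_train_validation(mat, seed=46)
        table = vs.ablation_suite(train, val, n_trees=100, seed=47)
        t = table.set_index("configuration")
        assert abs(t.loc["only_perceptual", "accuracy"] - 0.5) < 0.08
        assert t.loc["full", "accuracy"] >= t["accuracy"].drop("full").max() - 0.03
        assert t.loc["only_striatal", "accuracy"] > 0.8

    def test_unknown_group_rejected(self):
        mat = self._planted_mat(seed=48)
        train, val = vs.split_train_validation(mat, seed=49)
        with pytest.raises(KeyError, match="unknown features"):
            vs.ablation_suite(train, val, groups={"bogus": ["nope"]})

    def test_difficulty_split_sizes_and_ordering(self):
        mat = self._planted_mat(seed=50)
        easy, hard = vs.difficulty_split(mat, quantile=0.5)
        assert abs(len(easy.data) - len(hard.data)) <= len(mat.data) * 0.02 + 2
        assert (np.abs(easy.dvalues).mean() > np.abs(hard.dvalues).mean())

    @pytest.mark.parametrize("q", [0.0, 1.0])
    def test_degenerate_quantile_rejected(self, q):
        mat = self._planted_mat(seed=51)
        with pytest.raises(ValueError, match="quantile"):
            vs.difficulty_split(mat, quantile=q)

    def test_hard_trials_elevate_hard_coupled_features(self):
        """Features informative only on small-dValue trials rank higher there."""
        rng = np.random.default_rng(52)
        n = 1200
        y = rng.integers(0, 2, size=n)
        dv = rng.uniform(0, 1, size=n)
        hard_mask = dv < 0.33
        df = pd.DataFrame({roi: rng.normal(size=n) for roi in vs.ROI_NAMES})
        for roi in ("caudate", "putamen"):
            df[roi] += 1.5 * (2 * y - 1)  # always informative
        for roi in ("FFA", "OC"):
            df[roi] += np.where(hard_mask, 2.0 * (2 * y - 1), 0.0)
        df["subject_id"] = "sub-0"
        df["trial_sign"] = "+/-"
        df["label"] = np.where(y == 1, "optimal", "suboptimal")
        df["dvalue"] = dv
        mat = vs.assemble_matrix([df], seed=53)
        easy, hard = vs.difficulty_split(mat, quantile=1 / 3)

        def ffa_rank(subset, seed):
            rep, _ = forest.decode(subset, n_trees=150, seed=seed,
                                   n_importance_repeats=3)
            return rep.importance.set_index("feature").loc["FFA", "rank"]

        assert ffa_rank(hard, 54) < ffa_rank(easy, 55)
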