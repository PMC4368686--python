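import itertools

import numpy as np
import pandas as pd
import pytest

from hrvrisk.models import (
    ModelSpec,
    RuleTree,
    baseline_chi2,
    baseline_t_test,
    baseline_table,
    evaluate,
    fit_model,
    holdout_split,
    report_from_predictions,
    rule_tree_classify,
    rule_tree_evaluate,
    threshold_classifier_roc,
    tune_model,
)
from hrvrisk.synthetic import simulate_feature_table


class TestBaselineTests:
    def test_age_p_value_from_published_summaries(self):
        assert baseline_t_test(71.4, 7.0, 122, 74.1, 6.5, 17) == pytest.approx(
            0.136, abs=0.005
        )

    def test_lvmi_p_value_from_published_summaries(self):
        assert baseline_t_test(130.1, 26.1, 122, 140.2, 25.1, 17) == pytest.approx(
            0.135, abs=0.005
        )

    def test_identical_groups_p_one(self):
        assert baseline_t_test(10.0, 2.0, 50, 10.0, 2.0, 50) == pytest.approx(1.0)
        assert baseline_t_test(10.0, 0.0, 50, 10.0, 0.0, 50) == 1.0

    def test_sex_chi2_from_published_counts(self):
        # high-risk female 8/17 vs low-risk female 41/122
        assert baseline_chi2(8, 9, 41, 81) == pytest.approx(0.277, abs=0.005)

    def test_equal_proportions_p_one(self):
        assert baseline_chi2(10, 10, 20, 20) == pytest.approx(1.0)

    def test_perfect_association_tiny_p(self):
        assert baseline_chi2(10, 0, 0, 10) < 1e-4

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert baseline_chi2(0, 0, 5, 5) == 1.0

    def test_baseline_table_layout(self, rng):
        df = pd.DataFrame({
            "age": rng.normal(70, 5, 60),
            "smoker": rng.integers(0, 2, 60),
            "label": np.r_[np.zeros(40, dtype=int), np.ones(20, dtype=int)],
        })
        tab = baseline_table(df)
        assert set(tab.index) == {"age", "smoker"}
        assert tab.loc["age", "kind"] == "continuous"
        assert tab.loc["smoker", "kind"] == "categorical"
        assert ((0 <= tab["p_value"]) & (tab["p_value"] <= 1)).all()


class TestHoldoutSplit:
    def make_cohort(self, n_low=122, n_high=17, seed=0):
        return simulate_feature_table(n_low, n_high, 2, 2, seed=seed)

    def test_60_40_sizes(self):
        train, test = holdout_split(self.make_cohort(), seed=1)
        assert len(train) == 83
        assert len(test) == 56

    def test_stratified_test_has_seven_high_risk(self):
        _, test = holdout_split(self.make_cohort(), seed=1)
        assert int(test["label"].sum()) == 7

    def test_partition_is_disjoint_and_exhaustive(self):
        df = self.make_cohort()
        train, test = holdout_split(df, seed=2)
        assert len(train) + len(test) == len(df)
        assert set(train.index).isdisjoint(test.index)

    def test_deterministic(self):
        df = self.make_cohort()
        a1, b1 = holdout_split(df, seed=5)
        a2, b2 = holdout_split(df, seed=5)
        assert a1.equals(a2) and b1.equals(b2)

    def test_single_class_rejected(self):
        df = self.make_cohort().assign(label=0)
        with pytest.raises(ValueError):
            holdout_split(df)


class TestTuneModel:
    def test_single_combination_returned_unchanged(self):
        df = simulate_feature_table(40, 40, 2, 3, effect_size=1.5, seed=0)
        spec = tune_model("C45", df, grid=[{"CF": 0.3, "MI": 5}], k=5, seed=0)
        assert spec.hyperparameters == {"CF": 0.3, "MI": 5}
        assert spec.family == "C45"

    def test_planted_signal_beats_majority_rate(self):
        df = simulate_feature_table(80, 40, 3, 5, effect_size=2.0, seed=1)
        spec = tune_model("RF", df, grid=[{"NT": 100, "NF": 2}], k=5, seed=1)
        est = fit_model(spec, df)
        acc = np.mean(est.predict(df[spec.features].to_numpy()) == df["label"])
        assert acc >= 80 / 120

    def test_empty_grid_rejected(self):
        df = simulate_feature_table(20, 20, 1, 1, seed=0)
        with pytest.raises(ValueError):
            tune_model("NB", df, grid=[])

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(family="NB", hyperparameters={"NT": 5})
        with pytest.raises(ValueError):
            ModelSpec(family="RF", hyperparameters={"NT": -1})
        with pytest.raises(ValueError):
            ModelSpec(family="XXX")


class TestEvaluate:
    def test_perfect_scorer_auc_100(self):
        y = np.r_[np.zeros(30, dtype=int), np.ones(10, dtype=int)]
        rep = report_from_predictions(y, y, y.astype(float))
        assert rep.auc == 100.0
        assert rep.acc == 100.0

    def test_random_scorer_auc_near_50(self):
        aucs = []
        for s in range(100):
            rng = np.random.default_rng(s)
            y = np.r_[np.zeros(45, dtype=int), np.ones(11, dtype=int)]
            scores = rng.random(56)
            rep = report_from_predictions(y, (scores > 0.5).astype(int), scores)
            aucs.append(rep.auc)
        assert np.mean(aucs) == pytest.approx(50.0, abs=5.0)

    def test_confusion_arithmetic(self):
        # TP=5 FN=2 TN=43 FP=6
        y = np.r_[np.ones(7, dtype=int), np.zeros(49, dtype=int)]
        pred = np.r_[np.ones(5), np.zeros(2), np.ones(6), np.zeros(43)].astype(int)
        rep = report_from_predictions(y, pred)
        assert rep.sen == pytest.approx(71.4, abs=0.05)
        assert rep.spe == pytest.approx(87.8, abs=0.05)
        assert rep.acc == pytest.approx(85.7, abs=0.05)
        assert rep.confusion == {"TP": 5, "FN": 2, "TN": 43, "FP": 6}
        lo, hi = rep.acc_ci
        assert lo < rep.acc < hi

    def test_roc_is_monotone(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 80)
        rep = report_from_predictions(y, y, rng.random(80))
        fpr = [p[0] for p in rep.roc_points]
        tpr = [p[1] for p in rep.roc_points]
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_single_class_test_set_rejected(self):
        with pytest.raises(ValueError):
            report_from_predictions(np.zeros(10, dtype=int), np.zeros(10, dtype=int))

    def test_fitted_model_evaluation(self):
        train = simulate_feature_table(60, 30, 2, 2, effect_size=2.0, seed=0)
        test = simulate_feature_table(40, 20, 2, 2, effect_size=2.0, seed=1)
        spec = tune_model("NB", train, k=5, seed=0)
        rep = evaluate(fit_model(spec, train), spec, test)
        assert rep.auc > 80.0


class TestRuleTree:
    def test_high_hrvti_is_low_risk_regardless(self):
        f = {"HRVTi": 20.0, "SampEn": 0.1, "LF_pct": 1.0, "LF": 1.0, "CD": 0.1}
        assert rule_tree_classify(f) == "low_risk"

    def test_depressed_hrvti_and_sampen_is_high_risk(self):
        f = {"HRVTi": 10.0, "SampEn": 0.8, "LF_pct": 50.0, "LF": 0.0, "CD": 9.0}
        assert rule_tree_classify(f) == "high_risk"

    def test_cd_branch(self):
        f = {"HRVTi": 10.0, "SampEn": 1.2, "LF_pct": 25.0, "LF": 0.02, "CD": 3.0}
        assert rule_tree_classify(f) == "high_risk"
        assert rule_tree_classify({**f, "CD": 4.0}) == "low_risk"

    def test_boundary_equality_falls_through(self):
        tree = RuleTree()
        f = {"HRVTi": 13.6, "SampEn": 0.997, "LF_pct": 18.1, "LF": 0.011, "CD": 3.43}
        # every comparison is strict, so equality proceeds to the final
        # branch where LF > cut fails -> low risk
        assert rule_tree_classify(f, tree) == "low_risk"

    def test_truth_table_over_all_threshold_sides(self):
        tree = RuleTree()
        lo_hi = {
            "HRVTi": (10.0, 20.0), "SampEn": (0.8, 1.2),
            "LF_pct": (10.0, 25.0), "LF": (0.005, 0.02), "CD": (3.0, 4.0),
        }
        for bits in itertools.product([0, 1], repeat=5):
            f = {k: v[b] for (k, v), b in zip(lo_hi.items(), bits)}
            hrvti_low, sampen_low = bits[0] == 0, bits[1] == 0
            lfpct_low, lf_low, cd_low = bits[2] == 0, bits[3] == 0, bits[4] == 0
            if not hrvti_low:
                want = "low_risk"
            elif sampen_low or lfpct_low:
                want = "high_risk"
            elif (not lf_low) and cd_low:
                want = "high_risk"
            else:
                want = "low_risk"
            assert rule_tree_classify(f, tree) == want, bits

    def test_missing_feature_named_in_error(self):
        with pytest.raises(ValueError, match="SampEn"):
            rule_tree_classify(
                {"HRVTi": 10.0, "SampEn": float("nan"), "LF_pct": 20.0,
                 "LF": 0.01, "CD": 3.0}
            )

    def test_rule_tree_auc_is_mean_of_sen_spe(self, rng):
        df = pd.DataFrame({
            "HRVTi": rng.uniform(5, 25, 80),
            "SampEn": rng.uniform(0.5, 1.5, 80),
            "LF_pct": rng.uniform(5, 50, 80),
            "LF": rng.uniform(0.001, 0.02, 80),
            "CD": rng.uniform(1, 6, 80),
            "label": rng.integers(0, 2, 80),
        })
        rep = rule_tree_evaluate(df)
        assert rep.auc == pytest.approx((rep.sen + rep.spe) / 2.0, abs=1e-9)


class TestThresholdClassifier:
    def test_label_identical_parameter_auc_100(self):
        y = np.r_[np.zeros(30, dtype=int), np.ones(10, dtype=int)]
        rep = threshold_classifier_roc(y.astype(float), y)
        assert rep.auc == 100.0

    def test_independent_parameter_auc_near_50(self):
        aucs = []
        for s in range(100):
            rng = np.random.default_rng(s)
            y = np.r_[np.zeros(60, dtype=int), np.ones(15, dtype=int)]
            aucs.append(threshold_classifier_roc(rng.random(75), y).auc)
        assert np.mean(aucs) == pytest.approx(50.0, abs=5.0)

    def test_constant_parameter_auc_50(self):
        y = np.r_[np.zeros(10, dtype=int), np.ones(5, dtype=int)]
        assert threshold_classifier_roc(np.ones(15), y).auc == 50.0

    def test_lvmi_group_gaussians_bracket_published_discrimination(self):
        # LVMi drawn from the two printed group distributions: modest
        # single-parameter discrimination, mean AUC in the mid range
        aucs = []
        for s in range(200):
            rng = np.random.default_rng(s)
            vals = np.r_[rng.normal(130.1, 26.1, 122), rng.normal(140.2, 25.1, 17)]
            y = np.r_[np.zeros(122, dtype=int), np.ones(17, dtype=int)]
            aucs.append(threshold_classifier_roc(vals, y).auc)
        assert 55.0 <= np.mean(aucs) <= 70.0
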