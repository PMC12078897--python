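"""Evaluation statistics vs hand arithmetic and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from habitatmri.evaluate import (
    calibration_curve,
    cohens_kappa,
    cohort_comparison_tests,
    decision_curve,
    delong_test,
    icc_two_way,
    linear_shap,
    roc_auc_delong,
    threshold_metrics,
)
from habitatmri.models import fit_logistic
from oracles import auc_bruteforce, fisher_exact_bruteforce


class TestAuc:
    def test_perfect_separation(self):
        auc, ci, _ = roc_auc_delong([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert ci[1] <= 1.0

    def test_tiny_hand_examples(self):
        auc, *_ = roc_auc_delong([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 0])
        assert auc == 1.0
        auc, *_ = roc_auc_delong([0.9, 0.6, 0.8, 0.7], [1, 1, 0, 0])
        assert auc == 0.5

    def test_equals_bruteforce_concordance_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 200))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc, *_ = roc_auc_delong(scores, labels)
            assert auc == pytest.approx(auc_bruteforce(scores, labels), abs=1e-12)

    def test_ci_width_shrinks_like_sqrt_n(self, rng):
        widths = []
        for n in (100, 400):
            scores = np.concatenate([rng.normal(1, 1, n // 2), rng.normal(0, 1, n // 2)])
            labels = np.array([1] * (n // 2) + [0] * (n // 2))
            _, ci, _ = roc_auc_delong(scores, labels)
            widths.append(ci[1] - ci[0])
        assert widths[1] == pytest.approx(widths[0] / 2, rel=0.35)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_delong([0.1, 0.2], [1, 1])


class TestDelongTest:
    def test_self_comparison_p_is_one(self, rng):
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        assert delong_test(s, s, y) == 1.0

    def test_symmetric_in_model_order(self, rng):
        y = np.array([0, 1] * 30)
        a, b = rng.random(60), rng.random(60)
        assert delong_test(a, b, y) == pytest.approx(delong_test(b, a, y))

    def test_informative_vs_noise_detected(self):
        rng = np.random.default_rng(5)
        rejections = 0
        for _ in range(20):
            n = 500
            y = rng.integers(0, 2, n)
            good = y + rng.normal(0, 0.7, n)
            noise = rng.normal(0, 1, n)
            rejections += delong_test(good, noise, y) < 0.01
        assert rejections >= 19


class TestThresholdMetrics:
    def test_hand_confusion_matrix(self):
        # TP=9 FN=1 TN=8 FP=2
        y = np.array([1] * 10 + [0] * 10)
        s = np.array([0.9] * 9 + [0.1] + [0.8] * 2 + [0.2] * 8)
        m = threshold_metrics(s, y, 0.5)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["precision"] == pytest.approx(9 / 11)

    def test_threshold_below_all_scores(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        m = threshold_metrics(rng.random(30) + 1.0, y, 0.0)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_no_positive_calls_precision_missing(self):
        m = threshold_metrics([0.1, 0.2], [0, 1], 0.9)
        assert np.isnan(m["precision"])
        assert all(0 <= m[k] <= 1 for k in ("sensitivity", "specificity", "accuracy"))


class TestCurves:
    def test_calibrated_scores_match_observed(self):
        rng = np.random.default_rng(11)
        p = rng.random(5000)
        y = (rng.random(5000) < p).astype(int)
        cal = calibration_curve(p, y, n_bins=10)
        # each bin holds ~500 patients: binomial error ~ 0.045 at 2 sigma
        assert np.all(np.abs(cal["observed"] - cal["predicted"]) < 0.06)

    def test_decision_curve_references(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        dc = decision_curve(rng.random(200), y, thresholds=[0.1, float(y.mean()), 0.9])
        assert np.all(dc["treat_none"] == 0.0)
        at_prev = dc.loc[np.isclose(dc["threshold"], y.mean()), "treat_all"].iloc[0]
        assert at_prev == pytest.approx(0.0, abs=1e-12)

    def test_better_model_dominates_midrange(self):
        rng = np.random.default_rng(3)
        n = 4000
        y = rng.integers(0, 2, n)
        good = np.clip(0.5 * y + 0.25 + rng.normal(0, 0.1, n), 0.01, 0.99)
        weak = np.clip(0.5 * y + 0.25 + rng.normal(0, 0.45, n), 0.01, 0.99)
        grid = np.linspace(0.3, 0.7, 9)
        nb_good = decision_curve(good, y, grid)["net_benefit"]
        nb_weak = decision_curve(weak, y, grid)["net_benefit"]
        assert (nb_good >= nb_weak - 1e-9).mean() > 0.8


class TestLinearShap:
    def _model(self, rng, n=60, p=4):
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
        y = (X["f0"].to_numpy() + 0.5 * rng.normal(size=n) > 0).astype(int)
        return fit_logistic(X, y), X

    def test_background_mean_has_zero_attribution(self, rng):
        model, X = self._model(rng)
        bg = X.mean()
        rep = linear_shap(model, pd.DataFrame([bg]), background=bg)
        np.testing.assert_allclose(rep.values.to_numpy(), 0.0, atol=1e-10)

    def test_additivity_to_log_odds(self, rng):
        model, X = self._model(rng)
        rep = linear_shap(model, X)
        recon = rep.base_value + rep.values.sum(axis=1).to_numpy()
        np.testing.assert_allclose(recon, model.decision(X), atol=1e-8)

    def test_zero_coefficient_zero_attribution(self, rng):
        model, X = self._model(rng)
        model.coef[2] = 0.0
        rep = linear_shap(model, X)
        assert np.all(rep.values["f2"] == 0.0)

    def test_missing_feature_rejected(self, rng):
        model, X = self._model(rng)
        with pytest.raises(ValueError):
            linear_shap(model, X.drop(columns=["f1"]))


class TestAgreement:
    def test_hand_kappa(self):
        # po = 0.70, pe = 0.50 -> kappa = 0.40
        assert cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.40)

    def test_perfect_agreement(self):
        assert cohens_kappa([[25, 0], [0, 25]]) == 1.0
        r = np.random.default_rng(0).normal(size=(30, 1))
        assert icc_two_way(np.hstack([r, r])) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_marginals_flagged(self):
        assert np.isnan(cohens_kappa([[10, 0], [0, 0]]))

    def test_icc_matches_variance_ratio_at_scale(self):
        rng = np.random.default_rng(4)
        n = 500
        truth = rng.normal(0, 2.0, n)
        ratings = truth[:, None] + rng.normal(0, 1.0, (n, 2))
        expected = 4.0 / 5.0  # var_true / (var_true + var_noise)
        assert icc_two_way(ratings) == pytest.approx(expected, abs=0.05)


class TestCohortComparisons:
    def test_identical_groups_p_near_one(self):
        base = pd.DataFrame({"bin": [0, 1] * 20, "cont": np.tile(np.arange(40), 1)})
        df = pd.concat([base.assign(group=0), base.assign(group=1)], ignore_index=True)
        out = cohort_comparison_tests(df, "group")
        assert out.loc["bin", "p"] == pytest.approx(1.0)
        assert out.loc["cont", "p"] > 0.9

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = [[8, 2], [1, 9]]
        from scipy import stats

        _, p_scipy = stats.fisher_exact(table)
        assert p_scipy == pytest.approx(fisher_exact_bruteforce(table), abs=1e-12)
        # a sparse 2x2 routes to Fisher inside the comparison table
        g = [0] * 10 + [1] * 10
        x = [1] * 8 + [0] * 2 + [1] * 1 + [0] * 9
        out = cohort_comparison_tests(pd.DataFrame({"group": g, "x": x}), "group")
        assert out.loc["x", "test"] == "fisher"
        assert out.loc["x", "p"] == pytest.approx(p_scipy)

    def test_mann_whitney_extreme_arrangement(self):
        from itertools import combinations

        from scipy import stats

        a, b = [1, 2, 3], [4, 5, 6]
        # exhaustive: of C(6,3)=20 rank assignments only 1 is as extreme
        ranks = set(range(1, 7))
        count = sum(
            1 for c in combinations(ranks, 3) if sum(c) <= 1 + 2 + 3
        )
        assert count / 20 == pytest.approx(1 / 20)
        _, p = stats.mannwhitneyu(a, b, alternative="less", method="exact")
        assert p == pytest.approx(1 / 20)

    def test_constant_variable_skipped(self):
        df = pd.DataFrame({"group": [0, 1] * 10, "flat": 1.0})
        out = cohort_comparison_tests(df, "group")
        assert "skipped" in out.loc["flat", "test"]
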