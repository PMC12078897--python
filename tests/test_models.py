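"""Subregion/final logistic models, ITH index and candidate enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from habitatmri.models import (
    FINAL_MODEL_NAMES,
    SUBREGIONS,
    enumerate_candidates,
    fit_final_models,
    fit_logistic,
    fit_subregion_model,
    ith_index,
    select_habitat_model,
    univariable_multivariable_lr,
    youden_threshold,
)


class TestLogisticFits:
    def test_intercept_only_predicts_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        m = fit_logistic(pd.DataFrame(index=range(100)), y)
        p = m.predict_probability(pd.DataFrame(index=range(100)))
        np.testing.assert_allclose(p, 0.30, atol=1e-12)

    def test_two_by_two_odds_ratio_closed_form(self):
        # counts [[40,10],[10,40]] -> OR = (40*40)/(10*10) = 16
        x = np.array([0] * 50 + [1] * 50, dtype=float)
        y = np.array([0] * 40 + [1] * 10 + [0] * 10 + [1] * 40)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        beta_per_unit = m.coef[0] / m.sd[0]
        assert np.exp(beta_per_unit) == pytest.approx(16.0, abs=1e-6)

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=60)})
        y = (X["a"] > 0).astype(int).to_numpy()  # separable -> ridge fallback
        model = fit_subregion_model(X, y, "DWI_habitat1")
        p = model.predict_probability(X)
        assert np.all((p > 0) & (p < 1))


class TestIthIndex:
    def test_mean_of_two(self):
        probs = {"T2WI_habitat1": np.array([0.8]), "DWI_habitat2": np.array([0.4])}
        assert ith_index(probs, {"T2WI_habitat1", "DWI_habitat2"})[0] == pytest.approx(0.6)

    def test_singleton_is_identity(self):
        probs = {r: np.array([0.3, 0.9]) for r in SUBREGIONS}
        np.testing.assert_allclose(ith_index(probs, {"DWI_habitat2"}), [0.3, 0.9])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=4, unique=True))
    def test_bounded_and_permutation_invariant(self, vals):
        regions = list(SUBREGIONS[: len(vals)])
        probs = {r: np.array([v]) for r, v in zip(regions, vals)}
        idx = ith_index(probs, set(regions))[0]
        assert 0.0 <= idx <= 1.0
        idx_rev = ith_index(dict(reversed(list(probs.items()))), set(reversed(regions)))[0]
        assert idx == pytest.approx(idx_rev)

    def test_missing_member_uses_available(self):
        probs = {"T2WI_habitat1": np.array([0.8])}
        out = ith_index(probs, {"T2WI_habitat1", "DWI_habitat2"})
        assert out[0] == pytest.approx(0.8)


class TestCandidates:
    def test_exactly_13_candidates(self):
        cands = [c.subset for c in enumerate_candidates()]
        assert len(cands) == 13
        assert len(set(cands)) == 13

    def test_within_sequence_pairs_excluded(self):
        cands = [c.subset for c in enumerate_candidates()]
        assert frozenset({"DWI_habitat1", "DWI_habitat2"}) not in cands
        assert frozenset({"T2WI_habitat1", "T2WI_habitat2"}) not in cands

    def test_cross_sequence_pair_present(self):
        cands = [c.subset for c in enumerate_candidates()]
        assert frozenset({"T2WI_habitat1", "DWI_habitat2"}) in cands
        singletons = [c for c in cands if len(c) == 1]
        assert len(singletons) == 4

    def test_selection_argmax_and_tie_break(self, rng):
        y_tr = np.array([0, 1] * 10)
        probs_tr = {r: rng.random(20) for r in SUBREGIONS}
        models = {}
        aucs = {c.subset: 0.5 for c in enumerate_candidates()}
        winner = frozenset({"T2WI_habitat1", "DWI_habitat2"})
        aucs[winner] = 0.9
        hm = select_habitat_model(aucs, models, None, y_tr, probs_tr)
        assert hm.subset == winner
        # exact tie: smaller subset wins
        aucs[frozenset({"DWI_habitat1"})] = 0.9
        hm = select_habitat_model(aucs, models, None, y_tr, probs_tr)
        assert hm.subset == frozenset({"DWI_habitat1"})


class TestUnivariableMultivariable:
    def test_two_by_two_or_and_ci(self):
        df = pd.DataFrame(
            {
                "grade": [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40,
                "marker": [0.0] * 50 + [1.0] * 50,
            }
        )
        table, retained = univariable_multivariable_lr(df)
        assert table.loc["marker", "or_uni"] == pytest.approx(16.0, rel=1e-4)
        assert table.loc["marker", "ci_low_uni"] > 1.0
        assert retained == ["marker"]

    def test_pure_noise_rarely_retained(self):
        rng = np.random.default_rng(0)
        kept = 0
        reps = 60
        for _ in range(reps):
            df = pd.DataFrame(
                {"grade": rng.integers(0, 2, 200), "x": rng.integers(0, 2, 200).astype(float)}
            )
            _, retained = univariable_multivariable_lr(df)
            kept += "x" in retained
        assert kept / reps < 0.15  # ~ alpha = 0.05 within binomial noise

    def test_planted_generator_effects_retained(self):
        from habitatmri.synthetic import CohortConfig, covariate_table, generate_cohort

        hits = 0
        for seed in range(3):
            cohort = generate_cohort(CohortConfig(n_patients=160, seed=50 + seed))
            tab = covariate_table(cohort)
            _, retained = univariable_multivariable_lr(tab)
            hits += {"tumor_margin_infiltrative", "t2wi_targetoid_sign"} <= set(retained)
        assert hits >= 2

    def test_single_level_covariate_dropped(self):
        df = pd.DataFrame({"grade": [0, 1] * 20, "flat": np.ones(40)})
        table, retained = univariable_multivariable_lr(df)
        assert "flat" not in table.index and retained == []


class TestFinalModels:
    def _blocks(self, rng, n=80):
        y = (rng.random(n) > 0.5).astype(int)
        mk = lambda p, s: pd.DataFrame(
            rng.normal(size=(n, p)) + s * y[:, None], columns=[f"{s}_{i}" for i in range(p)]
        )
        return {"clinlabimag": mk(3, 1), "radiomics": mk(5, 2), "habitat": mk(1, 3)}, y

    def test_seven_models_with_expected_names(self, rng):
        blocks, y = self._blocks(rng)
        bundle = fit_final_models(blocks, y)
        assert tuple(bundle.models) == FINAL_MODEL_NAMES
        assert set(bundle.thresholds) == set(FINAL_MODEL_NAMES)

    def test_combined_dimension_is_block_sum(self, rng):
        blocks, y = self._blocks(rng)
        bundle = fit_final_models(blocks, y)
        dims = {k: v.shape[1] for k, v in blocks.items()}
        assert len(bundle.models["Combined"].feature_names) == sum(dims.values())

    def test_empty_block_rejected(self, rng):
        blocks, y = self._blocks(rng)
        blocks["habitat"] = blocks["habitat"].iloc[:, :0]
        with pytest.raises(ValueError):
            fit_final_models(blocks, y)

    def test_youden_threshold_maximises_j(self, rng):
        y = np.array([0] * 50 + [1] * 50)
        s = np.concatenate([rng.normal(0.3, 0.1, 50), rng.normal(0.7, 0.1, 50)])
        t = youden_threshold(s, y)
        from habitatmri.evaluate import threshold_metrics

        m = threshold_metrics(s, y, t)
        j_at_t = m["sensitivity"] + m["specificity"] - 1
        for other in np.linspace(0.01, 0.99, 33):
            mo = threshold_metrics(s, y, other)
            assert j_at_t >= mo["sensitivity"] + mo["specificity"] - 1 - 1e-9
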