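"""Explainability: Shapley axioms and oracle agreement, PDP/ICE identities,
importances, phenotype clustering, correlations, surrogate rules."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import adjusted_rand_score
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from painecg.errors import ValidationError
from painecg.explain import (
    exact_shapley,
    feature_correlations,
    gini_importance,
    global_surrogate,
    ice_phenotypes,
    partial_dependence_ice,
    permutation_importance,
    shapley_interaction,
    tree_shapley,
)


class TestExactShapley:
    def test_additive_model_recovers_coefficients(self):
        f = lambda X: 2 * X[:, 0] + X[:, 1]
        exp = exact_shapley(f, np.array([1.0, 1.0]), np.zeros((1, 2)))
        np.testing.assert_allclose(exp.phi, [2.0, 1.0], atol=1e-12)

    def test_product_model_splits_credit_equally(self):
        f = lambda X: X[:, 0] * X[:, 1]
        exp = exact_shapley(f, np.array([1.0, 1.0]), np.zeros((1, 2)))
        np.testing.assert_allclose(exp.phi, [0.5, 0.5], atol=1e-12)

    def test_constant_model_attributes_nothing(self):
        f = lambda X: np.full(len(X), 7.0)
        exp = exact_shapley(f, np.ones(3), np.zeros((2, 3)))
        np.testing.assert_allclose(exp.phi, 0.0, atol=1e-12)
        assert exp.base_value == 7.0

    def test_symmetry_axiom(self):
        f = lambda X: X[:, 0] + X[:, 1]  # interchangeable features
        exp = exact_shapley(f, np.array([2.0, 2.0]), np.zeros((1, 2)))
        assert exp.phi[0] == pytest.approx(exp.phi[1], abs=1e-12)

    def test_dummy_axiom(self):
        f = lambda X: 3 * X[:, 0]
        exp = exact_shapley(f, np.array([1.0, 5.0]), np.zeros((1, 2)))
        assert exp.phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_feature_limit_enforced(self):
        with pytest.raises(ValidationError, match="exceeds"):
            exact_shapley(lambda X: X[:, 0], np.zeros(20), np.zeros((1, 20)))


class TestTreeShapley:
    def test_stump_attributes_only_split_feature(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] > 0).astype(int)
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        exp = tree_shapley(stump, X[:5], X[:20])
        for e in exp:
            assert np.all(e.phi[1:] == 0.0)

    def test_matches_exact_enumeration_on_ensemble(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 8))
        y = X[:, 0] - 2 * X[:, 1] + X[:, 2] * X[:, 3] + 0.1 * rng.normal(size=300)
        rf = RandomForestRegressor(n_estimators=12, max_depth=5, random_state=1).fit(X, y)
        bg = X[:6]
        tree_exp = tree_shapley(rf, X[100:103], bg)
        for i, row in enumerate(X[100:103]):
            oracle = exact_shapley(rf.predict, row, bg)
            np.testing.assert_allclose(tree_exp[i].phi, oracle.phi, atol=1e-4)

    def test_efficiency_holds_per_row(self, fitted_cascade):
        from painecg.cascade import standardize

        model, test = fitted_cascade
        X, _ = standardize(test, scaler=model.scaler)
        X = X[model.selected_features].to_numpy()
        exp = tree_shapley(model.classifier, X[:4], X[4:24])
        for e in exp:
            assert e.efficiency_gap < 1e-6

    def test_modulated_features_outrank_noise(self, fitted_cascade):
        """The generator's pain-modulated biomarkers carry the attribution mass."""
        from painecg.cascade import standardize

        model, test = fitted_cascade
        X, _ = standardize(test, scaler=model.scaler)
        X = X[model.selected_features].to_numpy()
        exp = tree_shapley(model.classifier, X[:12], X[12:44])
        mean_abs = np.mean(np.abs([e.phi for e in exp]), axis=0)
        modulated = {
            "ecg_rms", "ecg_peak_to_peak", "ecg_power", "decg_rms",
            "rr_mean", "rr_std", "sdnn", "rr_rmssd", "pnn50",
            "hr_mean", "ibi_mean", "tri_index", "tinn",
        }
        top3 = [model.selected_features[i] for i in np.argsort(-mean_abs)[:3]]
        assert set(top3) <= modulated


class TestShapleyInteraction:
    def test_additive_model_has_zero_interactions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 2))
        y = 2 * X[:, 0] - X[:, 1]
        rf = RandomForestRegressor(n_estimators=10, max_depth=3, random_state=0).fit(X, y)
        # additive structure: check a forest of stumps, which cannot mix features
        stumps = RandomForestRegressor(n_estimators=20, max_depth=1, random_state=0).fit(X, y)
        inter = shapley_interaction(stumps, X[:4], X[:10])
        assert np.max(np.abs(inter[:, 0, 1])) < 1e-6

    def test_product_model_has_nonzero_interaction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 2))
        y = X[:, 0] * X[:, 1]
        rf = RandomForestRegressor(n_estimators=20, max_depth=6, random_state=0).fit(X, y)
        vals = shapley_interaction(rf, X[:6], X[:20], pair=(0, 1))
        assert np.max(np.abs(vals)) > 0.01

    def test_rows_sum_to_shapley_values(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        y = X[:, 0] * X[:, 1] + X[:, 2]
        rf = RandomForestRegressor(n_estimators=8, max_depth=4, random_state=0).fit(X, y)
        inter = shapley_interaction(rf, X[:3], X[:8])
        phi = np.array([e.phi for e in tree_shapley(rf, X[:3], X[:8])])
        np.testing.assert_allclose(inter.sum(axis=2), phi, atol=1e-10)


class TestImportances:
    def test_gini_concentrates_on_single_informative_feature(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 5))
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        rep = gini_importance(rf)
        assert rep.mean[0] > 0.8
        assert rep.mean.sum() == pytest.approx(1.0)

    def test_gini_near_uniform_under_pure_noise_labels(self):
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 6))
            y = rng.integers(0, 2, size=200)
            rf = RandomForestClassifier(n_estimators=40, random_state=seed).fit(X, y)
            worst = max(worst, gini_importance(rf).mean.max())
        assert worst < 3.0 / X.shape[1]

    def test_permutation_unused_feature_is_null(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 2))
        y = (X[:, 0] > 0).astype(int)
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        rep = permutation_importance(stump, X, y, "accuracy", n_repeats=30, seed=0)
        assert abs(rep.mean[1]) <= 2 * max(rep.sd[1], 1e-12)

    def test_perfect_binary_feature_costs_half_accuracy(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=400)
        X = np.column_stack([y.astype(float), rng.normal(size=400)])
        tree = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        rep = permutation_importance(tree, X, y, "accuracy", n_repeats=50, seed=0)
        assert rep.mean[0] == pytest.approx(0.5, abs=0.1)

    def test_mean_plus_minus_sd_report_format(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = (X[:, 0] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        rep = permutation_importance(rf, X, y, "accuracy", n_repeats=10, seed=0)
        line = f"{rep.features[0]}: {rep.mean[0]:.4f} ± {rep.sd[0]:.4f}"
        assert "±" in line and rep.n_repeats == 10

    def test_metric_model_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 2))
        reg = RandomForestRegressor(n_estimators=5, random_state=0).fit(X, X[:, 0])
        with pytest.raises(ValidationError):
            permutation_importance(reg, X, X[:, 0] > 0, "accuracy", n_repeats=2)


class TestPDPICE:
    def test_closed_form_quadratic_plus_shift(self):
        f = lambda X: X[:, 0] ** 2 + X[:, 1]
        X = np.array([[0.0, 0.0], [0.0, 2.0]])
        grid = np.linspace(-1, 1, 11)
        res = partial_dependence_ice(f, X, 0, grid=grid)
        np.testing.assert_allclose(res.pd_values, grid**2 + 1.0, atol=1e-12)
        np.testing.assert_allclose(res.ice[0], grid**2, atol=1e-12)
        np.testing.assert_allclose(res.ice[1], grid**2 + 2.0, atol=1e-12)

    def test_ignored_feature_gives_flat_curves(self):
        f = lambda X: X[:, 0]
        X = np.random.default_rng(0).normal(size=(20, 2))
        res = partial_dependence_ice(f, X, 1, n_grid=10)
        assert np.ptp(res.pd_values) == 0.0
        assert np.all(np.ptp(res.ice, axis=1) == 0.0)

    def test_pd_is_exact_mean_of_ice(self, fitted_cascade):
        from painecg.cascade import standardize

        model, test = fitted_cascade
        X, _ = standardize(test, scaler=model.scaler)
        X = X[model.selected_features]
        res = partial_dependence_ice(model.classifier, X, model.selected_features[0])
        np.testing.assert_array_equal(res.pd_values, res.ice.mean(axis=0))


class TestICEPhenotypes:
    @staticmethod
    def _two_family_result():
        grid = np.linspace(0, 1, 20)
        rng = np.random.default_rng(0)
        rising = grid[None, :] * rng.uniform(0.8, 1.2, size=(30, 1))
        flat = np.zeros((30, 20)) + rng.normal(0, 0.01, size=(30, 20))
        ice = np.vstack([rising, flat])
        from painecg.explain import PDPResult

        return PDPResult("x", grid, ice.mean(axis=0), ice), np.r_[np.zeros(30), np.ones(30)]

    def test_recovers_two_parametric_families(self):
        res, truth = self._two_family_result()
        labels, _ = ice_phenotypes(res, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_identical_curves_have_zero_dispersion(self):
        from painecg.explain import PDPResult

        grid = np.linspace(0, 1, 10)
        ice = np.tile(grid, (8, 1))
        res = PDPResult("x", grid, ice.mean(axis=0), ice)
        labels, dispersion = ice_phenotypes(res, k=3, seed=0)
        assert dispersion == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        res, _ = self._two_family_result()
        a, _ = ice_phenotypes(res, k=3, seed=5)
        b, _ = ice_phenotypes(res, k=3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_k_larger_than_n_rejected(self):
        res, _ = self._two_family_result()
        with pytest.raises(ValidationError):
            ice_phenotypes(res, k=100)


class TestCorrelations:
    def test_power_tracks_rms_and_hr_opposes_ibi(self, default_feature_table):
        corr = feature_correlations(default_feature_table)
        assert corr.loc["ecg_power", "ecg_rms"] > 0.95
        assert corr.loc["hr_mean", "ibi_mean"] < -0.95

    def test_unit_diagonal(self, default_feature_table):
        corr = feature_correlations(default_feature_table)
        diag = np.diag(corr.loc[["ecg_rms", "rr_mean", "sdnn"], ["ecg_rms", "rr_mean", "sdnn"]])
        np.testing.assert_allclose(diag, 1.0)


class TestGlobalSurrogate:
    def test_self_representable_model_has_perfect_fidelity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 3))
        y = ((X[:, 0] > 0) & (X[:, 1] > 0.5)).astype(int)
        shallow = DecisionTreeClassifier(max_depth=2, random_state=0).fit(X, y)
        res = global_surrogate(shallow, X, max_depth=5, seed=0)
        assert res.fidelity == 1.0

    def test_rules_are_if_and_then_with_thresholds(self, fitted_cascade):
        from painecg.cascade import standardize

        model, test = fitted_cascade
        X, _ = standardize(test, scaler=model.scaler)
        res = global_surrogate(model.classifier, X[model.selected_features], seed=0)
        assert res.rules
        assert all(r.startswith("IF ") and " THEN " in r for r in res.rules)
        assert any(feat in r for r in res.rules for feat in model.selected_features)

    def test_fidelity_nondecreasing_with_depth(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 4))
        y = (X[:, 0] + X[:, 1] ** 2 + 0.5 * rng.normal(size=500) > 0.5).astype(int)
        rf = RandomForestClassifier(n_estimators=40, random_state=0).fit(X, y)
        for seed in range(3):
            shallow = global_surrogate(rf, X, max_depth=1, seed=seed).fidelity
            deep = global_surrogate(rf, X, max_depth=5, seed=seed).fidelity
            assert deep >= shallow
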