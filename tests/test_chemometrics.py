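"""PLS-DA stack: preprocessing, fitting, VIP, GA, dCV, ROC, SR, batch check."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabopipe.chemometrics import (
    ablation_rerun,
    classify,
    fit_plsda,
    ga_select,
    log10_autoscale,
    pca_batch_check,
    repeated_double_cv,
    roc_auc,
    selectivity_ratio,
    sr_tiers,
    vip_scores,
    vip_select,
)
from metabopipe.synthetic import feature_scenario


class TestLog10Autoscale:
    def test_power_of_ten_column(self):
        X = np.array([[1.0], [10.0], [100.0]])
        Z, rec = log10_autoscale(X, pseudo=0.0)
        np.testing.assert_allclose(rec["means"], [1.0])
        np.testing.assert_allclose(Z[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped_with_warning(self):
        X = np.column_stack([np.ones(5), np.arange(1.0, 6.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, rec = log10_autoscale(X, pseudo=0.0)
        assert Z.shape[1] == 1
        assert rec["kept_columns"] == [1]

    def test_autoscale_contract(self, rng):
        X = rng.lognormal(size=(30, 8))
        Z, _ = log10_autoscale(X)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-12)
        assert np.all(np.abs(Z.std(axis=0, ddof=1) - 1) < 1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            log10_autoscale(np.array([[-1.0, 2.0]]))


class TestPlsda:
    def test_perfectly_informative_variable(self, rng):
        n = 40
        y = (rng.random(n) > 0.5).astype(float)
        col = (y - y.mean()) / y.std(ddof=1)
        noise = rng.normal(size=(n, 4))
        yc = y - y.mean()
        noise -= np.outer(yc @ noise / (yc @ yc), yc).T  # orthogonal to y
        X = np.column_stack([col, noise])
        model = fit_plsda(X, y, A=1)
        yhat = model.predict(X)
        ss_res = ((y - yhat) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot > 0.999

    def test_regression_vector_matches_deflation_path(self, rng):
        X = rng.normal(size=(25, 6))
        y = (rng.random(25) > 0.5).astype(float)
        model = fit_plsda(X, y, A=3)
        # prediction via scores/loadings path: yhat = y_mean + sum_a q_a t_a
        yhat_b = model.predict(X)
        yhat_t = model.y_mean + model.x_scores @ model.y_loadings
        np.testing.assert_allclose(yhat_b, yhat_t, atol=1e-10)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(30, 10))
        y = (rng.random(30) > 0.5).astype(float)
        model = fit_plsda(X, y, A=4)
        g = model.x_scores.T @ model.x_scores
        off = g - np.diag(np.diag(g))
        assert np.all(np.abs(off) < 1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_plsda(rng.normal(size=(10, 3)), np.ones(10), A=1)

    def test_pure_noise_training_r2_small(self):
        r2s = []
        for seed in range(21):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 5))
            y = (rng.random(100) > 0.5).astype(float)
            model = fit_plsda(X, y, A=1)
            yhat = model.predict(X)
            r2s.append(1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum())
        assert np.median(r2s) < 0.2

    def test_classify_threshold_rule(self):
        np.testing.assert_array_equal(
            classify(np.array([0.49, 0.5, 0.51])), [0, 1, 1]
        )
        np.testing.assert_array_equal(classify(np.array([0.1, 0.2])), [0, 0])
        np.testing.assert_array_equal(
            classify(np.array([0.0, 0.3]), threshold=0.0), [1, 1]
        )


class TestVip:
    def test_norm_identity(self, rng):
        X = rng.normal(size=(40, 12))
        y = (rng.random(40) > 0.5).astype(float)
        model = fit_plsda(X, y, A=3)
        v = vip_scores(model)
        assert abs((v**2).sum() - 12) < 1e-8

    def test_closed_form_at_one_component(self, rng):
        X = rng.normal(size=(30, 7))
        y = (rng.random(30) > 0.5).astype(float)
        model = fit_plsda(X, y, A=1)
        v = vip_scores(model)
        w = model.weights[:, 0]
        expected = np.sqrt(7) * np.abs(w) / np.linalg.norm(w)
        np.testing.assert_allclose(v, expected, atol=1e-10)

    def test_informative_variable_attains_max_vip(self, rng):
        n = 60
        y = (rng.random(n) > 0.5).astype(float)
        X = rng.normal(size=(n, 9))
        X[:, 4] = (y - y.mean()) + 0.05 * rng.normal(size=n)
        model = fit_plsda(X, y, A=2)
        v = vip_scores(model)
        assert np.argmax(v) == 4
        assert v[4] > 1.0


class TestRoc:
    def test_perfect_and_inverted_ranking(self):
        y = np.array([0, 0, 1, 1])
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert auc == 1.0
        _, auc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), y)
        assert auc == 0.0

    @given(st.lists(st.integers(-5, 5), min_size=8, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_trapezoid_equals_mannwhitney_count(self, raw):
        yhat = np.array(raw, dtype=float) / 2.0
        y = np.array([0, 1] * 4)
        _, auc = roc_auc(yhat, y)
        pos = yhat[y == 1]
        neg = yhat[y == 0]
        wins = sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in pos for b in neg
        )
        oracle = wins / (len(pos) * len(neg))
        assert abs(auc - oracle) < 1e-12


class TestSelectivityRatio:
    def test_hand_computed_small_matrix(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(5, 3))
            X = X - X.mean(axis=0)
            y = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
            model = fit_plsda(X, y, A=2, center=False)
            sr = selectivity_ratio(model, X)
            b = model.coef
            t = X @ b / np.linalg.norm(b)
            p = X.T @ t / (t @ t)
            for j in range(3):
                explained = np.linalg.norm(t * p[j]) ** 2
                residual = np.linalg.norm(X[:, j] - t * p[j]) ** 2
                assert abs(sr[j] - explained / residual) < 1e-10

    def test_zero_covariance_variable_scores_zero(self, rng):
        n = 50
        y = np.array([0.0, 1.0] * 25)
        X = np.zeros((n, 2))
        X[:, 0] = y - y.mean()
        v = rng.normal(size=n)
        t = X[:, 0]
        v = v - v @ t / (t @ t) * t  # orthogonal to the target component
        X[:, 1] = v
        model = fit_plsda(X, y, A=1, center=False)
        sr = selectivity_ratio(model, X)
        assert sr[1] < 1e-20
        assert sr[0] > 0.1  # informative variable lands in the top tier

    def test_tiers_partition(self):
        sr = np.array([0.5, 0.08, 0.01])
        tiers = sr_tiers(sr)
        assert list(tiers["strong"]) == [0]
        assert list(tiers["moderate"]) == [1]
        assert list(tiers["below"]) == [2]

    def test_zero_coefficient_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = (rng.random(10) > 0.5).astype(float)
        model = fit_plsda(X, y, A=1)
        model.coef = np.zeros(3)
        with pytest.raises(ValueError):
            selectivity_ratio(model, X)


class TestGa:
    @staticmethod
    def _toy_fitness(mask):
        target = np.array([True, False, True, True, False])
        return float(np.sum(mask != target)) / 5.0

    def test_reaches_exhaustive_optimum_on_toy(self):
        res = ga_select(
            np.zeros((10, 5)), np.array([0, 1] * 5),
            fitness=self._toy_fitness, pop_size=20, n_generations=50, seed=3,
        )
        best = min(
            (self._toy_fitness(np.array(bits, dtype=bool))
             for bits in itertools.product([0, 1], repeat=5))
        )
        achieved = self._toy_fitness(
            np.isin(np.arange(5), res.selected)
        )
        assert achieved == best
        assert list(res.selected) == [0, 2, 3]

    def test_elitism_makes_best_fitness_monotone(self):
        res = ga_select(
            np.zeros((10, 6)), np.array([0, 1] * 5),
            fitness=lambda m: float(m.sum()) / 6.0 + 0.1,
            pop_size=12, n_generations=20, seed=1,
        )
        hist = res.trace["best_fitness_per_generation"]
        assert np.all(np.diff(hist) <= 0)

    def test_frozen_dynamics_without_mutation(self):
        p = 6
        init = np.tile(np.array([True, False, True, False, True, False]), (8, 1))
        res = ga_select(
            np.zeros((10, p)), np.array([0, 1] * 5),
            fitness=lambda m: float(m.sum()),
            mutation_rate=0.0, n_generations=10, seed=0,
            init_population=init,
        )
        assert np.all(res.trace["final_population"] == init[0][None, :])

    def test_too_few_variables_rejected(self):
        with pytest.raises(ValueError):
            ga_select(np.zeros((10, 1)), np.array([0, 1] * 5), fitness=lambda m: 0.0)


class TestDcv:
    def test_separable_data_perfect_every_repetition(self, rng):
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = 0.3 * rng.normal(size=(n, 6))
        X[:, 0] = 5.0 * (y - 0.5) + 0.05 * rng.normal(size=n)
        res = repeated_double_cv(X, y, n_repetitions=5, seed=0)
        assert np.all(res.sensitivity == 1.0)
        assert np.all(res.specificity == 1.0)

    def test_every_sample_predicted_each_repetition(self, rng):
        n = 30
        y = np.array([0, 1] * 15)
        X = rng.normal(size=(n, 5))
        res = repeated_double_cv(X, y, n_repetitions=3, seed=1)
        assert res.predictions.shape == (3, n)
        assert np.all(np.isfinite(res.predictions))

    def test_same_seed_reproducible(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.array([0, 1] * 15)
        a = repeated_double_cv(X, y, n_repetitions=3, seed=7)
        b = repeated_double_cv(X, y, n_repetitions=3, seed=7)
        np.testing.assert_array_equal(a.predictions, b.predictions)
        np.testing.assert_array_equal(a.chosen_components, b.chosen_components)

    def test_permuted_labels_auc_near_half(self):
        X, y, _, _ = feature_scenario(seed=2, n_noise_features=60, n_markers=10)
        Z, _ = log10_autoscale(X)
        aucs = []
        for pseed in range(3):
            yp = np.random.default_rng(pseed).permutation(y)
            res = repeated_double_cv(Z, yp, n_repetitions=5, seed=pseed)
            aucs.append(res.auc_mean)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_tiny_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="stratified"):
            repeated_double_cv(X, y, outer_k=5, n_repetitions=1, seed=0)


class TestVipSelect:
    def test_markers_dominate_selection(self):
        X, y, markers, _ = feature_scenario(seed=9)
        Z, _ = log10_autoscale(X)
        res = vip_select(Z, y, seed=9)
        hits = len(set(res.selected) & set(markers))
        assert hits >= 0.8 * len(markers)
        assert np.all(res.trace["vip"][res.selected] > 1.0)


class TestPcaBatchCheck:
    def test_injected_batch_offset_flagged(self, rng):
        X = rng.normal(size=(40, 15))
        batches = np.repeat([0, 1], 20)
        X[batches == 1] += 2.0
        report = pca_batch_check(X, batches)
        assert not report["passed"]
        assert 0 in report["flagged_pcs"]

    def test_no_batch_effect_usually_passes(self):
        passed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 10))
            batches = np.repeat([0, 1], 20)
            passed += pca_batch_check(X, batches, alpha=0.01)["passed"]
        assert passed >= 16

    def test_single_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_batch_check(rng.normal(size=(10, 4)), np.zeros(10))


class TestAblation:
    def test_empty_drop_set_is_reference(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.array([0, 1] * 20)
        X[:, 0] = 2.0 * (y - 0.5) + 0.2 * rng.normal(size=40)
        rows = ablation_rerun(X, y, drop_sets=[[]], n_repetitions=3, seed=5)
        assert rows[1]["d_sensitivity"] == 0.0
        assert rows[1]["d_specificity"] == 0.0

    def test_dropping_the_only_informative_variable_hurts(self, rng):
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 6))
        X[:, 2] = 2.5 * (y - 0.5) + 0.2 * rng.normal(size=n)
        rows = ablation_rerun(X, y, drop_sets=[[5], [2]], n_repetitions=5, seed=4)
        ref, noise_drop, info_drop = rows
        band = 2 * max(ref["sd_sensitivity"], 0.02)
        assert abs(noise_drop["d_sensitivity"]) <= band + 1e-9
        assert info_drop["d_sensitivity"] < -2 * max(ref["sd_sensitivity"], 0.02)
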