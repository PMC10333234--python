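import numpy as np
import pytest
from scipy import stats
from sklearn.kernel_ridge import KernelRidge as SkKernelRidge

import cofluct as cf
from cofluct.prediction import (REGRESSION_ALPHA_GRID, SVC_C_GRID,
                                _fit_confound_model, cbpm_fit,
                                ridge_classifier)


class TestScore:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert cf.score(y, y, "pearson_r") == pytest.approx(1.0)
        assert cf.score(y, y, "r2") == pytest.approx(1.0)
        assert cf.score(y, y, "mae") == 0.0

    def test_constant_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.full(4, y.mean())
        assert cf.score(y, yhat, "r2") == pytest.approx(0.0)

    def test_balanced_accuracy_arithmetic(self):
        # TP=50, FN=0, TN=25, FP=25: sensitivity 1.0, specificity 0.5
        y = np.array([1] * 50 + [0] * 50)
        yhat = np.array([1] * 50 + [1] * 25 + [0] * 25)
        assert cf.score(y, yhat, "balanced_accuracy") == pytest.approx(0.75)
        assert cf.score(y, yhat, "accuracy") == pytest.approx(0.75)

    def test_balanced_equals_plain_when_classes_balanced(self, rng):
        y = np.repeat([0, 1], 20)
        yhat = rng.integers(0, 2, size=40)
        # balanced classes but per-class error rates differ in general;
        # equality holds when they coincide — force symmetric errors
        yhat = y.copy()
        flip = np.concatenate([rng.choice(20, 5, replace=False),
                               20 + rng.choice(20, 5, replace=False)])
        yhat[flip] = 1 - yhat[flip]
        assert cf.score(y, yhat, "balanced_accuracy") == pytest.approx(
            cf.score(y, yhat, "accuracy"))

    def test_pearson_matches_covariance_formulation(self, rng):
        y, yhat = rng.standard_normal(50), rng.standard_normal(50)
        assert cf.score(y, yhat, "pearson_r") == pytest.approx(
            stats.pearsonr(y, yhat).statistic, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cf.score(np.ones(5), np.arange(5.0), "pearson_r")


class TestResidualizeTargets:
    def test_exact_linear_target_residuals_vanish(self, rng):
        conf = rng.standard_normal((30, 3))
        y = conf @ [1.0, -2.0, 0.5] + 4.0
        tr_res, te_res, model = cf.residualize_targets(
            y[:20], conf[:20], y[20:], conf[20:])
        assert np.allclose(tr_res, 0, atol=1e-10)
        assert np.allclose(te_res, 0, atol=1e-10)

    def test_orthogonal_confound_leaves_centred_target(self, rng):
        n = 40
        conf = np.sin(np.arange(n))[:, None]
        conf = conf - conf.mean()
        y = rng.standard_normal(n)
        y = y - y.mean()
        y = y - conf.ravel() * (y @ conf.ravel()) / (conf.ravel() @ conf.ravel())
        tr_res, _, _ = cf.residualize_targets(y, conf, y, conf)
        assert np.allclose(tr_res, y - y.mean(), atol=1e-10)

    def test_against_normal_equations_oracle(self, rng):
        conf = rng.standard_normal((25, 2))
        y = rng.standard_normal(25)
        _, _, model = cf.residualize_targets(y, conf, y, conf)
        x = np.column_stack([np.ones(25), conf])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        assert np.allclose(model.coef, beta, atol=1e-10)

    def test_collinear_confound_dropped(self, rng):
        c = rng.standard_normal(20)
        conf = np.column_stack([c, 2 * c])
        with pytest.warns(RuntimeWarning, match="collinear"):
            model = _fit_confound_model(rng.standard_normal(20), conf)
        assert model.kept_columns == [0]


class TestPearsonKernel:
    def test_unit_self_similarity(self, rng):
        a = rng.standard_normal((6, 20))
        k = cf.pearson_kernel(a, a)
        assert np.allclose(np.diag(k), 1.0)

    def test_proportional_rows(self):
        a = np.array([[1.0, 2.0, 3.0]])
        b = np.array([[2.0, 4.0, 6.0]])
        assert cf.pearson_kernel(a, b)[0, 0] == pytest.approx(1.0)

    def test_against_pairwise_oracle(self, rng):
        a, b = rng.standard_normal((4, 15)), rng.standard_normal((5, 15))
        k = cf.pearson_kernel(a, b)
        for i in range(4):
            for j in range(5):
                assert k[i, j] == pytest.approx(
                    stats.pearsonr(a[i], b[j]).statistic, abs=1e-12)

    def test_constant_row_rejected(self, rng):
        a = rng.standard_normal((3, 10))
        a[1] = 5.0
        with pytest.raises(ValueError, match="constant"):
            cf.pearson_kernel(a, a)


class TestKernelRidge:
    def test_heavy_shrinkage_predicts_train_mean(self, rng):
        a = rng.standard_normal((10, 20))
        k = cf.pearson_kernel(a, a)
        y = rng.standard_normal(10)
        fit = cf.kernel_ridge(k, y, alpha=1e12)
        assert np.allclose(fit.predict(k), y.mean(), atol=1e-6)

    def test_zero_alpha_interpolates(self, rng):
        a = rng.standard_normal((8, 30))
        k = cf.pearson_kernel(a, a)
        y = rng.standard_normal(8)
        fit = cf.kernel_ridge(k, y, alpha=0.0)
        assert np.allclose(fit.predict(k), y, atol=1e-8)

    def test_against_direct_solve_oracle(self, rng):
        k = rng.standard_normal((6, 6))
        k = k @ k.T + np.eye(6)
        y = rng.standard_normal(6)
        alpha = 0.7
        fit = cf.kernel_ridge(k, y, alpha)
        c = np.linalg.solve(k + alpha * np.eye(6), y - y.mean())
        assert np.allclose(fit.dual_coef, c, atol=1e-8)

    def test_against_sklearn_cross_check(self, rng):
        """Independent route: sklearn's KernelRidge on the same precomputed
        Gram matrix with pre-centred targets gives the same predictions."""
        a = rng.standard_normal((12, 25))
        k = cf.pearson_kernel(a, a)
        y = rng.standard_normal(12)
        alpha = 2.5
        ours = cf.kernel_ridge(k, y, alpha)
        sk = SkKernelRidge(alpha=alpha, kernel="precomputed")
        sk.fit(k, y - y.mean())
        assert np.allclose(ours.predict(k), sk.predict(k) + y.mean(),
                           atol=1e-8)

    def test_negative_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            cf.kernel_ridge(np.eye(3), np.zeros(3), alpha=-1.0)


class TestCBPM:
    def test_informative_edge_recovered(self, rng):
        n, d = 60, 50
        x = rng.standard_normal((n, d))
        y = 3.0 * x[:, 7]
        # noise-free target: the true edge has p ~ 0, chance edges do not
        fit = cbpm_fit(x[:40], y[:40], p_threshold=1e-8)
        assert set(fit.pos_edges) == {7} and len(fit.neg_edges) == 0
        pred = fit.predict(x[40:])
        assert cf.score(y[40:], pred, "pearson_r") > 0.95

    def test_threshold_one_selects_all_edges(self, rng):
        x = rng.standard_normal((20, 10))
        y = rng.standard_normal(20)
        fit = cbpm_fit(x, y, p_threshold=1.0)
        assert len(fit.pos_edges) + len(fit.neg_edges) == 10

    def test_null_selection_rate_matches_alpha(self):
        """Type-I rate of the edge-wise screen: ~1% of independent edges
        survive p < 0.01."""
        rng = np.random.default_rng(42)
        rates = []
        for _ in range(30):
            x = rng.standard_normal((50, 200))
            y = rng.standard_normal(50)
            fit = cbpm_fit(x, y, p_threshold=0.01)
            rates.append((len(fit.pos_edges) + len(fit.neg_edges)) / 200)
        assert np.mean(rates) == pytest.approx(0.01, abs=0.005)

    def test_no_edges_falls_back_to_intercept(self, rng):
        x = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        with pytest.warns(RuntimeWarning, match="no edges"):
            fit = cbpm_fit(x, y, p_threshold=1e-12)
        assert fit.fallback
        assert np.allclose(fit.predict(x), y.mean())


class TestGrids:
    def test_regression_grid_verbatim(self):
        expected = (0, 0.00001, 0.0001, 0.001, 0.004, 0.007, 0.01, 0.04,
                    0.07, 0.1, 0.4, 0.7, 1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 10,
                    15, 20, 30, 40, 50, 60, 70, 80, 100, 150, 200, 300, 500,
                    700, 1000, 10_000, 100_000, 1_000_000)
        assert REGRESSION_ALPHA_GRID == expected

    def test_svc_grid_is_50_point_geomspace(self):
        assert len(SVC_C_GRID) == 50
        assert SVC_C_GRID[0] == pytest.approx(0.01)
        assert SVC_C_GRID[-1] == pytest.approx(100.0)
        ratios = np.diff(np.log(np.array(SVC_C_GRID)))
        assert np.allclose(ratios, ratios[0])


class TestNestedCV:
    @staticmethod
    def _toy_problem(rng, n=100, d=25, n_families=20):
        x = rng.standard_normal((n, d))
        beta = rng.standard_normal(d)
        y = x @ beta
        conf = rng.standard_normal((n, 2))
        groups = np.repeat(np.arange(n_families), n // n_families)
        return x, y, conf, groups

    def test_grouped_folds_never_split_families(self, rng):
        x, y, conf, groups = self._toy_problem(rng)
        cv = cf.CVSpec(scheme="grouped_kfold", k_outer=5, k_inner=3,
                       groups=groups, seed=0)
        for train, test in cv.outer_splits(len(y)):
            assert not set(groups[train]) & set(groups[test])

    def test_linear_target_recovered(self, rng):
        x, y, conf, groups = self._toy_problem(rng)
        cv = cf.CVSpec(scheme="grouped_kfold", k_outer=5, k_inner=3,
                       groups=groups, seed=0)
        res = cf.run_prediction_cv(x, y, None, cv, model="kernel_ridge",
                                   grid=[0.001, 0.1, 10.0],
                                   metrics=["pearson_r", "r2"])
        assert res.mean("pearson_r") > 0.85
        assert len(res.fold_scores["pearson_r"]) == 5
        assert len(res.chosen_params) == 5

    def test_repeated_kfold_yields_k_times_repeats_folds(self, rng):
        x, y, conf, _ = self._toy_problem(rng)
        cv = cf.CVSpec(scheme="repeated_kfold", k_outer=5, n_repeats=5,
                       k_inner=3, seed=1)
        res = cf.run_prediction_cv(x, y, None, cv, grid=[0.1],
                                   metrics=["pearson_r"])
        assert len(res.fold_scores["pearson_r"]) == 25

    def test_confound_driven_target_scores_drop_after_removal(self, rng):
        """A target that is pure confound should lose its apparent
        predictability once confounds are removed CV-consistently."""
        n = 80
        x = rng.standard_normal((n, 30))
        conf = rng.standard_normal((n, 1))
        # make features leak the confound so the naive model can exploit it
        x[:, 0] = conf.ravel() + 0.1 * rng.standard_normal(n)
        y = conf.ravel() + 0.3 * rng.standard_normal(n)
        cv = cf.CVSpec(scheme="repeated_kfold", k_outer=5, k_inner=3, seed=2)
        naive = cf.run_prediction_cv(x, y, None, cv, grid=[0.1, 10.0],
                                     metrics=["pearson_r"])
        adjusted = cf.run_prediction_cv(x, y, conf, cv, grid=[0.1, 10.0],
                                        metrics=["pearson_r"])
        assert naive.mean("pearson_r") > 0.8
        assert adjusted.mean("pearson_r") < 0.4

    def test_classification_path(self, rng):
        n = 80
        x = rng.standard_normal((n, 20))
        w = rng.standard_normal(20)
        y = (x @ w > 0).astype(int)
        conf = rng.standard_normal((n, 2))
        cv = cf.CVSpec(scheme="repeated_kfold", k_outer=5, k_inner=3, seed=3)
        res = cf.run_prediction_cv(x, y, conf, cv, model="ridge_classifier",
                                   grid=[0.1, 1.0, 10.0],
                                   metrics=["accuracy", "balanced_accuracy"])
        assert res.mean("accuracy") > 0.7
        assert all(0 <= v <= 1 for v in res.fold_scores["accuracy"])

    def test_ridge_classifier_separable(self, rng):
        x = np.vstack([rng.standard_normal((20, 5)) + 4,
                       rng.standard_normal((20, 5)) - 4])
        y = np.repeat([1, 0], 20)
        fit = ridge_classifier(x, y, alpha=1.0)
        assert np.mean(fit.predict(x) == y) == 1.0

    def test_misaligned_inputs_rejected(self, rng):
        x = rng.standard_normal((10, 5))
        with pytest.raises(ValueError, match="align"):
            cf.run_prediction_cv(x, np.zeros(9), None,
                                 cf.CVSpec(scheme="repeated_kfold",
                                           k_outer=2, seed=0))


class TestLeakageAudit:
    def test_test_fold_targets_never_influence_fits(self, rng):
        """Permuting test-fold targets leaves every fitted coefficient and
        confound model of that fold bit-identical."""
        n = 50
        x = rng.standard_normal((n, 30))
        y = x @ rng.standard_normal(30) + rng.standard_normal(n)
        conf = rng.standard_normal((n, 2))
        groups = np.repeat(np.arange(10), 5)
        cv = cf.CVSpec(scheme="grouped_kfold", k_outer=5, k_inner=3,
                       groups=groups, seed=0)
        for train_idx, test_idx in cv.outer_splits(n):
            fit = cf.fit_fold(x, y, conf, train_idx, cv, "kernel_ridge",
                              [0.1, 10.0], classification=False)
            y_perm = y.copy()
            y_perm[test_idx] = rng.permutation(y[test_idx])
            fit_perm = cf.fit_fold(x, y_perm, conf, train_idx, cv,
                                   "kernel_ridge", [0.1, 10.0],
                                   classification=False)
            assert fit.hyperparameter == fit_perm.hyperparameter
            assert np.array_equal(fit.estimator.dual_coef,
                                  fit_perm.estimator.dual_coef)
            assert np.array_equal(fit.confound_model.coef,
                                  fit_perm.confound_model.coef)
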