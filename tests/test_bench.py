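import numpy as np
import pytest

from netcog import bench
from netcog.deconfound import ConfoundRegressor, deconfound


class TestConfigs:
    def test_product_count(self):
        space = {
            "task": ["classification"],
            "algorithm": ["svm_linear", "knn"],
            "fs_method": ["none", "anova_f_top10"],
            "deconfound": ["nr", "cr"],
        }
        assert len(bench.enumerate_configs(space)) == 8

    def test_invalid_combinations_excluded(self):
        space = {
            "task": ["classification"],
            "algorithm": ["svm_linear"],
            "fs_method": ["none", "corr_top10"],  # corr filter is regression-only
        }
        cfgs = bench.enumerate_configs(space)
        assert len(cfgs) == 1 and cfgs[0].fs_method == "none"

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bench.enumerate_configs(
                {"task": ["classification"], "algorithm": ["svm_linear"],
                 "fs_method": ["corr_top10"]}
            )

    def test_default_spaces_counts_logged(self):
        ncls = len(bench.enumerate_configs(bench.default_classification_space()))
        nreg = len(bench.enumerate_configs(bench.default_regression_space()))
        assert ncls > 50 and nreg > 20

    def test_classification_deconfound_restricted(self):
        with pytest.raises(ValueError):
            bench.PipelineConfig(task="classification", deconfound="nr_cr")
        with pytest.raises(ValueError):
            bench.PipelineConfig(task="regression", algorithm="ridge",
                                 deconfound="cr")


class TestGrids:
    def test_knn_grid_has_13_points(self):
        assert len(bench.hyperparameter_grid("knn")) == 13

    def test_svm_c_grid(self):
        grid = [g["C"] for g in bench.hyperparameter_grid("svm_linear")]
        assert len(grid) == 10
        assert grid[0] == pytest.approx(1e-4)
        assert grid[-1] == pytest.approx(10.0)

    def test_tree_grid(self):
        grid = bench.hyperparameter_grid("decision_tree")
        assert len(grid) == 14  # 7 depths x 2 criteria
        assert {g["criterion"] for g in grid} == {"gini", "entropy"}

    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        y = rng.integers(0, 2, 40)
        scheme = bench.CVScheme(inner_folds=4, inner_repeats=1)
        # naive_bayes has an empty grid -> no tuning
        assert bench.grid_search("naive_bayes", X, y, scheme, "classification") == {}

    def test_grid_search_finds_planted_optimum(self):
        # strongly regularized optimum: tiny informative signal + noise dims
        rng = np.random.default_rng(1)
        n = 60
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 40)) * 2.0
        X[:, 0] += (y - 0.5) * 6.0
        scheme = bench.CVScheme(inner_folds=5, inner_repeats=2)
        best = bench.grid_search("knn", X[:, :5], y, scheme, "classification", seed=2)
        assert "n_neighbors" in best


class TestMetrics:
    def test_confusion_arithmetic(self):
        truth = np.array([1] * 50 + [0] * 50)
        pred = np.array([1] * 40 + [0] * 10 + [1] * 20 + [0] * 30)
        m = bench.classification_metrics(truth, pred)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.6)
        assert m["bac"] == pytest.approx(0.7)

    def test_perfect_and_constant_predictions(self):
        truth = np.array([0, 1, 0, 1])
        assert bench.classification_metrics(truth, truth)["bac"] == 1.0
        assert bench.classification_metrics(truth, np.ones(4))["bac"] == 0.5

    def test_regression_examples(self):
        m = bench.regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m["mae"] == pytest.approx(2 / 3)
        assert m["r2"] == pytest.approx(0.0)
        m = bench.regression_metrics([1.0, 2.0], [1.0, 2.0])
        assert m["mae"] == 0.0 and m["r2"] == 1.0

    def test_dummy_baselines(self):
        clf = bench.dummy_baseline("classification").fit(np.zeros((4, 1)),
                                                         [0, 0, 1, 0])
        assert (clf.predict(np.zeros((3, 1))) == 0).all()
        reg = bench.dummy_baseline("regression").fit(np.zeros((3, 1)), [1.0, 2.0, 3.0])
        assert reg.predict(np.zeros((1, 1)))[0] == pytest.approx(2.0)


class TestScaling:
    def test_train_statistics_applied_to_test(self):
        X_tr = np.array([[2.0], [4.0], [6.0]])
        X_te = np.array([[8.0]])
        Xt, Xs, _ = bench._scale_train_test(X_tr, X_te)
        assert Xt.mean() == pytest.approx(0.0)
        assert Xt.std() == pytest.approx(1.0)
        assert Xs[0, 0] == pytest.approx((8 - 4) / np.std([2, 4, 6]), abs=1e-6)

    def test_constant_feature_zeroed(self):
        X_tr = np.full((3, 1), 5.0)
        X_te = np.array([[7.0]])
        Xt, Xs, _ = bench._scale_train_test(X_tr, X_te)
        assert (Xt == 0).all() and (Xs == 0).all()

    def test_refit_on_test_differs(self):
        # leakage guard: scaling must come from train, not test
        X_tr = np.array([[0.0], [2.0]])
        X_te = np.array([[10.0], [12.0]])
        _, Xs, _ = bench._scale_train_test(X_tr, X_te)
        _, Xs_leak, _ = bench._scale_train_test(X_te, X_te)
        assert not np.allclose(Xs, Xs_leak)


class TestDeconfound:
    def test_identity_mode(self):
        X = np.arange(12.0).reshape(6, 2)
        y = np.arange(6.0)
        C = np.ones((6, 1))
        Xt, yt, Xs, ys = deconfound(X, y, X, y, C, C, mode="nr")
        np.testing.assert_array_equal(Xt, X)
        np.testing.assert_array_equal(yt, y)

    def test_perfect_confound_removed(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(55, 85, 100)
        y = 2.0 * age
        X = rng.standard_normal((100, 3))
        Xt, yt, Xs, ys = deconfound(
            X[:70], y[:70], X[70:], y[70:], age[:70, None], age[70:, None],
            mode="nr_cr",
        )
        assert np.abs(yt).max() < 1e-8
        assert np.abs(ys).max() < 1e-8

    def test_rank_deficient_rejected(self):
        X = np.zeros((5, 2))
        C = np.ones((5, 2))  # duplicate of intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            ConfoundRegressor().fit(X, confounds=C)

    def test_transformer_fit_on_train_only(self):
        rng = np.random.default_rng(4)
        C_tr = rng.standard_normal((50, 2))
        X_tr = C_tr @ np.array([[1.0, 0.0], [0.0, 2.0]]) + 0.01 * rng.standard_normal((50, 2))
        reg = ConfoundRegressor().fit(X_tr, confounds=C_tr)
        resid = reg.transform(X_tr, confounds=C_tr)
        assert np.abs(resid).max() < 0.1


class TestEvaluate:
    def _toy_classification(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 5))
        X[:, 0] += (y - 0.5) * 4.0
        return X, y

    def test_separable_problem_perfect_bac(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 30)
        X = rng.standard_normal((60, 2)) * 0.1
        X[:, 0] += y * 5.0
        cfg = bench.PipelineConfig(task="classification", algorithm="svm_linear")
        res = bench.evaluate(cfg, X, y, scheme=bench.CVScheme(outer_repeats=1))
        assert res.aggregate["mean_bac"] == 1.0
        assert res.robust

    def test_fold_count(self):
        X, y = self._toy_classification()
        cfg = bench.PipelineConfig(task="classification", algorithm="lda")
        res = bench.evaluate(cfg, X, y, scheme=bench.CVScheme())
        assert len(res.folds) == 50

    def test_ridge_recovers_slope(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(200)
        y = 3.0 * x + 0.3 * rng.standard_normal(200)
        cfg = bench.PipelineConfig(task="regression", algorithm="ridge")
        res = bench.evaluate(
            cfg, x[:, None], y, scheme=bench.CVScheme(outer_repeats=1)
        )
        assert res.aggregate["mean_r2"] > 0.85

    def test_leakage_guard_fitted_params_ignore_test_fold(self):
        """Corrupting a test fold after the fact must not change what was
        fitted on the corresponding training data."""
        X, y = self._toy_classification(n=60, seed=7)
        cfg = bench.PipelineConfig(
            task="classification", algorithm="lda", fs_method="anova_f_top10"
        )
        scheme = bench.CVScheme(outer_folds=5, outer_repeats=1, seed=3)
        res_a = bench.evaluate(cfg, X, y, scheme=scheme)
        # corrupt the test rows of fold 0 only
        folds = list(
            bench.RepeatedStratifiedKFold(
                n_splits=5, n_repeats=1, random_state=3
            ).split(X, y)
        )
        te0 = folds[0][1]
        X_bad = X.copy()
        X_bad[te0] += 100.0
        res_b = bench.evaluate(cfg, X_bad, y, scheme=scheme)
        np.testing.assert_array_equal(
            res_a.selected_features[0], res_b.selected_features[0]
        )

    def test_leaky_mode_inflates_null_bac(self):
        rng = np.random.default_rng(8)
        n, d = 60, 200
        X = rng.standard_normal((n, d))
        y = rng.integers(0, 2, n)
        cfg = bench.PipelineConfig(
            task="classification", algorithm="svm_linear", fs_method="anova_f_top10"
        )
        scheme = bench.CVScheme(outer_repeats=1, seed=4)
        leaky = bench.evaluate(cfg, X, y, scheme=scheme, leaky_selection=True)
        safe = bench.evaluate(cfg, X, y, scheme=scheme)
        assert leaky.aggregate["mean_bac"] > safe.aggregate["mean_bac"]

    def test_single_class_rejected(self):
        X = np.zeros((20, 2))
        y = np.zeros(20)
        cfg = bench.PipelineConfig(task="classification", algorithm="lda")
        with pytest.raises(ValueError, match="2 classes"):
            bench.evaluate(cfg, X, y)

    def test_robust_flag_boundary(self):
        X, y = self._toy_classification(n=100, seed=9)
        cfg = bench.PipelineConfig(task="classification", algorithm="lda")
        res = bench.evaluate(cfg, X, y, scheme=bench.CVScheme(outer_repeats=1))
        assert res.robust == (res.dummy_win_fraction > 0.8)


class TestSampleSizeMonotonicity:
    def test_mean_bac_nondecreasing_in_n_under_planted_signal(self):
        """With a planted effect, benchmark BAC does not degrade as the
        cohort grows (tolerance 0.02)."""
        from netcog import cognition, synth
        from netcog.experiments import cohort_features, composite_target

        bacs = []
        for n in (100, 200, 400):
            parc = synth.make_parcellation(12, 3)
            spec = synth.CohortSpec(
                n_subjects=n, segregation_sd=0.08, effect_beta=0.7, seed=29
            )
            cohort = synth.generate_cohort(parc, spec)
            X = cohort_features(cohort, set_id="all", n_surrogates=100, seed=29)
            target = composite_target(cohort)
            y = (cognition.make_groups(target).labels == "high").astype(int)
            cfg = bench.PipelineConfig(
                task="classification", algorithm="svm_linear",
                fs_method="anova_f_top10", seed=29,
            )
            res = bench.evaluate(
                cfg, X.to_numpy(), y.to_numpy(),
                scheme=bench.CVScheme(outer_repeats=2, seed=29),
            )
            bacs.append(res.aggregate["mean_bac"])
        assert bacs[1] >= bacs[0] - 0.02
        assert bacs[2] >= bacs[1] - 0.02
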