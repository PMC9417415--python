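"""Feature building, nested CV, metrics, Scheffe, importances, KDE split."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ecogrowth as eg
from conftest import FAST_GRID


class TestBuildFeatures:
    def test_zero_concentrations_map_one_decade_below_minimum(self, small_design,
                                                              truth_table):
        ft = eg.build_features(small_design, truth_table, "rate")
        col = small_design.component_names[3]
        conc = small_design.combinations[col]
        positive = conc[conc > 0]
        expected_fill = np.log10(positive.min()) - 1
        zero_rows = conc.index[conc == 0]
        if len(zero_rows):
            np.testing.assert_allclose(ft.X.loc[zero_rows, col], expected_fill)
        pos_rows = positive.index
        np.testing.assert_allclose(ft.X.loc[pos_rows, col],
                                   np.log10(positive), atol=1e-12)

    def test_forced_example_column(self):
        conc = pd.DataFrame({"a": [0.0, 0.01, 0.1, 1.0],
                             "b": [1.0, 1.0, 1.0, 1.0]},
                            index=list("wxyz"))
        gi = pd.DataFrame({"target_component": ["a"] * 4, "level": range(4),
                           "background_id": [0] * 4}, index=list("wxyz"))
        design = eg.MediumDesign(["a", "b"], conc, gi)
        params = pd.DataFrame({"rate": [1.0, 2, 3, 4]}, index=list("wxyz"))
        ft = eg.build_features(design, params, "rate", pseudo_decades=1)
        np.testing.assert_allclose(ft.X["a"], [-3, -2, -1, 0], atol=1e-12)

    def test_flagged_rows_dropped(self, small_design, truth_table):
        params = truth_table.copy()
        params["flag_rate"] = False
        params.iloc[:10, params.columns.get_loc("flag_rate")] = True
        ft = eg.build_features(small_design, params, "rate")
        assert len(ft.y) == len(truth_table) - 10


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = eg.compute_metrics([1.0, 2, 3], [1.0, 2, 3])
        assert (m["r2"], m["mse"], m["rmse"], m["mae"],
                m["explained_variance"]) == (1, 0, 0, 0, 1)

    def test_hand_arithmetic(self):
        m = eg.compute_metrics([0, 1], [0, 0])
        assert m["mse"] == pytest.approx(0.5)
        assert m["rmse"] == pytest.approx(0.7071, abs=1e-4)
        assert m["mae"] == pytest.approx(0.5)

    def test_matches_textbook_formulas_on_random_vectors(self):
        rng = np.random.default_rng(6)
        y, yh = rng.normal(size=50), rng.normal(size=50)
        m = eg.compute_metrics(y, yh)
        resid = y - yh
        assert m["mse"] == pytest.approx(np.mean(resid ** 2))
        assert m["rmse"] == pytest.approx(np.sqrt(np.mean(resid ** 2)))
        assert m["mae"] == pytest.approx(np.mean(np.abs(resid)))
        assert m["r2"] == pytest.approx(1 - np.sum(resid ** 2)
                                        / np.sum((y - y.mean()) ** 2))
        assert m["explained_variance"] == pytest.approx(1 - resid.var() / y.var())

    def test_constant_truth_leaves_r2_undefined(self):
        m = eg.compute_metrics([1.0, 1.0, 1.0], [1.0, 0.9, 1.1])
        assert np.isnan(m["r2"]) and np.isnan(m["explained_variance"])


class TestNestedCV:
    def _features(self, n=60, seed=0, noise=False):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = rng.normal(size=n) if noise else X["b"] * 2.0 + 1.0
        return eg.FeatureTable(X=X, y=pd.Series(y), parameter="rate")

    def test_linear_model_perfect_on_linear_response(self):
        ev = eg.nested_cv_evaluate(self._features(), model="linear", seed=0)
        assert (ev.fold_metrics["r2"] > 0.999999).all()
        assert (ev.fold_metrics["rmse"] < 1e-6).all()

    def test_pure_noise_has_no_predictive_power(self):
        r2 = []
        for seed in range(5):
            ev = eg.nested_cv_evaluate(self._features(seed=seed, noise=True),
                                       model="linear", seed=seed)
            r2.append(ev.fold_metrics["r2"].mean())
        assert np.mean(r2) <= 0.1

    def test_rmse_is_sqrt_mse_per_fold(self, small_design, truth_table):
        ft = eg.build_features(small_design, truth_table, "capacity")
        ev = eg.nested_cv_evaluate(ft, model="gbdt", grid=FAST_GRID, seed=0,
                                   n_estimators=50)
        np.testing.assert_allclose(ev.fold_metrics["rmse"],
                                   np.sqrt(ev.fold_metrics["mse"]), rtol=1e-12)
        assert len(ev.fold_metrics) == 5

    def test_no_leakage_from_test_fold_into_selection(self):
        """Perturbing responses only on one outer test fold must leave that
        fold's inner-CV hyperparameter choice unchanged."""
        from sklearn.model_selection import KFold
        ft = self._features(n=80, seed=3)
        ft.y = ft.y + np.random.default_rng(0).normal(0, 0.5, len(ft.y))
        base = eg.nested_cv_evaluate(ft, model="gbdt", grid=FAST_GRID, seed=1,
                                     n_estimators=30)
        outer = KFold(n_splits=5, shuffle=True, random_state=1)
        _, test0 = next(iter(outer.split(ft.X.to_numpy())))
        y2 = ft.y.copy()
        y2.iloc[test0] = 999.0
        poisoned = eg.FeatureTable(X=ft.X, y=y2, parameter="rate")
        redo = eg.nested_cv_evaluate(poisoned, model="gbdt", grid=FAST_GRID,
                                     seed=1, n_estimators=30)
        assert redo.best_params[0] == base.best_params[0]

    @pytest.mark.parametrize("name", ["knn", "rf", "svm", "nn", "ensemble"])
    def test_model_zoo_builds(self, name):
        est, grid = eg.ml.make_model(name, seed=0, n_estimators=10)
        assert est is not None
        if name == "svm":
            assert len(grid["model__C"]) == 8


class TestScheffe:
    def test_identical_models_not_significant(self):
        tbl = pd.DataFrame({"a": [0.5, 0.52, 0.48, 0.5, 0.51],
                            "b": [0.5, 0.52, 0.48, 0.5, 0.51]})
        out = eg.scheffe_compare(tbl)
        assert not out["significant"].any()

    def test_large_separation_matches_textbook_computation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.05, 5)
        b = rng.normal(1.0, 0.05, 5)   # ~20 pooled sd apart
        tbl = pd.DataFrame({"a": a, "b": b})
        out = eg.scheffe_compare(tbl)
        msw = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 8
        expected = (a.mean() - b.mean()) ** 2 / (msw * (1 / 5 + 1 / 5))
        assert out.iloc[0]["statistic"] == pytest.approx(expected)
        assert bool(out.iloc[0]["significant"])

    def test_never_significant_below_global_f(self):
        """Pairwise Scheffe contrasts cannot fire when the omnibus F is
        below its critical value."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            tbl = pd.DataFrame({m: rng.normal(0, 1, 5) for m in "abc"})
            out = eg.scheffe_compare(tbl)
            if out.attrs["f_global"] < out.attrs["f_critical"]:
                assert not out["significant"].any()

    def test_zero_variance_reported_degenerate(self):
        tbl = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        out = eg.scheffe_compare(tbl)
        assert out["degenerate"].all()


class TestImportance:
    def test_single_determinant_takes_almost_all_importance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        y = X["c"].copy()
        ft = eg.FeatureTable(X=X, y=y, parameter="rate")
        prof = eg.gbdt_importance(ft, grid=FAST_GRID, seed=0, n_estimators=50)
        assert prof.mean["c"] > 0.95

    def test_importances_normalised(self, small_design, truth_table):
        ft = eg.build_features(small_design, truth_table, "tau")
        prof = eg.gbdt_importance(ft, grid={"max_depth": [2]}, seed=0,
                                  n_estimators=30)
        assert prof.mean.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(prof.per_fold.sum(axis=1), 1.0, atol=1e-9)


class TestSplitBimodal:
    def test_well_separated_mixture_threshold_in_gap(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 0.5, 500), rng.normal(5, 0.5, 500)])
        res = eg.split_bimodal(vals)
        assert res.separable
        assert 1.5 < res.threshold < 3.5
        assert len(res.low_ids) + len(res.high_ids) == 1000

    def test_unimodal_not_separable(self):
        rng = np.random.default_rng(1)
        assert not eg.split_bimodal(rng.normal(0, 1, 1000)).separable

    def test_identical_values_not_separable(self):
        assert not eg.split_bimodal(np.full(100, 3.3)).separable

    def test_threshold_equivariant_under_affine_rescaling(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(0, 0.4, 400), rng.normal(4, 0.4, 400)])
        base = eg.split_bimodal(vals)
        shifted = eg.split_bimodal(2.5 * vals + 7.0)
        assert shifted.threshold == pytest.approx(2.5 * base.threshold + 7.0,
                                                  rel=1e-6)

    def test_split_subsets_support_reprediction(self):
        """Importance profiles recomputed on each split subset stay valid."""
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        y = X["a"] * 0.2 + np.where(rng.random(300) < 0.5, 0.0, 5.0)
        ft = eg.FeatureTable(X=X, y=pd.Series(y), parameter="capacity")
        res = eg.split_bimodal(ft.y)
        assert res.separable
        for ids in (res.low_ids, res.high_ids):
            sub = eg.FeatureTable(X=ft.X.loc[ids], y=ft.y.loc[ids],
                                  parameter="capacity")
            prof = eg.gbdt_importance(sub, grid={"max_depth": [2]}, seed=0,
                                      n_estimators=20)
            assert prof.mean.sum() == pytest.approx(1.0, abs=1e-9)
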