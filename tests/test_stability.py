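from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from petrad.stability import (
    ModelConfig,
    aggregate,
    correlation_filter,
    evaluate_test,
    fit_lasso,
    potentiate,
    results_to_frame,
    run_stability,
    split,
    standardize,
    transform_target,
)
from petrad.synthetic import make_regression_cohort


class TestCorrelationFilter:
    def test_feature_equal_to_target_retained(self, rng):
        y = rng.uniform(2, 5, 20)
        X = pd.DataFrame({"self": y, "noise": rng.normal(size=20)})
        kept, table = correlation_filter(X, y)
        assert "self" in kept
        assert table.loc["self", "r"] == pytest.approx(1.0)

    def test_constant_feature_dropped_before_testing(self, rng):
        y = rng.uniform(2, 5, 20)
        X = pd.DataFrame({"const": np.ones(20), "ok": y + rng.normal(0, 0.1, 20)})
        kept, table = correlation_filter(X, y)
        assert "const" not in table.index
        assert "ok" in kept

    def test_missing_feature_dropped(self, rng):
        y = rng.uniform(2, 5, 10)
        col = y.copy()
        col[3] = np.nan
        kept, table = correlation_filter(pd.DataFrame({"gappy": col}), y)
        assert "gappy" not in table.index

    def test_p_value_matches_t_oracle_at_r044_n40(self):
        # construct two vectors with r very close to 0.44, n = 40
        rng = np.random.default_rng(8)
        n = 40
        for _ in range(200):
            x = rng.standard_normal(n)
            y = 0.44 * (x - x.mean()) / x.std() + rng.standard_normal(n) * np.sqrt(1 - 0.44**2)
            r = np.corrcoef(x, y)[0, 1]
            if abs(r - 0.44) < 0.005:
                break
        _, table = correlation_filter(pd.DataFrame({"x": x}), y)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert table.loc["x", "p"] == pytest.approx(2 * sps.t.sf(abs(t), n - 2), rel=1e-6)
        # at r ~= 0.44 and n = 40 the two-sided p is ~0.0044 -> retained
        assert table.loc["x", "p"] < 0.05

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            correlation_filter(pd.DataFrame({"a": [1.0, 2.0]}), np.array([1.0, 2.0]))


class TestStandardize:
    def test_hand_oracle_123(self):
        tr, _, _ = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(tr["a"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self, rng):
        col = rng.standard_normal(50)
        col = (col - col.mean()) / col.std(ddof=1)
        tr, _, _ = standardize(pd.DataFrame({"a": col}))
        np.testing.assert_allclose(tr["a"].to_numpy(), col, atol=1e-12)

    def test_test_value_at_train_mean_maps_to_zero(self):
        train = pd.DataFrame({"a": [1.0, 3.0, 5.0]})
        test = pd.DataFrame({"a": [3.0]})
        _, te, _ = standardize(train, test)
        assert te["a"].iloc[0] == 0.0

    def test_zero_variance_train_column_dropped(self):
        train = pd.DataFrame({"flat": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0]})
        tr, _, params = standardize(train)
        assert list(tr.columns) == ["ok"]
        assert list(params.index) == ["ok"]


class TestTargetTransform:
    @pytest.mark.parametrize("tnr", [1.0, 3.26, 10.0])
    def test_round_trip(self, tnr):
        assert potentiate(transform_target(np.array([tnr])))[0] == pytest.approx(tnr)

    def test_log10_values(self):
        np.testing.assert_allclose(transform_target(np.array([1.0, 10.0])), [0.0, 1.0])

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            transform_target(np.array([2.0, 0.0]))


class TestSplit:
    def test_40_cases_gives_28_12(self):
        tr, te = split(40, 0.7, seed=0)
        assert len(tr) == 28 and len(te) == 12

    def test_deterministic(self):
        a = split(40, 0.7, seed=123)
        b = split(40, 0.7, seed=123)
        np.testing.assert_array_equal(a[0], b[0])

    def test_partition(self):
        tr, te = split(25, 0.7, seed=5)
        assert sorted(np.concatenate([tr, te]).tolist()) == list(range(25))
        assert set(tr).isdisjoint(te)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            split(1, 0.7, seed=0)


class TestFitLasso:
    def test_infinite_penalty_gives_intercept_only(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        Xs, _, _ = standardize(X)
        y = rng.uniform(0.3, 0.7, 20)
        intercept, coefs = fit_lasso(Xs, y, lambda_rule="fixed:1e9")
        assert intercept == pytest.approx(y.mean())
        assert np.all(coefs.to_numpy() == 0.0)

    def test_zero_penalty_recovers_univariate_ols(self, rng):
        x = rng.standard_normal(30)
        x = (x - x.mean()) / x.std(ddof=1)
        slope_true = 0.37
        y = 0.5 + slope_true * x
        intercept, coefs = fit_lasso(
            pd.DataFrame({"f": x}), y, lambda_rule="fixed:1e-12"
        )
        # closed-form OLS on centered/scaled x
        slope_ols = float(np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2))
        assert coefs["f"] == pytest.approx(slope_ols, abs=1e-6)
        assert coefs["f"] == pytest.approx(slope_true, abs=1e-6)

    def test_duplicated_features_sparse_at_strong_penalty(self, rng):
        x = rng.standard_normal(30)
        y = 0.3 * x + rng.normal(0, 0.01, 30)
        X = pd.DataFrame({"a": x, "b": x.copy()})
        Xs, _, _ = standardize(X)
        _, coefs = fit_lasso(Xs, y, lambda_rule="fixed:0.2")
        # coordinate descent may leave ~1e-16 dust on the duplicate column
        assert int((coefs.abs() > 1e-8).sum()) <= 1

    def test_empty_feature_set(self):
        intercept, coefs = fit_lasso(pd.DataFrame(index=range(5)), np.full(5, 0.51))
        assert intercept == pytest.approx(0.51)
        assert coefs.empty


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([2.0, 3.0, 4.0])
        coefs = pd.Series({"f": 1.0})
        X = pd.DataFrame({"f": np.log10(y)})
        res = evaluate_test(0.0, coefs, X, y)
        assert res.mae == pytest.approx(0.0, abs=1e-12)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_constant_shift_on_tnr_scale(self):
        y = np.array([2.0, 3.0, 4.0])
        coefs = pd.Series({"f": 1.0})
        X = pd.DataFrame({"f": np.log10(y + 1.0)})
        res = evaluate_test(0.0, coefs, X, y)
        assert res.mae == pytest.approx(1.0)
        assert res.rmse == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_intercept_only_constant_predictions(self):
        res = evaluate_test(0.5, pd.Series(dtype=float), pd.DataFrame(index=range(3)),
                            np.array([2.0, 3.0, 4.0]))
        assert np.isnan(res.spearman_rho)
        assert np.isfinite(res.mae)

    def test_metrics_on_tnr_scale_not_log(self):
        # a case where log-scale and TNR-scale errors differ by a lot
        y = np.array([10.0, 100.0])
        coefs = pd.Series({"f": 1.0})
        X = pd.DataFrame({"f": np.array([2.0, 1.0])})  # predicts 100 and 10
        res = evaluate_test(0.0, coefs, X, y)
        assert res.mae == pytest.approx(90.0)  # log-scale MAE would be 1.0


class TestRunStability:
    def test_emits_exactly_n_tests(self, rng):
        X, tnr, _ = make_regression_cohort(n_cases=30, n_features=15, seed=2)
        results = run_stability(X, tnr, ModelConfig(n_tests=7, master_seed=1))
        assert len(results) == 7
        assert [r.test_index for r in results] == list(range(7))

    def test_deterministic_in_master_seed(self):
        X, tnr, _ = make_regression_cohort(n_cases=30, n_features=15, seed=2)
        cfg = ModelConfig(n_tests=5, master_seed=42)
        a = results_to_frame(run_stability(X, tnr, cfg))
        b = results_to_frame(run_stability(X, tnr, cfg))
        pd.testing.assert_frame_equal(a, b)

    def test_single_test(self):
        X, tnr, _ = make_regression_cohort(n_cases=20, n_features=10, seed=3)
        assert len(run_stability(X, tnr, ModelConfig(n_tests=1))) == 1


class TestAggregate:
    def _result(self, i, mae, selected=()):
        from petrad.stability import TestResult

        return TestResult(test_index=i, mae=mae, rmse=mae, spearman_rho=0.5,
                          spearman_p=0.1, selected=list(selected))

    def test_median_of_three(self):
        rep = aggregate([self._result(i, m) for i, m in enumerate([1.0, 2.0, 3.0])])
        assert rep.metrics["mae"]["median"] == 2.0

    def test_share_percentage(self):
        results = [self._result(i, 1.0, [("f", 0.01)]) for i in range(157)]
        results += [self._result(157 + i, 1.0) for i in range(143)]
        rep = aggregate(results)
        row = rep.predictors.iloc[0]
        assert row["n_models"] == 157
        assert row["share_pct"] == pytest.approx(52.3, abs=0.05)

    def test_never_selected_feature_absent(self):
        rep = aggregate([self._result(0, 1.0, [("a", 0.1)])])
        assert list(rep.predictors["feature"]) == ["a"]

    def test_mean_significance(self):
        results = [self._result(0, 1.0, [("a", 0.2)]), self._result(1, 1.0, [("a", 0.4)])]
        rep = aggregate(results)
        assert rep.predictors.iloc[0]["mean_significance"] == pytest.approx(0.3)
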