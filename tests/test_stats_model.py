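"""Screening, multi-correlation, preprocessing and model machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mlcqa.errors import ConfigurationError, ValidationError
from mlcqa.stats_model import (
    Scaler,
    cross_validate,
    fit_lm,
    fit_rf,
    importances_pct,
    kfold_indices,
    mse,
    multi_correlation,
    preprocess,
    spearman_screen,
    train_and_evaluate,
    variance_explained_pct,
)


def table_from(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestSpearmanScreen:
    def test_perfect_and_inverse_monotone(self, rng):
        y = rng.normal(size=30)
        tbl = table_from({"same": y, "inv": np.exp(-y), "deviation_mm": y})
        out = spearman_screen(tbl, ["same", "inv"])
        assert out.loc["same", "spearman_r"] == pytest.approx(1.0)
        assert out.loc["inv", "spearman_r"] == pytest.approx(-1.0)
        assert bool(out.loc["same", "effective"])

    def test_constant_factor_is_nan_and_ineffective(self, rng):
        tbl = table_from({"const": np.ones(20), "deviation_mm": rng.normal(size=20)})
        out = spearman_screen(tbl, ["const"])
        assert np.isnan(out.loc["const", "spearman_r"])
        assert not bool(out.loc["const", "effective"])

    def test_null_spread_at_cohort_size(self):
        """Independent factor at n = 744: |r| stays below 0.073 (the 95%
        null quantile at this n) in about 95% of replicates."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 600
        for _ in range(reps):
            r, _ = stats.spearmanr(rng.normal(size=744), rng.normal(size=744))
            hits += abs(r) < 0.073
        assert 0.93 < hits / reps < 0.97


class TestMultiCorrelation:
    def test_exact_factor_gives_R_one(self, rng):
        y = rng.normal(size=40)
        res = multi_correlation(pd.DataFrame({"x": y}), y)
        assert res.R == pytest.approx(1.0)

    def test_single_factor_equals_abs_pearson(self, rng):
        x = rng.normal(size=60)
        y = -0.6 * x + rng.normal(size=60)
        res = multi_correlation(pd.DataFrame({"x": x}), y)
        assert res.R == pytest.approx(abs(np.corrcoef(x, y)[0, 1]), abs=1e-12)

    def test_r_squared_matches_independent_ols(self, rng):
        """R is corr(y, y-hat) with y-hat from an independent lstsq path."""
        for _ in range(50):
            X = rng.normal(size=(40, 5))
            y = X @ rng.normal(size=5) + rng.normal(size=40)
            res = multi_correlation(pd.DataFrame(X, columns=list("abcde")), y)
            design = np.column_stack([np.ones(40), X])
            beta = np.linalg.lstsq(design, y, rcond=None)[0]
            R_ref = np.corrcoef(y, design @ beta)[0, 1]
            assert res.R == pytest.approx(R_ref, abs=1e-10)
            assert res.r_squared == pytest.approx(R_ref**2, abs=1e-10)

    def test_null_R_inflation_scale(self):
        """Independent y at k=11, n=744: the null mean of R sits near
        sqrt(k/(n-1)), the small-sample inflation floor."""
        rng = np.random.default_rng(11)
        Rs = [
            multi_correlation(
                pd.DataFrame(rng.normal(size=(744, 11))), rng.normal(size=744)
            ).R
            for _ in range(150)
        ]
        expected = np.sqrt(11 / 743)
        assert np.mean(Rs) == pytest.approx(expected, rel=0.1)

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=30)})
        with pytest.raises(ValidationError, match="a, b"):
            multi_correlation(X, rng.normal(size=30))


class TestPreprocess:
    def test_training_columns_span_unit_interval(self, rng):
        train = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        scaled, _ = preprocess(train, train)
        assert np.allclose(scaled.min(), 0.0)
        assert np.allclose(scaled.max(), 1.0)

    def test_hand_worked_midpoint(self):
        train = pd.DataFrame({"x": [0.0, 10.0]})
        scaled, scaler = preprocess(train, pd.DataFrame({"x": [5.0]}))
        assert scaled["x"].iloc[0] == pytest.approx(0.5)

    def test_no_clipping_outside_training_range(self):
        train = pd.DataFrame({"x": [0.0, 10.0]})
        scaled, _ = preprocess(train, pd.DataFrame({"x": [15.0]}))
        assert scaled["x"].iloc[0] > 1.0

    def test_zero_variance_column_named(self):
        train = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValidationError, match="flat"):
            Scaler().fit(train)

    def test_inverse_transform_round_trip(self, rng):
        train = pd.DataFrame({"y": rng.normal(size=15)})
        scaled, scaler = preprocess(train, train)
        back = scaler.inverse_transform_column(scaled["y"].to_numpy(), "y")
        np.testing.assert_allclose(back, train["y"], atol=1e-12)


class TestModels:
    def test_mse_hand_case(self):
        assert mse([0.0, 2.0], [0.0, 0.0]) == pytest.approx(2.0)

    def test_perfect_prediction(self, rng):
        y = rng.normal(size=10)
        assert mse(y, y) == 0.0
        assert variance_explained_pct(y, y) == 100.0

    def test_rf_constant_target(self, rng):
        X = rng.normal(size=(30, 4))
        model = fit_rf(X, np.full(30, 1.3), mtry=2, oob=False)
        np.testing.assert_allclose(model.predict(X), 1.3)

    def test_rf_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 4))
        y = X[:, 0] + rng.normal(scale=0.1, size=60)
        p1 = fit_rf(X, y, mtry=2, seed=5, oob=False).predict(X)
        p2 = fit_rf(X, y, mtry=2, seed=5, oob=False).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_rf_oob_beats_mean_baseline(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 5))
        y = np.sin(2 * X[:, 0]) + 0.5 * X[:, 1] ** 2 + rng.normal(scale=0.2, size=300)
        model = fit_rf(X, y, mtry=3, seed=0, oob=True)
        assert model.oob_score_ > 0  # R^2 > 0 <=> OOB MSE below Var(y)

    def test_mtry_exceeding_inputs_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            fit_rf(rng.normal(size=(20, 3)), rng.normal(size=20), mtry=6)

    def test_lm_exact_linear_truth(self, rng):
        X = rng.normal(size=(50, 3))
        beta = np.array([1.0, -2.0, 0.5])
        model = fit_lm(X, X @ beta + 3.0)
        Xt = rng.normal(size=(20, 3))
        assert mse(Xt @ beta + 3.0, model.predict(Xt)) < 1e-20

    def test_lm_recovers_coefficients_within_3se(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(200, 3))
        beta = np.array([0.8, -0.4, 0.0])
        y = X @ beta + rng.normal(scale=0.5, size=200)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        model = fit_lm(X, y)
        np.testing.assert_allclose(model.coef_, fit.params[1:], atol=1e-10)
        assert np.all(np.abs(model.coef_ - beta) < 3 * fit.bse[1:])

    def test_rf_beats_lm_on_nonlinear_truth(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(400, 4))
        y = np.sin(2.5 * X[:, 0]) + X[:, 1] * X[:, 2] + rng.normal(scale=0.1, size=400)
        Xtr, ytr, Xte, yte = X[:280], y[:280], X[280:], y[280:]
        rf = fit_rf(Xtr, ytr, mtry=2, seed=0, oob=False)
        lm = fit_lm(Xtr, ytr)
        assert mse(yte, rf.predict(Xte)) < mse(yte, lm.predict(Xte))

    def test_importances_sum_to_100(self, rng):
        X = rng.normal(size=(80, 5))
        y = X[:, 0] + rng.normal(scale=0.2, size=80)
        imp = importances_pct(fit_rf(X, y, mtry=3, oob=False), list("abcde"))
        assert sum(imp.values()) == pytest.approx(100.0, abs=1e-9)
        assert all(v >= 0 for v in imp.values())


class TestCrossValidation:
    def test_fold_sizes_at_cohort_training_n(self):
        folds = kfold_indices(521, 5, seed=0)
        sizes = sorted((len(va) for _, va in folds), reverse=True)
        assert sizes == [105, 104, 104, 104, 104]

    def test_folds_partition_training_rows(self):
        folds = kfold_indices(83, 5, seed=1)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(83))
        for tr, va in folds:
            assert not set(tr) & set(va)

    @staticmethod
    def _toy_table(rng, n=60):
        X = rng.normal(size=(n, 11))
        y = 0.4 + 0.1 * X[:, 0] + rng.normal(scale=0.05, size=n)
        cols = [
            "correlation", "energy", "entropy", "homogeneity", "dice",
            "ME", "BL", "MSC", "PWM", "LO", "CO",
        ]
        tbl = pd.DataFrame(X, columns=cols)
        tbl["deviation_mm"] = y
        return tbl

    def test_fold_scalers_ignore_test_rows(self, rng):
        """Injecting an outlier into a held-out test row must not change any
        fold scaler fitted inside the training set (no leakage)."""
        tbl = self._toy_table(rng, n=80)
        res1 = train_and_evaluate(tbl, seed=3, n_trees=20)
        poisoned = tbl.copy()
        j = res1.test_indices[0]
        poisoned.loc[j, "deviation_mm"] = 99.0
        poisoned.loc[j, "PWM"] = -50.0
        res2 = train_and_evaluate(poisoned, seed=3, n_trees=20)
        for p1, p2 in zip(res1.cv.fold_scaler_params, res2.cv.fold_scaler_params):
            for key in p1:
                np.testing.assert_array_equal(p1[key], p2[key])
        np.testing.assert_allclose(res1.cv.fold_mse_scaled, res2.cv.fold_mse_scaled)

    def test_split_is_disjoint_and_complete(self, rng):
        tbl = self._toy_table(rng, n=50)
        res = train_and_evaluate(tbl, seed=0, n_trees=20)
        assert not set(res.train_indices) & set(res.test_indices)
        assert len(res.train_indices) + len(res.test_indices) == 50

    def test_cv_result_shapes(self, rng):
        tbl = self._toy_table(rng, n=60)
        cv = cross_validate(tbl, n_folds=5, seed=0, n_trees=20)
        assert len(cv.fold_mse_scaled) == 5
        assert len(cv.fold_scaler_params) == 5
        assert cv.mse_scaled >= 0
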