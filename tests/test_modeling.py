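import numpy as np
import pandas as pd
import pytest

from funcdens.modeling import (
    ModelError,
    RelaxedLassoResult,
    adjusted_r2,
    bootstrap_adj_r2_ci,
    model_accepted,
    nested_cv_r2,
    predict,
    relaxed_lasso_fit,
    standardize,
)


def _design(rng, n=500, p=10, beta=None, sigma=0.1):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta, dtype=float)
    y = X @ np.pad(beta, (0, p - len(beta))) + rng.normal(0, sigma, size=n)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]), y


class TestStandardize:
    def test_closed_form_and_population_denominator(self):
        out, rec = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["a"], [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert rec.scale["a"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std()
        out, _ = standardize(pd.DataFrame({"a": x}))
        np.testing.assert_allclose(out["a"], x, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out, rec = standardize(df)
        assert list(out.columns) == ["a"]
        assert rec.dropped_constant == ("b",)

    def test_all_constant_is_model_error(self):
        with pytest.raises(ModelError):
            standardize(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = np.arange(10.0)
        assert adjusted_r2(y, y, 3) == 1.0

    def test_zero_r2_penalized_below_zero(self):
        y = np.array([1.0, -1.0] * 50)
        y_hat = np.full(100, y.mean())
        assert adjusted_r2(y, y_hat, 5) < 0.0

    def test_closed_form_arithmetic(self):
        # R^2 = 0.5, n = 101, p = 10 -> 1 - 0.5 * 100 / 90
        rng = np.random.default_rng(0)
        y = rng.normal(size=101)
        ss_tot = np.sum((y - y.mean()) ** 2)
        resid = y - y.mean()
        y_hat = y - resid * np.sqrt(0.5 * ss_tot / np.sum(resid**2))
        assert adjusted_r2(y, y_hat, 10) == pytest.approx(1 - 0.5 * 100 / 90, abs=1e-9)

    def test_degenerate_sample_size_flagged(self):
        with pytest.raises(ModelError):
            adjusted_r2(np.arange(5.0), np.arange(5.0), 4)


class TestRelaxedLasso:
    def test_recovers_planted_support_and_coefficients(self):
        rng = np.random.default_rng(42)
        X, y = _design(rng, beta=[2.0, -3.0], sigma=0.1)
        fit = relaxed_lasso_fit(X, y, seed=0)
        assert set(fit.selected) == {"x0", "x1"}
        assert fit.coefficients["x0"] == pytest.approx(2.0, abs=0.05)
        assert fit.coefficients["x1"] == pytest.approx(-3.0, abs=0.05)

    def test_single_perfect_predictor_noiseless(self):
        rng = np.random.default_rng(1)
        X, y = _design(rng, n=100, p=5, beta=[1.0], sigma=0.0)
        fit = relaxed_lasso_fit(X, y, seed=0)
        assert fit.adj_r2 > 0.999
        assert "x0" in fit.selected

    def test_pure_noise_yields_intercept_only_most_runs(self):
        flagged = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X, y = _design(rng, n=100, p=10, beta=None, sigma=1.0)
            fit = relaxed_lasso_fit(X, y, seed=seed)
            flagged += fit.intercept_only
        assert flagged >= 40  # >= 80% of 50 null runs

    def test_relaxed_refit_rss_not_above_lasso_rss(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(5)
        X, y = _design(rng, n=200, p=8, beta=[1.0, 0.5, -0.7], sigma=0.5)
        fit = relaxed_lasso_fit(X, y, seed=0)
        Xs, _ = standardize(X)
        lasso = Lasso(alpha=fit.alpha).fit(Xs.to_numpy(), y)
        rss_lasso = np.sum((y - lasso.predict(Xs.to_numpy())) ** 2)
        rss_relaxed = (1 - fit.r2) * np.sum((y - y.mean()) ** 2)
        assert rss_relaxed <= rss_lasso + 1e-9

    def test_adj_r2_never_exceeds_r2(self):
        rng = np.random.default_rng(7)
        X, y = _design(rng, n=120, p=6, beta=[0.8, -0.4], sigma=1.0)
        fit = relaxed_lasso_fit(X, y, seed=0)
        assert fit.adj_r2 <= fit.r2

    def test_seeded_runs_are_bit_reproducible(self):
        rng = np.random.default_rng(9)
        X, y = _design(rng, n=150, p=6, beta=[1.0, -1.0], sigma=0.8)
        a = relaxed_lasso_fit(X, y, seed=3)
        b = relaxed_lasso_fit(X, y, seed=3)
        assert a.selected == b.selected
        assert (a.coefficients == b.coefficients).all()
        assert a.cv_r2 == b.cv_r2 and a.alpha == b.alpha

    def test_row_floor_and_fold_guards(self):
        rng = np.random.default_rng(0)
        X, y = _design(rng, n=20, p=3, beta=[1.0], sigma=0.1)
        with pytest.raises(ModelError):
            relaxed_lasso_fit(X, y, min_rows=30)
        with pytest.raises(ModelError):
            relaxed_lasso_fit(X.iloc[:8], y[:8], folds=10, min_rows=5)


class TestBootstrapCI:
    def test_noiseless_interval_collapses_near_one(self):
        rng = np.random.default_rng(11)
        X, y = _design(rng, n=200, p=4, beta=[1.5], sigma=1e-8)
        fit = relaxed_lasso_fit(X, y, seed=0)
        lo, hi = bootstrap_adj_r2_ci(X, y, fit, B=200, seed=0)
        assert hi - lo < 0.01 and lo > 0.99

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(13)
        X, y = _design(rng, n=150, p=5, beta=[1.0, -0.6], sigma=1.0)
        fit = relaxed_lasso_fit(X, y, seed=0)
        lo, hi = bootstrap_adj_r2_ci(X, y, fit, B=500, seed=1)
        assert lo <= fit.adj_r2 <= hi

    def test_small_b_warns_and_intercept_only_rejected(self):
        rng = np.random.default_rng(17)
        X, y = _design(rng, n=100, p=4, beta=[2.0], sigma=0.2)
        fit = relaxed_lasso_fit(X, y, seed=0)
        with pytest.warns(UserWarning):
            bootstrap_adj_r2_ci(X, y, fit, B=50, seed=0)
        X2, y2 = _design(np.random.default_rng(18), n=100, p=4, beta=None, sigma=1.0)
        fit2 = relaxed_lasso_fit(X2, y2, seed=4)
        if fit2.intercept_only:
            with pytest.raises(ModelError):
                bootstrap_adj_r2_ci(X2, y2, fit2, B=200, seed=0)


class TestModelAcceptance:
    def _result(self, ci, pvalue=0.001, selected=("rho",)):
        return RelaxedLassoResult(
            selected=selected,
            coefficients=pd.Series({"const": 0.0, "rho": 1.0}),
            pvalues=pd.Series({"rho": pvalue}),
            r2=0.3, adj_r2=(ci[0] + ci[1]) / 2, cv_r2=0.2, adj_r2_ci=ci,
            alpha=0.1, n=150, p_selected=len(selected), intercept_only=not selected,
            lambda_rule="1se", seed=0,
        )

    def test_published_interval_pattern(self):
        # an interval with lower bound 0.14 passes the > 0.10 rule,
        # one with lower bound 0.08 fails it
        assert model_accepted(self._result((0.14, 0.46))) is True
        assert model_accepted(self._result((0.08, 0.34))) is False

    def test_requires_significant_feature(self):
        assert model_accepted(self._result((0.2, 0.5), pvalue=0.2)) is False

    def test_intercept_only_rejected(self):
        res = self._result((0.2, 0.5))
        res.selected = ()
        res.intercept_only = True
        assert model_accepted(res) is False

    def test_missing_ci_is_an_error(self):
        res = self._result((0.2, 0.5))
        res.adj_r2_ci = None
        with pytest.raises(ModelError):
            model_accepted(res)


class TestNestedCV:
    def test_same_seed_gives_identical_folds_and_score(self, default_bundle):
        agg = default_bundle["aggregated"]
        dm = default_bundle["distances"]
        a = nested_cv_r2(agg, dm, "peak_current", seed=5)
        b = nested_cv_r2(agg, dm, "peak_current", seed=5)
        assert a == b

    def test_hotspot_signal_is_predictive_out_of_fold(self, default_bundle):
        agg = default_bundle["aggregated"]
        dm = default_bundle["distances"]
        cv = nested_cv_r2(agg, dm, "peak_current", seed=0)
        assert cv > 0.3

    def test_too_few_variants_rejected(self, default_bundle):
        dm = default_bundle["distances"]
        few = default_bundle["aggregated"][:5]
        with pytest.raises(ModelError):
            nested_cv_r2(few, dm, "peak_current", outer_folds=10)


class TestPredict:
    def test_prediction_uses_only_selected_columns(self, rng):
        X, y = _design(rng, n=120, p=5, beta=[2.0], sigma=0.1)
        fit = relaxed_lasso_fit(X, y, seed=0)
        yhat = predict(fit, X)
        assert np.corrcoef(yhat, y)[0, 1] ** 2 > 0.99
        X_perturbed = X.copy()
        for c in X.columns:
            if c not in fit.selected:
                X_perturbed[c] = 999.0
        np.testing.assert_array_equal(predict(fit, X_perturbed), yhat)
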