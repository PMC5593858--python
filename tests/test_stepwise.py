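import numpy as np
import pytest
from scipy import stats

import aquaspec as aq
from aquaspec.stepwise import (
    InsufficientDataError,
    SingularDesignError,
    durbin_watson,
    ols_fit,
    partial_f_enter,
    partial_f_remove,
    stepwise_select,
)


def nested_f_oracle(X_reduced, X_full, y, df2):
    """Classic nested-model F from two independent full fits."""
    sse_r = ols_fit(X_reduced, y).ss_resid
    sse_f = ols_fit(X_full, y).ss_resid
    return ((sse_r - sse_f) / 1.0) / (sse_f / df2)


class TestOLS:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 1, 10)
        state = ols_fit(x, 3 + 2 * x)
        assert state.intercept == pytest.approx(3.0)
        assert state.coefficients[0] == pytest.approx(2.0)
        assert state.ss_resid == pytest.approx(0.0, abs=1e-20)

    def test_orthogonal_predictor_gets_zero_slope(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])  # centred, orthogonal to x
        assert ols_fit(x, y).coefficients[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        state = ols_fit(X, y)
        D = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert np.allclose([state.intercept, *state.coefficients], beta, rtol=1e-8)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        state = ols_fit(X, y)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose([state.intercept, *state.coefficients], res.params, rtol=1e-8)
        assert state.ss_resid == pytest.approx(res.ssr, rel=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(SingularDesignError, match="x2"):
            ols_fit(np.column_stack([x, 2 * x]), rng.normal(size=20), names=["x1", "x2"])

    def test_ss_decomposition(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        state = ols_fit(X, y)
        assert state.ss_total == pytest.approx(state.ss_regression + state.ss_resid)


class TestPartialF:
    def test_redundant_candidate_gets_zero(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        f, p = partial_f_enter(x, y, x.copy())
        assert f == 0.0 and p == 1.0

    def test_perfect_candidate_capped_with_p_zero(self):
        x = np.linspace(0, 1, 12)
        f, p = partial_f_enter(np.empty((12, 0)), 2 + 5 * x, x)
        assert f >= 1e6 and p == 0.0

    def test_enter_equals_nested_oracle_small_n(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        f, p = partial_f_enter(X[:, :1], y, X[:, 1])
        n, l = 8, 1
        f_oracle = nested_f_oracle(X[:, :1], X, y, n - l - 2)
        assert f == pytest.approx(f_oracle, rel=1e-10)
        assert p == pytest.approx(stats.f.sf(f_oracle, 1, n - l - 2), rel=1e-10)

    def test_remove_equals_nested_oracle_small_n(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        f, _ = partial_f_remove(X, y, member=1)
        f_oracle = nested_f_oracle(X[:, :1], X, y, 8 - 2 - 1)
        assert f == pytest.approx(f_oracle, rel=1e-10)

    def test_duplicated_member_removal_is_free(self, rng):
        x = rng.normal(size=20)
        # exactly duplicated column: deleting either copy costs nothing
        Xdup = np.column_stack([x, rng.normal(size=20), x])
        f, p = partial_f_remove(Xdup, rng.normal(size=20), member=2)
        assert f == pytest.approx(0.0, abs=1e-6) and p == pytest.approx(1.0)

    def test_null_member_f_near_one(self):
        """For a coefficient that is truly zero, the removal F is F(1, df)
        distributed with expectation df/(df-2) ~ 1."""
        rng = np.random.default_rng(99)
        fs = []
        for _ in range(300):
            X = rng.normal(size=(100, 2))
            y = 1.0 + 2.0 * X[:, 0] + rng.normal(size=100)  # column 1 inert
            fs.append(partial_f_remove(X, y, member=1)[0])
        assert np.mean(fs) == pytest.approx(1.0, abs=0.25)

    def test_insufficient_df_raises(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(InsufficientDataError):
            partial_f_enter(X, rng.normal(size=5), rng.normal(size=5))


class TestStepwiseSelection:
    def test_exact_single_variable_model(self, rng):
        Z = rng.normal(size=(30, 3))
        y = 2.0 + 3.0 * Z[:, 0]
        model = stepwise_select(Z, y, names=["Z1", "Z2", "Z3"])
        assert model.variable_names == ("Z1",)
        assert model.intercept == pytest.approx(2.0, abs=1e-8)
        assert model.coefficients[0] == pytest.approx(3.0, rel=1e-8)
        assert model.r2 == pytest.approx(1.0)

    def test_pure_noise_rarely_selects(self):
        """Family-wise entry behaviour at alpha 0.05: with six inert
        candidates, most replicates end with the empty model."""
        rng = np.random.default_rng(4)
        empty = 0
        reps = 300
        for _ in range(reps):
            Z = rng.normal(size=(72, 6))
            model = stepwise_select(Z, rng.normal(size=72))
            empty += not model.variable_names
        # best-of-six entry at alpha=0.05 keeps ~75-85% of runs empty
        assert empty / reps > 0.60

    def test_recovers_planted_model(self):
        z, y, truth = aq.generate_cross_variable_data(n=72, rng=42)
        model = stepwise_select(z, y)
        assert set(model.variable_names) == set(truth.active_variables)

    def test_candidate_order_invariance(self, rng):
        z, y, _ = aq.generate_cross_variable_data(n=72, rng=5)
        base = stepwise_select(z.values, y, names=z.names)
        perm = rng.permutation(6)
        shuffled = stepwise_select(
            z.values[:, perm], y, names=[z.names[j] for j in perm]
        )
        assert set(base.variable_names) == set(shuffled.variable_names)
        base_coef = dict(zip(base.variable_names, base.coefficients))
        shuf_coef = dict(zip(shuffled.variable_names, shuffled.coefficients))
        for name in base_coef:
            assert shuf_coef[name] == pytest.approx(base_coef[name], rel=1e-9)

    def test_monotone_residual_ss_through_log(self):
        z, y, _ = aq.generate_cross_variable_data(n=72, rng=8)
        model = stepwise_select(z, y)
        # replay the step log: residual SS never rises on entry
        in_model: list[str] = []
        last_ssr = float(np.sum((y - y.mean()) ** 2))
        for entry in model.step_log:
            if entry["action"] == "enter":
                in_model.append(entry["variable"])
            else:
                in_model.remove(entry["variable"])
            X = np.column_stack([z.column(nm) for nm in in_model]) if in_model else np.empty((72, 0))
            ssr = ols_fit(X, y).ss_resid
            if entry["action"] == "enter":
                assert ssr <= last_ssr + 1e-12
            else:
                assert ssr >= last_ssr - 1e-12
            last_ssr = ssr

    def test_report_renders_equation(self):
        z, y, _ = aq.generate_cross_variable_data(n=72, rng=3)
        model = stepwise_select(z, y)
        eq = model.equation()
        assert eq.startswith("Y = ")
        for name in model.variable_names:
            assert name in eq
        assert "Durbin-Watson" in model.report()

    def test_retained_variables_pass_stay_test(self):
        z, y, _ = aq.generate_cross_variable_data(n=72, rng=21)
        model = stepwise_select(z, y, alpha_out=0.05)
        for name in model.variable_names:
            assert model.partial_p[name] <= 0.05

    def test_fixed_f_threshold_mode(self):
        z, y, truth = aq.generate_cross_variable_data(n=72, rng=42)
        model = stepwise_select(z, y, f_in=4.0, f_out=3.9)
        assert set(model.variable_names) >= set(truth.active_variables) - {None}


class TestDurbinWatson:
    def test_hand_value(self):
        assert durbin_watson(np.array([1.0, 2.0, 3.0])) == pytest.approx(2 / 14)

    def test_alternating_residuals_approach_four(self):
        e = np.resize([1.0, -1.0], 1000)
        assert durbin_watson(e) == pytest.approx(4.0, abs=0.01)

    def test_iid_residuals_near_two(self):
        e = np.random.default_rng(0).normal(size=20000)
        assert durbin_watson(e) == pytest.approx(2.0, abs=0.05)

    def test_matches_statsmodels(self, rng):
        sm_tools = pytest.importorskip("statsmodels.stats.stattools")
        e = rng.normal(size=50)
        assert durbin_watson(e) == pytest.approx(sm_tools.durbin_watson(e), rel=1e-12)

    def test_zero_residuals_not_applicable(self):
        assert np.isnan(durbin_watson(np.zeros(10)))
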