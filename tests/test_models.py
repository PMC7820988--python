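import numpy as np
import pytest
import statsmodels.api as sm

from selstab import (Dataset, FitError, SeparationError,
                     SingularDesignError, fit_model, term_test)
from selstab.models import FittedModel, term_pvalues

from conftest import make_linear_dataset
from oracles import chi2_sf_by_quadrature, cox_grid_argmax


def _manual_fit(params, bse, cov, family="logistic", df_resid=None,
                term_map=None):
    p = len(params)
    cols = tuple(f"c{i}" for i in range(p))
    if term_map is None:
        term_map = {c: np.array([i]) for i, c in enumerate(cols)}
    return FittedModel(family=family, columns=cols, term_map=term_map,
                       params=np.asarray(params, float),
                       bse=np.asarray(bse, float),
                       cov=np.asarray(cov, float), loglik=0.0, aic=0.0,
                       nobs=100, df_resid=df_resid)


class TestLinear:
    def test_two_group_means(self):
        # intercept = mean of first group, slope = difference of means
        d = Dataset(np.array([[0.0], [0.0], [1.0], [1.0]]),
                    np.array([1.0, 2.0, 3.0, 4.0]), {"x": [0]}, "linear")
        f = fit_model(d)
        assert f.intercept == pytest.approx(1.5)
        assert f.params[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_statsmodels_normal_equations(self, seed):
        d = make_linear_dataset(N=50, seed=seed, corr=0.5)
        f = fit_model(d)
        res = sm.OLS(d.y, sm.add_constant(d.X)).fit()
        np.testing.assert_allclose(f.params, res.params[1:], rtol=1e-8)
        np.testing.assert_allclose(f.intercept, res.params[0], rtol=1e-8)
        np.testing.assert_allclose(f.bse, res.bse[1:], rtol=1e-8)
        np.testing.assert_allclose(f.cov, np.asarray(res.cov_params())[1:, 1:],
                                   rtol=1e-7, atol=1e-12)
        assert f.loglik == pytest.approx(res.llf, rel=1e-10)
        assert f.aic == pytest.approx(res.aic, rel=1e-10)
        assert f.df_resid == res.df_resid

    def test_subset_of_terms(self, toy_linear):
        f = fit_model(toy_linear, ["x1", "x3"])
        assert f.columns == ("x1", "x3")
        res = sm.OLS(toy_linear.y,
                     sm.add_constant(toy_linear.X[:, [0, 2]])).fit()
        np.testing.assert_allclose(f.params, res.params[1:], rtol=1e-8)

    def test_aic_definition(self, toy_linear):
        f = fit_model(toy_linear)
        assert f.aic == pytest.approx(-2 * f.loglik + 2 * (len(f.params) + 1))

    def test_aic_drop_matches_wald_square_minus_two(self):
        # dropping a 1-df term with Wald statistic z changes AIC by ~ z^2 - 2
        d = make_linear_dataset(N=4000, seed=5, beta=(1.0, 0.033, 0.0),
                                corr=0.0)
        full = fit_model(d)
        z = full.params[1] / full.bse[1]
        reduced = fit_model(d, ["x1", "x3"])
        assert reduced.aic - full.aic == pytest.approx(z ** 2 - 2, abs=0.05)

    def test_singular_design_raises(self, toy_linear):
        X = np.column_stack([toy_linear.X, toy_linear.X[:, 0]])
        terms = dict({t: toy_linear.terms[t] for t in toy_linear.term_names})
        terms["dup"] = [toy_linear.p]
        d = Dataset(X, toy_linear.y, terms, "linear")
        with pytest.raises(SingularDesignError):
            fit_model(d)

    def test_too_few_observations(self):
        d = make_linear_dataset(N=60, seed=1)
        with pytest.raises(FitError):
            fit_model(d.subset(np.arange(5)))


class TestLogistic:
    def test_sign_symmetry_gives_zero_slope(self):
        # (x, y) mapped to (-x, 1-y) leaves the sample invariant, so the
        # ML slope and intercept are exactly 0 by symmetry
        x = np.tile([-1.0, -1.0, 1.0, 1.0], 10)
        y = np.tile([0.0, 1.0, 1.0, 0.0], 10)
        d = Dataset(x[:, None], y, {"x": [0]}, "logistic")
        f = fit_model(d)
        assert abs(f.params[0]) < 1e-8
        assert abs(f.intercept) < 1e-8

    def test_recovers_truth_large_sample(self):
        rng = np.random.default_rng(3)
        N = 20000
        X = rng.standard_normal((N, 2))
        p = 1.0 / (1.0 + np.exp(-(0.5 + 1.0 * X[:, 0])))
        y = (rng.random(N) < p).astype(float)
        d = Dataset(X, y, {"a": [0], "b": [1]}, "logistic")
        f = fit_model(d)
        assert f.converged
        assert f.intercept == pytest.approx(0.5, abs=0.08)
        assert f.params[0] == pytest.approx(1.0, abs=0.08)
        assert f.params[1] == pytest.approx(0.0, abs=0.08)
        # likelihood at the optimum dominates the null model
        null = fit_model(d, [])
        assert f.loglik >= null.loglik

    def test_separation_flagged(self):
        x = np.repeat([-2.0, -1.0, 1.0, 2.0], 5)
        y = (x > 0).astype(float)
        d = Dataset(x[:, None], y, {"x": [0]}, "logistic")
        with pytest.raises(SeparationError):
            fit_model(d)


class TestCox:
    TIMES = np.array([1.0, 2.5, 3.0, 4.2, 5.1, 6.7])
    EVENTS = np.array([1.0, 1.0, 0.0, 1.0, 1.0, 1.0])
    XCOL = np.array([0.5, -1.0, 2.0, 0.0, 1.0, -0.5])

    def test_six_observation_grid_search_oracle(self):
        d = Dataset(self.XCOL[:, None], self.TIMES, {"x": [0]}, "cox",
                    event=self.EVENTS)
        f = fit_model(d)
        oracle = cox_grid_argmax(self.TIMES, self.EVENTS, self.XCOL)
        assert f.params[0] == pytest.approx(oracle, abs=1e-3)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        rng = np.random.default_rng(8)
        N = 120
        X = rng.standard_normal((N, 2))
        T = rng.exponential(1, N) / np.exp(0.7 * X[:, 0])
        C = rng.exponential(2, N)
        time, ev = np.minimum(T, C), (T <= C).astype(float)
        d = Dataset(X, time, {"a": [0], "b": [1]}, "cox", event=ev)
        f = fit_model(d)
        df = pd.DataFrame(X, columns=["a", "b"])
        df["T"], df["E"] = time, ev
        cph = lifelines.CoxPHFitter()
        cph.fit(df, "T", "E")
        np.testing.assert_allclose(f.params, cph.params_.values, atol=1e-4)
        np.testing.assert_allclose(f.bse, cph.standard_errors_.values,
                                   atol=1e-4)
        assert f.loglik >= fit_model(d, []).loglik

    def test_aic_has_no_intercept_parameter(self):
        d = Dataset(self.XCOL[:, None], self.TIMES, {"x": [0]}, "cox",
                    event=self.EVENTS)
        f = fit_model(d)
        assert f.aic == pytest.approx(-2 * f.loglik + 2)


class TestTermTests:
    def test_z_zero_gives_p_one(self):
        f = _manual_fit([0.0], [1.0], np.eye(1))
        assert term_test(f, "c0") == pytest.approx(1.0)

    def test_z_196_normal_reference(self):
        f = _manual_fit([1.96], [1.0], np.eye(1))
        assert term_test(f, "c0") == pytest.approx(0.05, abs=1e-3)

    def test_linear_uses_t_reference(self):
        f = _manual_fit([1.96], [1.0], np.eye(1), family="linear",
                        df_resid=10)
        # heavier tails than the normal reference
        assert term_test(f, "c0") > 0.05 + 1e-3

    def test_multicolumn_wald_against_quadrature_oracle(self):
        V = np.array([[0.04, 0.01], [0.01, 0.09]])
        b = np.array([0.30, -0.25])
        f = _manual_fit(b, np.sqrt(np.diag(V)), V,
                        term_map={"grp": np.array([0, 1])})
        w = float(b @ np.linalg.solve(V, b))
        assert term_test(f, "grp") == pytest.approx(
            chi2_sf_by_quadrature(w, 2), rel=1e-6)

    def test_unknown_term_raises(self):
        f = _manual_fit([1.0], [1.0], np.eye(1))
        with pytest.raises(KeyError):
            term_test(f, "nope")

    def test_vectorized_matches_scalar(self, toy_linear_grouped):
        f = fit_model(toy_linear_grouped)
        pv = term_pvalues(f, f.terms)
        for t, p in zip(f.terms, pv):
            assert term_test(f, t) == pytest.approx(p, rel=1e-12)

    def test_pvalues_in_unit_interval(self, toy_linear_grouped):
        f = fit_model(toy_linear_grouped)
        pv = term_pvalues(f, f.terms)
        assert ((pv >= 0) & (pv <= 1)).all()
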