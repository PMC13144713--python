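"""Factor model, regressions, correlations and indirect effects."""

import numpy as np
import pandas as pd
import pytest

from hardship_ddm import outcome_models as om


def factor_data(rng, n, loadings):
    lam = np.asarray(loadings)
    f = rng.standard_normal(n)
    X = lam * f[:, None] + np.sqrt(1 - lam ** 2) * rng.standard_normal((n, len(lam)))
    return pd.DataFrame(X, columns=[f"y{i+1}" for i in range(len(lam))]), f


class TestOneFactor:
    def test_loading_recovery_large_sample(self, rng):
        df, _ = factor_data(rng, 100_000, (0.8, 0.7, 0.6))
        fm = om.fit_one_factor(df)
        assert np.allclose(fm.loadings, [0.8, 0.7, 0.6], atol=0.01)

    def test_just_identified_closed_form(self, rng):
        # three indicators: lambda_1 = sqrt(c12 c13 / c23) at the ML solution
        df, _ = factor_data(rng, 5000, (0.75, 0.65, 0.55))
        fm = om.fit_one_factor(df)
        S = np.cov(df.to_numpy().T, ddof=0)
        lam1 = np.sqrt(S[0, 1] * S[0, 2] / S[1, 2])
        assert fm.loadings.iloc[0] == pytest.approx(lam1, abs=1e-4)

    def test_uncorrelated_indicators_warn(self, rng):
        df = pd.DataFrame(rng.standard_normal((2000, 4)),
                          columns=list("abcd"))
        fm = om.fit_one_factor(df)
        assert fm.warning is not None

    def test_scores_standardized_and_track_truth(self, rng):
        df, f = factor_data(rng, 3000, (0.8, 0.75, 0.7, 0.65, 0.6))
        fm = om.fit_one_factor(df)
        assert fm.scores.mean() == pytest.approx(0, abs=1e-10)
        assert fm.scores.std(ddof=0) == pytest.approx(1, abs=1e-10)
        assert np.corrcoef(fm.scores, f)[0, 1] > 0.85


class TestRegression:
    def test_single_standardized_predictor_beta_is_correlation(self, rng):
        x = pd.Series(rng.standard_normal(500))
        y = pd.Series(0.4 * x + rng.standard_normal(500))
        res = om.fit_regression(y, x.to_frame("x"))
        r = np.corrcoef(x, y)[0, 1]
        assert res.beta("x") == pytest.approx(r, abs=1e-12)

    def test_complete_data_equals_normal_equations(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        y = pd.Series(X @ [1.0, -0.5, 0.2] + rng.standard_normal(200))
        res = om.fit_regression(y, X)
        Xd = np.column_stack([np.ones(200), X.to_numpy()])
        b = np.linalg.solve(Xd.T @ Xd, Xd.T @ y.to_numpy())
        assert np.allclose(res.table["b"].to_numpy(), b, atol=1e-10)

    def test_intercept_only_returns_mean(self, rng):
        y = pd.Series(rng.standard_normal(100) + 3.0)
        res = om.fit_regression(y, pd.DataFrame(index=y.index))
        assert res.table.loc["const", "b"] == pytest.approx(y.mean())

    def test_collinearity_names_predictors(self, rng):
        x = rng.standard_normal(100)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        y = pd.Series(rng.standard_normal(100))
        with pytest.raises(ValueError, match="collinear.*x1.*x2"):
            om.fit_regression(y, X)

    def test_fiml_equals_ols_when_complete(self, rng):
        X = pd.DataFrame(rng.standard_normal((300, 2)), columns=["a", "b"])
        y = pd.Series(X @ [0.5, -0.3] + rng.standard_normal(300))
        ols = om.fit_regression(y, X, missing="complete")
        fiml = om.fit_regression(y, X, missing="fiml")
        assert np.allclose(ols.table["b"], fiml.table["b"], atol=1e-6)

    def test_fiml_beats_complete_case_under_mar(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        ymis = y.copy()
        # missingness depends on x (MAR): complete-case is biased via
        # selection on x only in the intercept, coefficients stay ok;
        # check FIML recovers the generating slope
        drop = rng.random(n) < 0.5 / (1 + np.exp(-2 * x))
        ymis[drop] = np.nan
        res = om.fit_regression(pd.Series(ymis), pd.DataFrame({"x": x}),
                                missing="fiml", n_boot_se=50)
        assert res.table.loc["x", "b"] == pytest.approx(0.5, abs=0.08)


class TestMediation:
    def _mediation_data(self, rng, n=300, a=-0.4, b=-0.3):
        x = rng.standard_normal(n)
        m = a * x + rng.standard_normal(n)
        y = b * m + 0.1 * x + rng.standard_normal(n)
        return pd.Series(x), pd.Series(m), pd.Series(y)

    def test_additivity_total_equals_direct_plus_indirect(self, rng):
        x, m, y = self._mediation_data(rng)
        cov = pd.DataFrame({"c": rng.standard_normal(len(x))})
        res = om.estimate_indirect(x, m, y, covariates=cov, n_boot=1000, seed=1)
        assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-12)

    def test_null_mediator_ci_covers_zero(self, rng):
        covered = 0
        for k in range(25):
            x = pd.Series(rng.standard_normal(200))
            m = pd.Series(0.4 * x + rng.standard_normal(200))
            y = pd.Series(0.3 * x + rng.standard_normal(200))  # y indep of m | x
            res = om.estimate_indirect(x, m, y, n_boot=1000, seed=k)
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered >= 21

    def test_bootstrap_deterministic_under_seed(self, rng):
        x, m, y = self._mediation_data(rng)
        r1 = om.estimate_indirect(x, m, y, n_boot=1000, seed=7)
        r2 = om.estimate_indirect(x, m, y, n_boot=1000, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_preconditions(self, rng):
        x, m, y = self._mediation_data(rng, n=30)
        with pytest.raises(ValueError, match="n >= 50"):
            om.estimate_indirect(x, m, y)
        x, m, y = self._mediation_data(rng)
        with pytest.raises(ValueError, match="n_boot"):
            om.estimate_indirect(x, m, y, n_boot=100)


class TestPearson:
    def test_exact_cases_and_oracle(self, rng):
        x = rng.standard_normal(50)
        assert om.pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert om.pearson_correlation(x, -2 * x)[0] == pytest.approx(-1.0)
        y = rng.standard_normal(50)
        r, _ = om.pearson_correlation(x, y)
        rr = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(rr, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            om.pearson_correlation([1, 1, 1, 1], [1, 2, 3, 4])
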