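"""Hardship scoring and the fixed-loading latent growth curve."""

import numpy as np
import pandas as pd
import pytest

from hardship_ddm import longitudinal as lg


def items_frame(records):
    """records: (subject, wave_age, [8 item values])"""
    rows = []
    for sid, age, vals in records:
        row = {"subject_id": sid, "wave_age": age}
        row.update({f"item{i+1}": v for i, v in enumerate(vals)})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_wave_sums(n, rng, mean=(1.0, 0.15), sd=(0.8, 0.1), corr=0.3,
                       resid_sd=1.0):
    """Direct continuous simulation from the growth model (test oracle side)."""
    cov = np.array([[sd[0] ** 2, corr * sd[0] * sd[1]],
                    [corr * sd[0] * sd[1], sd[1] ** 2]])
    lat = rng.multivariate_normal(mean, cov, size=n)
    lam = np.array(lg.LOADINGS)
    Y = lat[:, :1] + lat[:, 1:] * lam[None, :] + resid_sd * rng.standard_normal((n, 4))
    return pd.DataFrame(Y, columns=list(lg.WAVE_AGES)), lat


class TestScoring:
    def test_wave_and_cumulative_sums(self):
        recs = [("s", 1, [1] + [0] * 7), ("s", 3, [1, 1] + [0] * 6),
                ("s", 5, [0] * 8), ("s", 9, [1, 1, 1] + [0] * 5)]
        sc = lg.score_hardship(items_frame(recs))
        assert list(sc.wave_sums.loc["s"]) == [1, 2, 0, 3]
        assert sc.cumulative["s"] == 6

    def test_bounds(self):
        all_zero = [("a", w, [0] * 8) for w in lg.WAVE_AGES]
        all_one = [("b", w, [1] * 8) for w in lg.WAVE_AGES]
        sc = lg.score_hardship(items_frame(all_zero + all_one))
        assert sc.cumulative["a"] == 0
        assert sc.cumulative["b"] == 32

    def test_invalid_item_value_rejected(self):
        recs = [("s", 1, [2] + [0] * 7)]
        with pytest.raises(ValueError, match="item values"):
            lg.score_hardship(items_frame(recs))

    def test_partial_wave_rescaled_or_dropped(self):
        six_obs = [1, 1, 0, 0, 1, 0, np.nan, np.nan]   # 6 observed -> rescale
        five_obs = [1, 1, 0, 0, 1, np.nan, np.nan, np.nan]  # 5 -> wave missing
        sc = lg.score_hardship(items_frame([("s", 1, six_obs), ("s", 3, five_obs)]))
        assert sc.wave_sums.loc["s", 1] == pytest.approx(3 * 8 / 6)
        assert np.isnan(sc.wave_sums.loc["s", 3])


class TestGrowthFit:
    def test_exact_linear_data_recovers_means_and_flags_boundary(self):
        lam = np.array(lg.LOADINGS)
        Y = pd.DataFrame(np.tile(1.0 + 0.5 * lam, (30, 1)), columns=list(lg.WAVE_AGES))
        fit = lg.fit_lgcm(Y)
        assert fit.mean_i == pytest.approx(1.0, abs=1e-4)
        assert fit.mean_s == pytest.approx(0.5, abs=1e-4)
        assert fit.heywood

    def test_matches_mixed_model_oracle_on_complete_data(self, rng):
        import statsmodels.formula.api as smf
        Y, _ = simulate_wave_sums(400, rng)
        fit = lg.fit_lgcm(Y)
        long = Y.reset_index().melt(id_vars="index", var_name="age", value_name="y")
        long["t"] = long["age"].map(dict(zip(lg.WAVE_AGES, lg.LOADINGS)))
        mod = smf.mixedlm("y ~ t", long, groups=long["index"], re_formula="~t")
        md = max((mod.fit(reml=False, method=m, maxiter=2000)
                  for m in ("cg", "lbfgs")), key=lambda r: r.llf)
        assert fit.loglik == pytest.approx(md.llf, abs=1e-4)
        assert fit.mean_i == pytest.approx(md.params["Intercept"], abs=1e-3)
        assert fit.mean_s == pytest.approx(md.params["t"], abs=1e-3)

    def test_parameter_recovery_at_study_scale(self, rng):
        Y, _ = simulate_wave_sums(3714, rng)
        fit = lg.fit_lgcm(Y)
        assert abs(fit.mean_i - 1.0) < 3 * fit.se_mean_i
        assert abs(fit.mean_s - 0.15) < 3 * fit.se_mean_s
        assert fit.var_i == pytest.approx(0.64, rel=0.15)
        assert fit.var_s == pytest.approx(0.01, rel=0.25)

    def test_masking_20pct_waves_moves_means_by_under_3_se(self, rng):
        Y, _ = simulate_wave_sums(2000, rng)
        full = lg.fit_lgcm(Y)
        Ym = Y.copy()
        mask = rng.random(Y.shape) < 0.2
        Ym[mask] = np.nan
        masked = lg.fit_lgcm(Ym)
        assert abs(masked.mean_i - full.mean_i) < 3 * masked.se_mean_i
        assert abs(masked.mean_s - full.mean_s) < 3 * masked.se_mean_s


class TestFactorScores:
    def test_no_noise_limit_equals_line_coefficients(self, rng):
        Y, lat = simulate_wave_sums(300, rng, resid_sd=1e-4)
        fit = lg.fit_lgcm(Y)
        scores = lg.factor_scores(fit, Y).scores
        assert np.allclose(scores["i"], lat[:, 0], atol=1e-2)
        assert np.allclose(scores["s"], lat[:, 1], atol=1e-2)

    def test_shrinkage_and_partial_wave_scoring(self, rng):
        Y, lat = simulate_wave_sums(1500, rng)
        Y.iloc[:100, 2:] = np.nan           # partial-wave subjects still scored
        Y.iloc[0, :] = np.nan               # zero-wave subject dropped
        fit = lg.fit_lgcm(Y.iloc[1:])
        gs = lg.factor_scores(fit, Y)
        assert 0 in gs.dropped
        assert len(gs.scores) == len(Y) - 1
        assert gs.scores["i"].var(ddof=0) <= fit.var_i * 1.02
        assert gs.scores["s"].var(ddof=0) <= fit.var_s * 1.02
        # closed-form oracle for the score-truth correlation of complete-wave
        # subjects: with gain G = Psi L' Sigma^-1, corr = (G L Psi)_ss /
        # sqrt((G Sigma G')_ss Psi_ss); assert the empirical value matches
        lam = np.array(fit.loadings)
        L = np.column_stack([np.ones(4), lam])
        Psi = np.array([[0.64, 0.3 * 0.8 * 0.1], [0.3 * 0.8 * 0.1, 0.01]])
        S = L @ Psi @ L.T + 1.0 * np.eye(4)
        G = Psi @ L.T @ np.linalg.inv(S)
        expected = (G @ L @ Psi)[1, 1] / np.sqrt((G @ S @ G.T)[1, 1] * Psi[1, 1])
        complete = Y.iloc[100:].dropna().index
        r = np.corrcoef(gs.scores.loc[complete, "s"], lat[complete, 1])[0, 1]
        assert r == pytest.approx(expected, abs=0.06)
        assert r > 0.5
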