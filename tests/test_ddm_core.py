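"""First-passage density, closed-form summaries, simulator, likelihood."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from hardship_ddm import ddm_core as dc
from hardship_ddm._wfpt import _f_lower_scaled_branch

TABLE_MEANS = dict(v=2.89, a=1.38, z=0.49, t0=0.36)


@pytest.fixture(scope="module")
def mean_params():
    return dc.DDMParams(**TABLE_MEANS)


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(v=2.0, a=-1.0),
        dict(v=2.0, a=1.0, z=0.0),
        dict(v=2.0, a=1.0, z=1.1),
        dict(v=2.0, a=1.0, t0=-0.1),
        dict(v=2.0, a=1.0, sv=-0.5),
        dict(v=2.0, a=1.0, z=0.1, sz=0.3),       # start range leaves (0, 1)
        dict(v=2.0, a=1.0, t0=0.1, st0=0.3),     # t0 range goes negative
    ])
    def test_invariants_enforced(self, bad):
        with pytest.raises(dc.DDMValidationError):
            dc.DDMParams(**bad)


class TestDensity:
    def test_zero_before_nondecision_time(self, mean_params):
        assert dc.wfpt_density(0.30, "correct", mean_params) == 0.0
        assert dc.wfpt_density(0.36, "correct", mean_params) == 0.0

    @pytest.mark.parametrize("params", [
        dc.DDMParams(**TABLE_MEANS),
        dc.DDMParams(v=0.5, a=0.8, z=0.3, t0=0.2),
        dc.DDMParams(v=-1.0, a=2.0, z=0.6, t0=0.5),
        dc.DDMParams(v=2.89, a=1.38, z=0.49, t0=0.36, sv=1.45, sz=0.15, st0=0.12),
        dc.DDMParams(v=4.0, a=1.0, z=0.5, t0=0.3, sv=0.5),
    ])
    def test_normalization_by_quadrature(self, params):
        total = quad(lambda t: dc.wfpt_density(t, "correct", params)
                     + dc.wfpt_density(t, "error", params),
                     0, 30, limit=300)[0]
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_series_branches_agree_on_overlap(self):
        # on a (tau, w) grid where both expansions are affordable the two
        # branches must agree to the requested absolute tolerance
        for tau in np.linspace(0.02, 2.0, 25):
            for w in (0.2, 0.5, 0.8):
                fs = _f_lower_scaled_branch(tau, w, 1e-9, True)
                fl = _f_lower_scaled_branch(tau, w, 1e-9, False)
                assert abs(fs - fl) < 1e-6

    def test_density_matches_simulation_histogram(self, mean_params):
        sim = dc.simulate_trials(mean_params, 200_000, seed=99).completed
        rts = sim.rt[sim.correct == 1]
        lo, hi = 0.595, 0.605                      # 10 ms bin at t = 0.6 s
        p_bin = ((rts >= lo) & (rts < hi)).sum() / len(sim.rt)
        se = math.sqrt(p_bin * (1 - p_bin) / len(sim.rt))
        pred = quad(lambda t: dc.wfpt_density(t, "correct", mean_params), lo, hi)[0]
        assert abs(p_bin - pred) < 3 * se

    def test_invalid_inputs_raise(self, mean_params):
        with pytest.raises(dc.DDMValidationError):
            dc.wfpt_density(np.inf, "correct", mean_params)
        with pytest.raises(dc.DDMValidationError):
            dc.wfpt_density(0.5, "upper", mean_params)


class TestChoiceProbability:
    def test_zero_drift_returns_start_point(self):
        p = dc.DDMParams(v=0.0, a=1.38, z=0.5)
        assert dc.choice_probability(p) == pytest.approx(0.5, abs=1e-12)
        p = dc.DDMParams(v=0.0, a=1.38, z=0.37)
        assert dc.choice_probability(p) == pytest.approx(0.37, abs=1e-9)

    def test_published_mean_parameters_value(self):
        p = dc.DDMParams(v=2.89, a=1.38, z=0.49, t0=0.36)
        assert dc.choice_probability(p) == pytest.approx(0.980, abs=5e-4)

    @pytest.mark.parametrize("v,z", [(1.5, 0.4), (2.89, 0.49), (0.3, 0.7)])
    def test_antisymmetry(self, v, z):
        p1 = dc.choice_probability(dc.DDMParams(v=v, a=1.38, z=z))
        p2 = dc.choice_probability(dc.DDMParams(v=-v, a=1.38, z=1 - z))
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)


class TestMeanDecisionTime:
    def test_zero_drift_limit(self):
        p = dc.DDMParams(v=1e-9, a=1.38, z=0.5)
        assert dc.mean_decision_time(p) == pytest.approx(1.38 ** 2 / 4, rel=1e-6)

    def test_closed_form_value_and_symmetry(self):
        p = dc.DDMParams(v=2.89, a=1.38, z=0.5)
        expected = (1.38 / (2 * 2.89)) * math.tanh(2.89 * 1.38 / 2)
        assert dc.mean_decision_time(p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.230, abs=5e-4)
        m = dc.mean_decision_time(dc.DDMParams(v=-2.89, a=1.38, z=0.5))
        assert m == pytest.approx(expected, rel=1e-12)

    def test_variabilities_unsupported(self):
        with pytest.raises(dc.UnsupportedCaseError):
            dc.mean_decision_time(dc.DDMParams(v=1.0, a=1.0, sv=0.5))


class TestSimulator:
    def test_nondecision_floor_and_determinism(self, mean_params):
        s1 = dc.simulate_trials(mean_params, 5000, seed=4)
        s2 = dc.simulate_trials(mean_params, 5000, seed=4)
        assert np.array_equal(s1.rt, s2.rt, equal_nan=True)
        assert np.array_equal(s1.correct, s2.correct)
        assert s1.completed.rt.min() >= 0.36
        s3 = dc.simulate_trials(mean_params, 5000, seed=5)
        assert not np.array_equal(s1.rt, s3.rt, equal_nan=True)

    @pytest.mark.parametrize("params", [
        dc.DDMParams(**TABLE_MEANS),
        dc.DDMParams(v=2.89, a=1.38, z=0.49, t0=0.36, sv=1.45, sz=0.15, st0=0.12),
        dc.DDMParams(v=0.8, a=1.0, z=0.6, t0=0.25),
    ])
    def test_choice_proportion_matches_closed_form(self, params):
        n = 40_000
        sim = dc.simulate_trials(params, n, seed=17).completed
        p_hat = (sim.correct == 1).mean()
        p = dc.choice_probability(params)
        se = math.sqrt(p * (1 - p) / len(sim.rt))
        assert abs(p_hat - p) < 3 * se

    def test_mean_decision_time_matches_closed_form(self, mean_params):
        sim = dc.simulate_trials(mean_params, 40_000, seed=23).completed
        m_hat = sim.rt.mean() - mean_params.t0
        m = dc.mean_decision_time(mean_params)
        se = (sim.rt - mean_params.t0).std() / math.sqrt(len(sim.rt))
        assert abs(m_hat - m) < 3 * se

    def test_deadline_flags_omissions(self):
        p = dc.DDMParams(v=0.1, a=3.0, z=0.5, t0=0.3)
        sim = dc.simulate_trials(p, 2000, deadline=1.0, seed=8)
        assert sim.omitted.sum() > 0
        assert np.isnan(sim.rt[sim.omitted == 1]).all()
        assert (sim.correct[sim.omitted == 1] == -1).all()
        assert sim.completed.rt.max() <= 1.0

    def test_validation(self, mean_params):
        with pytest.raises(dc.DDMValidationError):
            dc.simulate_trials(mean_params, 0)
        with pytest.raises(dc.DDMValidationError):
            dc.simulate_trials(mean_params, 10, deadline=0.2)


class TestLogLikelihood:
    def test_single_trial_equals_log_density(self, mean_params):
        ll = dc.log_likelihood([0.6], [1], mean_params)
        assert ll == pytest.approx(
            math.log(dc.wfpt_density(0.6, "correct", mean_params)), rel=1e-12)
        ll_err = dc.log_likelihood([0.6], [0], mean_params)
        assert ll_err == pytest.approx(
            math.log(dc.wfpt_density(0.6, "error", mean_params)), rel=1e-12)

    def test_empty_set_is_zero(self, mean_params):
        assert dc.log_likelihood([], [], mean_params) == 0.0

    def test_rt_before_nondecision_time_gives_minus_inf(self, mean_params):
        assert dc.log_likelihood([0.3], [1], mean_params) == -np.inf

    def test_true_parameters_beat_perturbed_drift(self):
        truth = dc.DDMParams(v=2.89, a=1.38, z=0.49, t0=0.36, sv=1.0)
        for seed in range(5):
            sim = dc.simulate_trials(truth, 5000, seed=seed).completed
            ll0 = dc.log_likelihood(sim.rt, sim.correct, truth)
            for dv in (+0.5, -0.5):
                alt = dc.DDMParams(v=2.89 + dv, a=1.38, z=0.49, t0=0.36, sv=1.0)
                assert ll0 > dc.log_likelihood(sim.rt, sim.correct, alt)
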