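"""Disease-model unit tests: trajectory, hazard, quadrature, event sampling."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from alstrialsim import (JointModelParameters, cumulative_hazard,
                         default_parameters, hazard_value, marginal_survival,
                         sample_event_time, sample_event_times,
                         trajectory_value, calibrate_weibull)


@pytest.mark.parametrize("b,treated,t,kwargs,expected", [
    ((0, 0, 0), 0, 0.0, {}, 38.0),
    ((0, 0, 0), 0, 12.0, {}, 38.0 - 12 * 1.06),
    ((2, 0.1, -0.01), 1, 10.0, {"slope_reduction": 0.15},
     40 + (-1.06 * 0.85 + 0.1) * 10 - 0.01 * 100),
])
def test_trajectory_examples(b, treated, t, kwargs, expected):
    p = JointModelParameters(**kwargs)
    assert trajectory_value(p, b, treated, t) == pytest.approx(expected)


def test_trajectory_rejects_negative_time(params):
    with pytest.raises(ValueError):
        trajectory_value(params, (0, 0, 0), 0, -1.0)


def test_parameter_validation():
    with pytest.raises(ValueError):
        JointModelParameters(weibull_shape=-1.0)
    with pytest.raises(ValueError):
        JointModelParameters(sigma_res=0.0)
    with pytest.raises(ValueError):
        JointModelParameters(re_cov=-np.eye(3))
    with pytest.raises(ValueError):
        JointModelParameters(slope_reduction=1.0)


def test_calibrated_defaults_accelerating_hazard(params):
    # death rates accelerate over time: Weibull shape above 1
    assert params.weibull_shape > 1.0


class TestHazard:
    def test_exponential_special_case(self):
        p = JointModelParameters(alpha=0.0, weibull_shape=1.0, weibull_scale=10.0)
        for t in (0.5, 3.0, 17.9):
            assert hazard_value(p, (0, 0, 0), 0, t) == pytest.approx(0.1)

    def test_gamma_halves_hazard(self):
        p = JointModelParameters(alpha=0.0, gamma=math.log(0.5),
                                 weibull_shape=1.4, weibull_scale=8.0)
        for t in (1.0, 6.0, 15.0):
            h0 = hazard_value(p, (0, 0, 0), 0, t)
            h1 = hazard_value(p, (0, 0, 0), 1, t)
            assert h1 / h0 == pytest.approx(0.5)

    def test_alpha_is_log_hr_per_point(self, params):
        # subjects whose latent value differs by one point at time t
        t = 7.0
        h_lo = hazard_value(params, (0, 0, 0), 0, t)
        h_hi = hazard_value(params, (1, 0, 0), 0, t)
        assert h_hi / h_lo == pytest.approx(0.88)

    def test_rejects_nonpositive_time(self, params):
        with pytest.raises(ValueError):
            hazard_value(params, (0, 0, 0), 0, 0.0)


class TestCumulativeHazard:
    def test_exponential_closed_form(self):
        p = JointModelParameters(alpha=0.0, weibull_shape=1.0, weibull_scale=10.0)
        assert cumulative_hazard(p, (0, 0, 0), 0, 5.0) == pytest.approx(0.5)

    def test_weibull_closed_form(self):
        p = JointModelParameters(alpha=0.0, weibull_shape=2.3, weibull_scale=9.0)
        assert cumulative_hazard(p, (0, 0, 0), 0, 7.0) == pytest.approx(
            (7 / 9) ** 2.3, rel=1e-8)
        assert cumulative_hazard(p, (0, 0, 0), 0, 0.0) == 0.0

    def test_against_trapezoid_oracle(self, params):
        b = np.array([1.0, -0.1, 0.005])
        t = 14.0
        ts = np.linspace(1e-9, t, 100_001)
        oracle = np.trapezoid(hazard_value(params, b, 0, ts), ts)
        assert cumulative_hazard(params, b, 0, t) == pytest.approx(
            oracle, rel=1e-6)

    def test_monotone_in_time(self, params):
        b = np.array([-2.0, 0.05, -0.01])
        H = [cumulative_hazard(params, b, 0, t) for t in np.linspace(0, 18, 10)]
        assert np.all(np.diff(H) > 0)


class TestEventSampling:
    def test_weibull_inverse_exact(self):
        p = JointModelParameters(alpha=0.0, weibull_shape=2.3, weibull_scale=9.0)
        u = 0.37
        t, obs = sample_event_time(p, (0, 0, 0), 0, u, 30.0)
        assert obs
        assert t == pytest.approx(9.0 * (-math.log(u)) ** (1 / 2.3), abs=1e-5)

    def test_censoring_branch(self):
        p = JointModelParameters(alpha=0.0, weibull_shape=1.0, weibull_scale=50.0)
        # H(horizon) = 18/50 = 0.36 < -log(0.5) = 0.69
        t, obs = sample_event_time(p, (0, 0, 0), 0, 0.5, 18.0)
        assert not obs and t == 18.0

    def test_monotone_in_u(self, params):
        b = (0.0, 0.0, 0.0)
        times = [sample_event_time(params, b, 0, u, 200.0)[0]
                 for u in (0.05, 0.2, 0.5, 0.8)]
        assert np.all(np.diff(times) < 0)

    def test_rejects_bad_u(self, params):
        with pytest.raises(ValueError):
            sample_event_time(params, (0, 0, 0), 0, 0.0, 18.0)

    def test_alpha_zero_times_are_weibull(self):
        """With no trajectory link, treated event times are exactly
        Weibull(shape, scale * exp(-gamma/shape))."""
        gamma = math.log(0.5)
        p = JointModelParameters(alpha=0.0, gamma=gamma,
                                 weibull_shape=1.6, weibull_scale=12.0)
        rng = np.random.default_rng(5)
        n = 4000
        u = rng.uniform(1e-12, 1, n)
        t, obs = sample_event_times(p, np.zeros((n, 3)), 1.0, u, 500.0)
        assert obs.all()
        scale = 12.0 * math.exp(-gamma / 1.6)
        ks = stats.kstest(t, stats.weibull_min(1.6, scale=scale).cdf)
        assert ks.pvalue > 0.01

    def test_km_matches_model_survival(self, params):
        """Kaplan-Meier of generated times tracks S(t) = E_b[exp(-H(t))]."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(11)
        n = 100_000
        b = rng.standard_normal((n, 3)) @ params.re_chol().T
        u = rng.uniform(1e-12, 1, n)
        t, obs = sample_event_times(params, b, 0.0, u, 18.0)
        km = KaplanMeierFitter().fit(t, obs)
        model = marginal_survival(params, [6.0, 12.0, 18.0], b=b)
        for tt, s_model in zip([6.0, 12.0, 18.0], model):
            s_km = float(km.predict(tt))
            mc_se = math.sqrt(s_model * (1 - s_model) / n)
            assert abs(s_km - s_model) < 4 * mc_se + 1e-3


class TestCalibration:
    def test_exponential_degenerate_closed_form(self):
        # alpha = 0, shape fixed at 1: scale = 12 / (-ln 0.865)
        lam = 12.0 / (-math.log(0.865))
        assert lam == pytest.approx(82.74, abs=0.01)
        p = JointModelParameters(alpha=0.0, weibull_shape=1.0, weibull_scale=lam)
        s = marginal_survival(p, [12.0], mc_n=10_000, seed=0)
        assert s[0] == pytest.approx(0.865, abs=1e-6)

    def test_idempotent_near_calibrated_defaults(self, params):
        shape, scale = calibrate_weibull(params, mc_n=40_000, seed=3)
        assert shape == pytest.approx(params.weibull_shape, rel=0.05)
        assert scale == pytest.approx(params.weibull_scale, rel=0.05)

    def test_rejects_bad_targets(self, params):
        with pytest.raises(ValueError):
            calibrate_weibull(params, {12.0: 0.5, 18.0: 0.6}, mc_n=20_000)


class TestMarginalSurvival:
    def test_monotone_and_one_at_zero(self, params):
        ts = np.array([0.0, 3.0, 6.0, 12.0, 18.0])
        s = marginal_survival(params, ts, mc_n=20_000, seed=1)
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) < 0)

    def test_indirect_pathway_improves_survival(self, params):
        """Slope reduction alone (gamma = 0) lifts 18-month survival."""
        treated = dataclasses.replace(params, slope_reduction=0.30)
        rng = np.random.default_rng(2)
        b = rng.standard_normal((100_000, 3)) @ params.re_chol().T
        s_placebo = marginal_survival(params, [18.0], b=b, treated=0.0)[0]
        s_treated = marginal_survival(treated, [18.0], b=b, treated=1.0)[0]
        assert s_treated > s_placebo + 0.01
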