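import numpy as np
import pytest
from scipy.stats import multivariate_normal

from aquapos.ctcrw import (
    POSITION_PRIOR_VAR,
    CTCRWParams,
    CtcrwDomainError,
    PredictionGrid,
    ctcrw_filter,
    ctcrw_fit,
    ctcrw_predict,
    ctcrw_simulate,
    ctcrw_smooth,
    transition,
)


def dense_oracle(times, y, params):
    """Direct joint-Gaussian evaluation for one axis.

    Builds the full state covariance by propagating prior + transition
    blocks, then evaluates the observation density and the conditional
    (smoothed) state moments with dense linear algebra — no Kalman
    recursion involved.
    """
    n = len(times)
    m = np.zeros(2 * n)
    S = np.zeros((2 * n, 2 * n))
    m[0] = y[0]
    S[0:2, 0:2] = np.diag([POSITION_PRIOR_VAR,
                           10.0 * params.stationary_velocity_var])
    for k in range(1, n):
        F, Q = transition(params, times[k] - times[k - 1])
        m[2 * k:2 * k + 2] = F @ m[2 * (k - 1):2 * k]
        for j in range(k):
            S[2 * k:2 * k + 2, 2 * j:2 * j + 2] = \
                F @ S[2 * (k - 1):2 * k, 2 * j:2 * j + 2]
            S[2 * j:2 * j + 2, 2 * k:2 * k + 2] = \
                S[2 * k:2 * k + 2, 2 * j:2 * j + 2].T
        S[2 * k:2 * k + 2, 2 * k:2 * k + 2] = \
            F @ S[2 * (k - 1):2 * k, 2 * (k - 1):2 * k] @ F.T + Q
    pos = np.arange(0, 2 * n, 2)
    C = S[np.ix_(pos, pos)] + params.measurement_error_sd**2 * np.eye(n)
    ll = multivariate_normal.logpdf(y, mean=m[pos], cov=C)
    K = S[:, pos] @ np.linalg.inv(C)
    cond_mean = m + K @ (y - m[pos])
    cond_cov = S - K @ S[pos, :]
    return ll, cond_mean, cond_cov


PARAMS = CTCRWParams(beta=0.05, sigma=0.5, measurement_error_sd=10.0)


class TestSimulate:
    def test_vanishing_noise_stays_put(self, rng):
        p = CTCRWParams(beta=0.1, sigma=1e-12, measurement_error_sd=0.0)
        pos = ctcrw_simulate(p, np.arange(0.0, 50.0, 5.0),
                             start=(7.0, -3.0), v0=(0.0, 0.0), rng=rng)
        np.testing.assert_allclose(pos[:, 0], 7.0, atol=1e-9)
        np.testing.assert_allclose(pos[:, 1], -3.0, atol=1e-9)

    def test_velocity_variance_reaches_stationary_limit(self):
        p = CTCRWParams(beta=0.5, sigma=0.8)
        _, Q = transition(p, 1000.0)  # beta * dt >> 1
        assert Q[1, 1] == pytest.approx(p.sigma**2 / (2 * p.beta), abs=1e-9)

    def test_velocity_autocorrelation_matches_ou_decay(self, rng):
        p = CTCRWParams(beta=0.5, sigma=1.0)
        times = np.arange(0.0, 100_000.0, 1.0)
        _, vel = ctcrw_simulate(p, times, rng=rng, return_states=True)
        v = vel[:, 0]
        rho = np.corrcoef(v[:-1], v[1:])[0, 1]
        expected = np.exp(-p.beta * 1.0)
        se = (1 - expected**2) / np.sqrt(len(v))
        assert abs(rho - expected) < 3 * se

    def test_nonincreasing_times_rejected(self, rng):
        with pytest.raises(CtcrwDomainError):
            ctcrw_simulate(PARAMS, [0.0, 1.0, 1.0], rng=rng)


class TestFilterSmoother:
    def _track(self, rng, n=8, sd=10.0):
        times = np.cumsum(rng.uniform(20.0, 80.0, n))
        truth = ctcrw_simulate(PARAMS, times, rng=rng)
        obs = truth + rng.normal(0, sd, size=truth.shape)
        return times, obs

    def test_zero_measurement_error_reproduces_observations(self, rng):
        times, obs = self._track(rng, sd=0.0)
        p = CTCRWParams(beta=0.05, sigma=0.5, measurement_error_sd=0.0)
        filt = ctcrw_filter(times, obs, p)
        np.testing.assert_allclose(filt.mean[:, 0], obs[:, 0], atol=1e-8)
        np.testing.assert_allclose(filt.mean[:, 2], obs[:, 1], atol=1e-8)
        smooth = ctcrw_smooth(times, obs, p)
        np.testing.assert_allclose(smooth.mean[:, 0], obs[:, 0], atol=1e-8)

    def test_loglik_and_smoothed_states_match_dense_oracle(self, rng):
        times, obs = self._track(rng, n=5)
        filt = ctcrw_filter(times, obs, PARAMS)
        smooth = ctcrw_smooth(times, obs, PARAMS)
        ll_oracle = 0.0
        for a in range(2):
            ll_a, cm, cc = dense_oracle(times, obs[:, a], PARAMS)
            ll_oracle += ll_a
            np.testing.assert_allclose(smooth.mean[:, 2 * a], cm[0::2],
                                       atol=1e-8)
            np.testing.assert_allclose(smooth.mean[:, 2 * a + 1], cm[1::2],
                                       atol=1e-8)
            np.testing.assert_allclose(smooth.cov[:, a, 0, 0],
                                       np.diag(cc)[0::2], atol=1e-8)
        assert filt.log_likelihood == pytest.approx(ll_oracle, abs=1e-8)
        assert smooth.log_likelihood == pytest.approx(ll_oracle, abs=1e-8)

    def test_smoothed_variance_never_exceeds_filtered(self, rng):
        times, obs = self._track(rng, n=30)
        filt = ctcrw_filter(times, obs, PARAMS)
        smooth = ctcrw_smooth(times, obs, PARAMS)
        assert np.all(smooth.position_var() <= filt.position_var() + 1e-9)

    def test_filter_equals_smoother_at_final_time(self, rng):
        times, obs = self._track(rng, n=12)
        filt = ctcrw_filter(times, obs, PARAMS)
        smooth = ctcrw_smooth(times, obs, PARAMS)
        np.testing.assert_allclose(filt.mean[-1], smooth.mean[-1], atol=1e-10)

    def test_translation_invariance(self, rng):
        times, obs = self._track(rng)
        base = ctcrw_filter(times, obs, PARAMS)
        shifted = ctcrw_filter(times, obs + np.array([1000.0, -500.0]), PARAMS)
        assert shifted.log_likelihood == pytest.approx(base.log_likelihood,
                                                       abs=1e-7)
        np.testing.assert_allclose(shifted.mean[:, 0], base.mean[:, 0] + 1000.0,
                                   atol=1e-6)

    def test_axis_swap_symmetry(self, rng):
        times, obs = self._track(rng)
        a = ctcrw_smooth(times, obs, PARAMS)
        b = ctcrw_smooth(times, obs[:, ::-1], PARAMS)
        np.testing.assert_allclose(a.mean[:, 0], b.mean[:, 2], atol=1e-10)
        np.testing.assert_allclose(a.mean[:, 2], b.mean[:, 0], atol=1e-10)

    def test_too_few_fixes_rejected(self):
        with pytest.raises(CtcrwDomainError):
            ctcrw_filter([0.0], [[0.0, 0.0]], PARAMS)


class TestPredict:
    def test_fencepost_grid_count(self):
        grid = PredictionGrid(interval=60.0, start=0.0, end=600.0)
        assert len(grid.times()) == 11

    def test_grid_outside_span_rejected(self, rng):
        times = np.arange(0.0, 300.0, 30.0)
        obs = ctcrw_simulate(PARAMS, times, rng=rng)
        with pytest.raises(CtcrwDomainError):
            ctcrw_predict(times, obs, PARAMS,
                          PredictionGrid(interval=60.0, start=1000.0, end=2000.0))

    def test_noiseless_prediction_at_observation_time(self, rng):
        times = np.arange(0.0, 300.0, 30.0)
        obs = ctcrw_simulate(PARAMS, times, rng=rng)
        p = CTCRWParams(beta=0.05, sigma=0.5, measurement_error_sd=0.0)
        pred = ctcrw_predict(times, obs, p,
                             PredictionGrid(interval=30.0, start=0.0, end=270.0))
        np.testing.assert_allclose(pred["x"], obs[:, 0], atol=1e-8)
        np.testing.assert_allclose(pred["y"], obs[:, 1], atol=1e-8)

    def test_predictions_vary_smoothly_between_fixes(self, rng):
        times = np.array([0.0, 600.0])
        obs = np.array([[0.0, 0.0], [100.0, 50.0]])
        pred = ctcrw_predict(times, obs, PARAMS,
                             PredictionGrid(interval=10.0, start=0.0, end=600.0))
        steps = np.hypot(np.diff(pred["x"]), np.diff(pred["y"]))
        # bound: 5 x the process displacement SD over one 10 s step,
        # plus the deterministic drift share of the gap
        _, Q = transition(PARAMS, 10.0)
        bound = 100.0 * 10.0 / 600.0 + 50.0 / 600.0 + 5.0 * np.sqrt(Q[0, 0])
        assert np.all(steps < bound + 5.0)


class TestFit:
    def test_fit_loglik_at_least_truth_loglik(self, rng):
        times = np.cumsum(rng.uniform(5.0, 15.0, 400))
        truth = ctcrw_simulate(PARAMS, times, rng=rng)
        obs = truth + rng.normal(0, 10.0, truth.shape)
        fit = ctcrw_fit(times, obs, measurement_error_sd=10.0, seed=0)
        ll_truth = ctcrw_filter(times, obs, PARAMS).log_likelihood
        assert fit.log_likelihood >= ll_truth - 1e-6

    def test_multi_start_stability(self, rng):
        times = np.cumsum(rng.uniform(5.0, 15.0, 300))
        truth = ctcrw_simulate(PARAMS, times, rng=rng)
        obs = truth + rng.normal(0, 10.0, truth.shape)
        lls = [ctcrw_fit(times, obs, measurement_error_sd=10.0,
                         n_starts=2, seed=s).log_likelihood
               for s in range(5)]
        assert max(lls) - min(lls) < 1e-4

    def test_too_few_fixes_for_fitting(self, rng):
        times = np.arange(0.0, 100.0, 10.0)
        obs = ctcrw_simulate(PARAMS, times, rng=rng)
        with pytest.raises(CtcrwDomainError):
            ctcrw_fit(times, obs)
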