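"""Core CT-HMM machinery: rates, transition matrices, likelihood, EM."""

import itertools

import numpy as np
import pytest
from scipy import linalg, stats

import rhythmarm as ra
from rhythmarm.cthmm import (
    ACTIVE,
    REST,
    _transition_objective,
    log_rates,
    transition_matrices,
)
from conftest import make_series


def brute_force_loglik(y, x, hours, params):
    """Marginal log-likelihood by explicit summation over all 2^T state paths."""
    T = len(y)
    e1, e2 = log_rates(params, x[:-1], hours[:-1])
    gammas = transition_matrices(np.exp(e1), np.exp(e2))
    logB = np.stack(
        [
            stats.poisson.logpmf(y, params.mu_rest),
            stats.poisson.logpmf(y, params.mu_active),
        ],
        axis=1,
    )
    total = -np.inf
    for path in itertools.product([0, 1], repeat=T):
        lp = np.log(params.delta[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(gammas[t - 1, path[t - 1], path[t]]) + logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


class TestTransitionRates:
    def test_zero_parameters_give_unit_rates(self):
        p = ra.CTHMMParams(0, 0, 0, 0, np.zeros(24), np.zeros(24), 1, 1, 0.05, 5, [0.5, 0.5])
        r = ra.transition_rates(p, x=0.0, hour=3)
        assert r.lambda1 == pytest.approx(1.0)
        assert r.lambda2 == pytest.approx(1.0)

    def test_log_linear_structure(self):
        p = ra.CTHMMParams(np.log(2), 0, 0, 0, np.zeros(24), np.zeros(24), 1, 1, 0.05, 5, [0.5, 0.5])
        assert ra.transition_rates(p, 0.0, 0).lambda1 == pytest.approx(2.0)
        b1 = np.zeros(24)
        b1[7] = -1.0
        p2 = ra.CTHMMParams(0, 1.0, 0, 0, b1, np.zeros(24), 1, 1, 0.05, 5, [0.5, 0.5])
        assert ra.transition_rates(p2, 1.0, 7).lambda1 == pytest.approx(1.0)

    def test_overflow_clamped(self):
        p = ra.CTHMMParams(100, 0, -100, 0, np.zeros(24), np.zeros(24), 1, 1, 0.05, 5, [0.5, 0.5])
        r = ra.transition_rates(p, 0.0, 0)
        assert np.isfinite(r.lambda1) and r.lambda2 > 0

    def test_invalid_hour(self):
        p = ra.CTHMMParams(0, 0, 0, 0, np.zeros(24), np.zeros(24), 1, 1, 0.05, 5, [0.5, 0.5])
        with pytest.raises(ValueError):
            ra.transition_rates(p, 0.0, 24)


class TestTransitionMatrix:
    def test_symmetric_unit_rates(self):
        g = ra.transition_matrix(ra.TransitionRates(1.0, 1.0))
        assert g[0, 0] == pytest.approx((1 + np.exp(-2)) / 2, abs=1e-12)

    def test_vanishing_rates_identity(self):
        g = ra.transition_matrix(ra.TransitionRates(1e-12, 1e-12))
        assert np.allclose(g, np.eye(2), atol=1e-10)

    def test_rows_stochastic(self, rng):
        for _ in range(50):
            l1, l2 = np.exp(rng.uniform(-6, 4, size=2))
            g = ra.transition_matrix(ra.TransitionRates(l1, l2), dt=rng.uniform(0.1, 5))
            assert np.allclose(g.sum(axis=1), 1.0, atol=1e-12)
            assert (g >= 0).all()

    def test_agrees_with_numerical_expm(self, rng):
        for _ in range(100):
            l1, l2 = np.exp(rng.uniform(-6, 4, size=2))
            dt = rng.uniform(0.2, 3)
            q = np.array([[-l1, l1], [l2, -l2]])
            assert np.allclose(
                ra.transition_matrix(ra.TransitionRates(l1, l2), dt),
                linalg.expm(q * dt),
                atol=1e-10,
            )

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            ra.transition_matrix(ra.TransitionRates(1, 1), dt=0)


class TestEmission:
    def test_zero_count_low_mean(self, default_params):
        lp = ra.emission_logpmf(0, REST, default_params)
        assert np.exp(lp) == pytest.approx(np.exp(-0.05))

    def test_pmf_formula(self):
        p = ra.CTHMMParams(0, 0, 0, 0, np.zeros(24), np.zeros(24), 1, 1, 0.05, 2.0, [0.5, 0.5])
        lp = ra.emission_logpmf(3, ACTIVE, p)
        assert np.exp(lp) == pytest.approx(np.exp(-2) * 8 / 6)

    def test_normalization(self, default_params):
        ys = np.arange(0, 200)
        total = np.exp(ra.emission_logpmf(ys, ACTIVE, default_params)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_rejects_negative_counts(self, default_params):
        with pytest.raises(ValueError):
            ra.emission_logpmf(-1, REST, default_params)


class TestSplitSegments:
    def _series_with_gap(self, gap):
        n = 24 * 7
        x = np.ones(n)
        x[50 : 50 + gap] = np.nan
        return make_series(x, np.ones(n, dtype=int))

    def test_long_gap_splits_in_two(self):
        segs = ra.split_segments(self._series_with_gap(30))
        assert len(segs) == 2
        assert sum(len(s) for s in segs) == 24 * 7 - 30

    def test_threshold_is_24_hours(self):
        assert len(ra.split_segments(self._series_with_gap(23))) == 1
        assert len(ra.split_segments(self._series_with_gap(24))) == 2

    def test_no_missing_single_segment(self):
        segs = ra.split_segments(self._series_with_gap(0))
        assert len(segs) == 1 and len(segs[0]) == 24 * 7

    def test_imputed_hours_count_as_originally_missing(self):
        series = self._series_with_gap(30)
        series.data.loc[series.data["X"].isna(), "X"] = 0.5
        series.data.loc[50:79, "imputed"] = True
        assert len(ra.split_segments(series)) == 2


class TestForwardBackward:
    def test_single_step_marginal(self, default_params):
        seg = make_series([1.0], [3])
        gamma, xi, ll = ra.forward_backward(seg, default_params)
        d = default_params.delta
        expected = np.log(
            d[REST] * stats.poisson.pmf(3, default_params.mu_rest)
            + d[ACTIVE] * stats.poisson.pmf(3, default_params.mu_active)
        )
        assert ll == pytest.approx(expected, abs=1e-12)
        assert xi.shape == (0, 2, 2)

    def test_matches_brute_force_enumeration(self, default_params, rng):
        for _ in range(10):
            y = rng.poisson(2, size=6)
            x = rng.lognormal(0, 0.5, size=6)
            seg = make_series(x, y, start_hour=int(rng.integers(0, 24)))
            _, _, ll = ra.forward_backward(seg, default_params)
            hours = seg.data["hour_of_day"].to_numpy()
            expected = brute_force_loglik(y, x, hours, default_params)
            assert ll == pytest.approx(expected, abs=1e-10)

    def test_posteriors_normalized_and_consistent(self, default_params, rng):
        y = rng.poisson(2, size=48)
        x = rng.lognormal(0, 0.5, size=48)
        seg = make_series(x, y)
        gamma, xi, _ = ra.forward_backward(seg, default_params)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        # pairwise posteriors marginalize exactly to the state posteriors
        assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-10)
        assert np.allclose(xi.sum(axis=1), gamma[1:], atol=1e-10)

    def test_missing_x_rejected(self, default_params):
        seg = make_series([1.0, np.nan, 1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            ra.forward_backward(seg, default_params)


class TestMstepGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        T = 40
        x = rng.lognormal(0, 0.5, T)
        hours = rng.integers(0, 24, T)
        xi = rng.dirichlet(np.ones(4), size=T).reshape(T, 2, 2)
        theta = rng.normal(0, 0.3, 52)
        args = (x, hours, xi, 0.8, 1.3)
        f0, g = _transition_objective(theta, *args)
        num = np.empty_like(theta)
        eps = 1e-6
        for i in range(len(theta)):
            tp = theta.copy()
            tp[i] += eps
            tm = theta.copy()
            tm[i] -= eps
            num[i] = (_transition_objective(tp, *args)[0] - _transition_objective(tm, *args)[0]) / (2 * eps)
        assert np.allclose(g, num, atol=1e-5)


class TestExpectedHoldingTime:
    @pytest.mark.parametrize("rate,expected", [(2.0, 0.5), (1.0, 1.0), (0.25, 4.0)])
    def test_reciprocal(self, rate, expected):
        assert ra.expected_holding_time(rate) == expected

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            ra.expected_holding_time(0.0)


class TestEmFit:
    def test_fit_recovers_states_and_canonical_order(self, fitted_participant):
        f = fitted_participant["fitted"]
        assert f.converged
        assert f.params.mu_active > f.params.mu_rest
        states = fitted_participant["states"][f.t_index]
        decoded = (f.state_posteriors > 0.5).astype(int)
        assert (decoded == states).mean() >= 0.9

    def test_objective_trace_monotone(self, fitted_participant):
        steps = np.diff(fitted_participant["fitted"].loglik_trace)
        assert (steps >= -1e-6 * (np.abs(fitted_participant["fitted"].loglik_trace[:-1]) + 1)).all()

    def test_constant_zero_counts_fail_convergence(self):
        n = 24 * 16
        series = make_series(np.full(n, 0.02), np.zeros(n, dtype=int))
        fitted = ra.em_fit(series)
        assert not fitted.converged
        assert "collapse" in fitted.message

    def test_min_hours_enforced(self):
        series = make_series(np.ones(100), np.ones(100, dtype=int))
        with pytest.raises(ra.InsufficientDataError):
            ra.em_fit(series)

    def test_model_json_round_trip(self, fitted_participant, tmp_path):
        f = fitted_participant["fitted"]
        path = tmp_path / "model.json"
        f.to_json(path)
        back = ra.FittedModel.from_json(path)
        assert back.converged == f.converged
        assert back.params.sigma1_sq == pytest.approx(f.params.sigma1_sq)
        assert np.allclose(back.params.b1, f.params.b1)

    def test_beta1_positive_when_truth_positive(self, fitted_participant):
        # accelerometer activity raises the rest-to-active hazard in truth
        assert fitted_participant["fitted"].params.beta1 > 0
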