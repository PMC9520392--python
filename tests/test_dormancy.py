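"""Dormancy HSMM fitting and two-branch accelerometer imputation."""

import numpy as np
import pytest

import rhythmarm as ra
from conftest import make_series


def night_block_missing(n_days=14, night_len=8, seed=0, p_obs_miss=0.0):
    """Missingness indicator: fully-missing nights, observed days."""
    rng = np.random.default_rng(seed)
    day = np.concatenate([np.ones(night_len), np.zeros(24 - night_len)])
    z = np.tile(day, n_days)
    z[(z == 0) & (rng.random(len(z)) < p_obs_miss)] = 1
    return z.astype(int)


class TestFitDormancyHsmm:
    def test_recovers_block_structure(self):
        z = night_block_missing()
        model = ra.fit_dormancy_hsmm(z)
        agree = (model.labels == z).mean()
        assert agree >= 0.95

    def test_noisy_blocks_still_recovered(self):
        # sporadic daytime gaps should not flip day hours to dormant
        z = night_block_missing(p_obs_miss=0.1, seed=3)
        truth = night_block_missing(p_obs_miss=0.0)
        model = ra.fit_dormancy_hsmm(z)
        assert (model.labels == truth).mean() >= 0.9

    def test_canonical_ordering_and_bounds(self):
        model = ra.fit_dormancy_hsmm(night_block_missing(seed=1, p_obs_miss=0.05))
        assert 0.0 <= model.p_miss_active <= model.p_miss_dormant <= 1.0
        assert np.all((model.dwell_params >= 0) & (model.dwell_params <= 1))

    def test_degenerate_all_observed(self):
        with pytest.raises(ra.DegenerateSequenceError):
            ra.fit_dormancy_hsmm(np.zeros(100, dtype=int))

    def test_degenerate_all_missing(self):
        with pytest.raises(ra.DegenerateSequenceError):
            ra.fit_dormancy_hsmm(np.ones(100, dtype=int))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ra.fit_dormancy_hsmm(np.tile([0, 1], 10))

    def test_em_loglik_nondecreasing(self):
        model = ra.fit_dormancy_hsmm(night_block_missing(p_obs_miss=0.08, seed=4))
        steps = np.diff(model.loglik_trace)
        assert (steps >= -1e-8).all()

    def test_loglik_matches_hmmlearn_oracle(self):
        # score our fitted parameters with an independent HMM implementation
        hmm = pytest.importorskip("hmmlearn.hmm")
        z = night_block_missing(p_obs_miss=0.05, seed=2)
        model = ra.fit_dormancy_hsmm(z)
        oracle = hmm.CategoricalHMM(n_components=2, init_params="")
        oracle.startprob_ = model.state_priors
        d0, d1 = model.dwell_params
        oracle.transmat_ = np.array([[d0, 1 - d0], [1 - d1, d1]])
        oracle.emissionprob_ = np.array(
            [[1 - model.p_miss_dormant, model.p_miss_dormant],
             [1 - model.p_miss_active, model.p_miss_active]]
        )
        expected = oracle.score(z.reshape(-1, 1))
        from rhythmarm.dormancy import _forward_backward_bernoulli

        A = oracle.transmat_
        p = np.array([model.p_miss_dormant, model.p_miss_active])
        _, _, ours = _forward_backward_bernoulli(z, model.state_priors, A, p)
        assert ours == pytest.approx(expected, abs=1e-8)


class TestImputeAccelerometer:
    def _series_with_gaps(self, seed=0, n=240):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(0, 0.4, n)
        y = rng.poisson(4, n)
        x[10:20] = np.nan
        return make_series(x, y), rng

    def test_observed_hours_bit_identical(self):
        series, _ = self._series_with_gaps()
        before = series.data["X"].copy()
        labels = np.zeros(len(series), dtype=int)
        model = ra.DormancyModel(0.9, 0.1, np.array([0.9, 0.9]), np.array([0.5, 0.5]), labels)
        out, _ = ra.impute_accelerometer(series, model)
        obs = ~before.isna()
        assert (out.data.loc[obs, "X"].to_numpy() == before[obs].to_numpy()).all()
        assert not out.data.loc[obs, "imputed"].any()
        assert not out.data["X"].isna().any()

    def test_dormant_hours_get_floor_exactly(self):
        series, _ = self._series_with_gaps()
        labels = np.zeros(len(series), dtype=int)
        labels[10:20] = 1
        model = ra.DormancyModel(0.9, 0.1, np.array([0.9, 0.9]), np.array([0.5, 0.5]), labels)
        out, fit = ra.impute_accelerometer(series, model)
        assert (out.data["X"].iloc[10:20] == fit.floor_value).all()

    def test_regression_branch_prediction(self):
        # complete hours lie exactly on X = 0.1 + 0.2 Y; a non-dormant missing
        # hour with Y = 5 must be filled with 1.1
        y = np.array([0, 1, 2, 3, 4, 5, 6, 5])
        x = 0.1 + 0.2 * y.astype(float)
        x[-1] = np.nan
        series = make_series(x, y)
        out, fit = ra.impute_accelerometer(series, None)
        assert fit.slope == pytest.approx(0.2)
        assert fit.intercept == pytest.approx(0.1)
        assert out.data["X"].iloc[-1] == pytest.approx(1.1)

    def test_negative_predictions_clipped_to_floor(self):
        x = np.array([3.0, 2.0, 1.0, 0.1, np.nan])  # steeply decreasing in Y
        series = make_series(x, np.array([0, 10, 20, 30, 40]))
        out, fit = ra.impute_accelerometer(series, None)
        assert out.data["X"].iloc[-1] == fit.floor_value

    def test_floor_below_median(self):
        series, _ = self._series_with_gaps(seed=9)
        out, fit = ra.impute_accelerometer(series, None)
        obs = series.data["X"].dropna()
        assert fit.floor_value <= obs.median()

    def test_too_few_complete_hours(self):
        series = make_series([np.nan, 1.0, np.nan], [1, 2, 3])
        with pytest.raises(ValueError):
            ra.impute_accelerometer(series, None)

    def test_rest_linked_missingness_lands_on_dormant_labels(self):
        # when gaps are generated only during rest, >= 90% of dormant-imputed
        # hours coincide with simulated rest hours
        truth = ra.make_truth(sigma_sq_total=2.0, p_miss_rest=0.6, p_miss_active=0.0)
        series, states = ra.simulate_participant(truth, n_days=14, seed=21)
        miss = np.isnan(series.data["X"].to_numpy())
        model = ra.fit_dormancy_hsmm(miss.astype(int), seed=0)
        out, _ = ra.impute_accelerometer(series, model)
        imputed_dormant = out.data["imputed"].to_numpy() & out.data["dormant"].to_numpy()
        assert imputed_dormant.sum() > 0
        assert (states[imputed_dormant] == 0).mean() >= 0.9
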