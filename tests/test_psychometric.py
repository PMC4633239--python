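"""Cumulative-Gaussian MLE, bootstrap resampling, and condition comparison."""

import numpy as np
import pytest
from scipy.special import ndtr
from sklearn.base import clone

from selfmotion.psychometric import (
    CumulativeGaussianPsychometric,
    ResampleError,
    compare,
    fit_cdf,
    negative_log_likelihood,
    resample,
)

from conftest import grid_search_mle, simulate_staircase_trials


def bernoulli_dataset(mu, sigma, x, rng):
    y = (rng.random(x.size) < ndtr((x - mu) / sigma)).astype(float)
    return x, y


class TestNegativeLogLikelihood:
    def test_single_trial_at_pse_gives_log_two(self):
        assert negative_log_likelihood(0.0, 1.0, 0.0, [0.0], [1]) == pytest.approx(
            np.log(2.0)
        )

    def test_saturated_responses_give_vanishing_nll(self):
        x = np.full(20, 50.0)
        y = np.ones(20)
        assert negative_log_likelihood(0.0, 1.0, 0.0, x, y) < 1e-8

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            negative_log_likelihood(0.0, 1.0, 0.0, [], [])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            negative_log_likelihood(0.0, 0.0, 0.0, [1.0], [1])

    def test_accepts_letter_labels(self):
        a = negative_log_likelihood(0.2, 1.0, 0.0, [0.0, 1.0], ["L", "R"])
        b = negative_log_likelihood(0.2, 1.0, 0.0, [0.0, 1.0], [0, 1])
        assert a == pytest.approx(b)


class TestFit:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_mle_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-4, 4, 40)
        x, y = bernoulli_dataset(0.5, 1.2, x, rng)
        fit = fit_cdf(x, y)
        if fit.degenerate:
            pytest.skip("separable draw")
        mu_g, sigma_g, cell_mu, cell_sigma = grid_search_mle(x, y)
        assert abs(fit.mu - mu_g) <= cell_mu
        assert abs(fit.sigma - sigma_g) <= cell_sigma

    def test_mle_matches_probit_regression(self):
        """Independent cross-check: with zero lapse the fit equals a probit
        GLM with mu = -b0/b1 and sigma = 1/b1."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        x = rng.uniform(-4, 4, 60)
        x, y = bernoulli_dataset(0.3, 1.1, x, rng)
        fit = fit_cdf(x, y)
        probit = sm.Probit(y, np.column_stack([np.ones_like(x), x])).fit(disp=0)
        b0, b1 = probit.params
        assert fit.mu == pytest.approx(-b0 / b1, abs=1e-4)
        assert fit.sigma == pytest.approx(1.0 / b1, abs=1e-4)

    def test_symmetric_responses_give_zero_pse(self):
        x = np.array([-3, -2, -1, 1, 2, 3, -3, -2, -1, 1, 2, 3], float)
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1, 0, 1, 0, 1], float)
        fit = fit_cdf(x, y)
        assert fit.mu == pytest.approx(0.0, abs=1e-6)

    def test_separable_data_flagged_with_gap_midpoint(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        fit = fit_cdf(x, y, sigma_floor=0.01)
        assert fit.degenerate
        assert fit.mu == pytest.approx(0.0)
        assert fit.sigma == pytest.approx(0.01)

    def test_all_identical_responses_flagged_not_raised(self):
        fit = fit_cdf([1.0, 2.0, 3.0], [1, 1, 1])
        assert fit.degenerate

    def test_translation_equivariance(self, rng):
        x = rng.uniform(-4, 4, 50)
        x, y = bernoulli_dataset(0.0, 1.0, x, rng)
        base = fit_cdf(x, y)
        shifted = fit_cdf(x + 5.0, y)
        assert shifted.mu == pytest.approx(base.mu + 5.0, abs=1e-4)
        assert shifted.sigma == pytest.approx(base.sigma, abs=1e-4)

    def test_scale_equivariance(self, rng):
        x = rng.uniform(-4, 4, 50)
        x, y = bernoulli_dataset(0.0, 1.0, x, rng)
        base = fit_cdf(x, y)
        scaled = fit_cdf(3.0 * x, y)
        assert scaled.mu == pytest.approx(3.0 * base.mu, abs=3e-4)
        assert scaled.sigma == pytest.approx(3.0 * base.sigma, abs=3e-4)

    def test_sklearn_estimator_protocol(self):
        est = CumulativeGaussianPsychometric(lapse=0.02, sigma_floor=0.05)
        assert est.get_params()["lapse"] == 0.02
        est2 = clone(est).set_params(lapse=0.0)
        x = np.linspace(-3, 3, 30)
        y = (x > 0.2).astype(int)
        y[::7] = 1 - y[::7]
        est2.fit(x, y)
        proba = est2.predict_proba(np.array([-10.0, est2.mu_, 10.0]))
        assert proba.shape == (3, 2)
        assert proba[1, 1] == pytest.approx(0.5, abs=1e-6)
        assert (est2.predict(np.array([-10.0, 10.0])) == [0, 1]).all()

    def test_lapse_changes_the_fitted_curve_asymptotes(self, rng):
        x = rng.uniform(-4, 4, 200)
        p = 0.05 + 0.9 * ndtr(x / 1.0)
        y = (rng.random(200) < p).astype(float)
        fit = fit_cdf(x, y, lapse=0.1)
        assert fit.sigma > 0
        assert not fit.degenerate


class TestResample:
    def test_single_resample_equals_direct_refit(self, rng):
        x = rng.uniform(-4, 4, 40)
        x, y = bernoulli_dataset(0.0, 1.1, x, rng)
        seed = 123
        dist = resample(x, y, n_resamples=1, rng=np.random.default_rng(seed))
        idx = np.random.default_rng(seed).integers(0, x.size, size=(1, x.size))[0]
        direct = fit_cdf(x[idx], y[idx])
        assert dist.estimates[0] == pytest.approx(direct.mu, abs=1e-4)

    def test_deterministic_under_fixed_seed(self, rng):
        x = rng.uniform(-4, 4, 40)
        x, y = bernoulli_dataset(0.0, 1.1, x, rng)
        d1 = resample(x, y, 100, np.random.default_rng(5))
        d2 = resample(x, y, 100, np.random.default_rng(5))
        assert np.array_equal(d1.estimates, d2.estimates)

    def test_batched_and_scalar_paths_agree(self, rng):
        """The vectorized bootstrap solver is the same MLE as the canonical
        optimizer on every replicate."""
        x = rng.uniform(-4, 4, 30)
        x, y = bernoulli_dataset(0.4, 1.0, x, rng)
        dist = resample(x, y, 50, np.random.default_rng(11))
        idx = np.random.default_rng(11).integers(0, x.size, size=(50, x.size))
        direct = np.array([fit_cdf(x[i], y[i]).mu for i in idx])
        assert np.allclose(dist.estimates, direct, atol=2e-4)

    def test_bootstrap_sd_shrinks_with_sample_size(self, rng):
        """Quadrupling the number of trials roughly halves the bootstrap SD."""
        sds = []
        for n in (40, 160):
            x = rng.uniform(-4, 4, n)
            x, y = bernoulli_dataset(0.0, 1.1, x, rng)
            sds.append(resample(x, y, 500, np.random.default_rng(n)).sd)
        assert sds[1] < 0.75 * sds[0]

    def test_distribution_summary_invariants(self, rng):
        x, y = simulate_staircase_trials(1.0, 1.1, rng)
        dist = resample(x, y, 300, np.random.default_rng(2))
        assert dist.ci_low <= dist.mean <= dist.ci_high
        assert dist.estimates.size + dist.n_failed == 300

    def test_rejects_nonpositive_resample_count(self, rng):
        with pytest.raises(ValueError):
            resample([0.0, 1.0], [0, 1], 0, rng)


class TestCompare:
    def _dist(self, values):
        from selfmotion.psychometric import ResampleDistribution

        return ResampleDistribution(
            estimates=np.asarray(values, float), n_resamples=len(values), confidence=0.95
        )

    def test_identical_distributions_give_null_result(self):
        d = self._dist(np.linspace(-1, 1, 200))
        out = compare(d, d)
        assert out.difference == pytest.approx(0.0)
        assert out.p_two_sided == pytest.approx(1.0)

    def test_disjoint_distributions_hit_continuity_floor(self):
        left = self._dist(np.linspace(0.0, 1.0, 400))
        right = self._dist(np.linspace(5.0, 6.0, 400))
        out = compare(left, right)
        assert out.p_two_sided == pytest.approx(1.0 / 401.0)
        assert out.difference == pytest.approx(-5.0)

    def test_difference_is_mean_left_minus_mean_right(self):
        left = self._dist([1.0, 2.0, 3.0])
        right = self._dist([0.0, 1.0, 2.0])
        out = compare(left, right)
        assert out.difference == pytest.approx(left.mean - right.mean)

    def test_mismatched_lengths_truncate_with_warning(self):
        left = self._dist(np.linspace(0, 1, 100))
        right = self._dist(np.linspace(0, 1, 80))
        with pytest.warns(UserWarning):
            out = compare(left, right)
        assert out.n_pairs == 80
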