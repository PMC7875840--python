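"""Central-tendency observer model: analytic values, identities, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuednum import (
    BayesObserver,
    fit_prior,
    likelihood_weight,
    nonlinearity_vs_noise_curve,
    posterior_mean,
    predict_mapping,
    sigma_r,
)


class TestSigmaR:
    def test_constant_noise_limit(self):
        assert sigma_r(7, 0.3, 0.0) == 0.3
        assert sigma_r(30, 0.3, 0.0) == 0.3

    def test_hand_value(self):
        assert sigma_r(16, 0.15, 0.5) == pytest.approx(0.6, abs=1e-12)

    def test_weber_regime_constant_cv(self):
        n = np.array([5.0, 10.0, 30.0])
        assert np.allclose(sigma_r(n, 0.2, 1.0) / n, 0.2)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sigma_r(0.5, 0.2, 0.5)
        with pytest.raises(ValueError):
            sigma_r(10, -1.0, 0.5)


class TestPosteriorMean:
    def test_coincident_centres(self):
        for sd in (0.1, 3.0, 100.0):
            assert posterior_mean(15, 15, 5, sd) == 15.0

    def test_fig5_parameters(self):
        # prior (15, 5), likelihood SD 3: (15*9 + 5*25)/(9 + 25) = 260/34
        assert posterior_mean(5, 15, 5, 3) == pytest.approx(260 / 34, abs=1e-12)

    def test_noiseless_likelihood_dominates(self):
        assert posterior_mean(30, 15, 5, 0.0) == 30.0

    def test_flat_likelihood_approaches_prior(self):
        assert posterior_mean(30, 15, 5, 1e6) == pytest.approx(15.0, abs=1e-6)

    def test_double_degenerate_is_error(self):
        with pytest.raises(ValueError):
            posterior_mean(5, 15, 0.0, 0.0)

    def test_shrinkage_monotone_in_sensory_noise(self):
        """More sensory noise pulls the estimate strictly closer to the prior."""
        dists = [abs(posterior_mean(25, 15, 5, s) - 15) for s in (0.5, 1, 2, 4, 8)]
        assert all(a > b for a, b in zip(dists, dists[1:]))


class TestLikelihoodWeight:
    def test_perfect_evidence(self):
        assert likelihood_weight(10, 0.0, 5.0) == 1.0

    def test_flat_prior_limit(self):
        assert likelihood_weight(10, 0.3, 1e9) == pytest.approx(1.0, abs=1e-9)

    def test_hand_value(self):
        assert likelihood_weight(15, 0.2, 5.0) == pytest.approx(25 / 34, abs=1e-12)

    def test_non_increasing_in_magnitude(self):
        x = np.linspace(1, 35, 50)
        w = likelihood_weight(x, 0.25, 17.0)
        assert np.all(np.diff(w) <= 0)
        assert np.all((w > 0) & (w <= 1))

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        x=st.floats(1.0, 35.0),
        wf=st.floats(0.0, 2.0),
        prior_sd=st.floats(0.1, 50.0),
        prior_mean=st.floats(1.0, 35.0),
    )
    def test_consistency_with_posterior_mean(self, x, wf, prior_sd, prior_mean):
        """W_L*x + (1-W_L)*P̄ equals the posterior mean with sigma_R = x*WF."""
        w = likelihood_weight(x, wf, prior_sd)
        lhs = posterior_mean(x, prior_mean, prior_sd, x * wf)
        assert lhs == pytest.approx(w * x + (1 - w) * prior_mean, abs=1e-12)


class TestPredictMapping:
    def test_constant_noise_values(self):
        obs = BayesObserver(
            prior_mean=15, prior_sd=5, noise_k=3, noise_exponent=0.0,
            response_jitter_sd=0.0,
        )
        pred = predict_mapping(obs, [5, 15, 30])
        assert pred.predicted_response[0] == pytest.approx(260 / 34, abs=1e-12)
        assert pred.predicted_response[1] == pytest.approx(15.0, abs=1e-12)
        assert pred.predicted_response[2] == pytest.approx((15 * 9 + 30 * 25) / 34, abs=1e-12)

    def test_shrinkage_bracketing(self):
        obs = BayesObserver()
        pred = predict_mapping(obs, np.arange(5, 31))
        n = pred.numerosities
        r = pred.predicted_response
        inside = n != obs.prior_mean
        assert np.all(r[inside] > np.minimum(n, obs.prior_mean)[inside])
        assert np.all(r[inside] < np.maximum(n, obs.prior_mean)[inside])
        assert r[n == 15][0] == pytest.approx(15.0)

    def test_monotone_increasing_over_default_ranges(self):
        for k in (0.3, 0.5, 1.0, 2.0):
            for a in (0.0, 0.5, 1.0):
                obs = BayesObserver(noise_k=k, noise_exponent=a, response_jitter_sd=0.0)
                pred = predict_mapping(obs, np.arange(5, 31))
                assert np.all(np.diff(pred.predicted_response) > 0), (k, a)

    def test_empty_numerosities_rejected(self):
        with pytest.raises(ValueError):
            predict_mapping(BayesObserver(), [])


class TestFitPrior:
    def _mapping_data(self, prior_sd, noise_k=0.8, noise_exponent=0.5):
        obs = BayesObserver(
            prior_mean=15, prior_sd=prior_sd, noise_k=noise_k,
            noise_exponent=noise_exponent, response_jitter_sd=0.0,
        )
        n = np.arange(5, 31, dtype=float)
        pred = predict_mapping(obs, n)
        return dict(zip(n, pred.predicted_response)), (noise_k, noise_exponent)

    @pytest.mark.parametrize("true_sd", [3.0, 5.0, 10.0])
    def test_self_consistency_recovery(self, true_sd):
        data, spec = self._mapping_data(true_sd)
        obs, r2 = fit_prior(data, spec)
        assert obs.prior_sd == pytest.approx(true_sd, abs=0.25)
        assert r2 > 0.999

    def test_identity_data_pegs_prior_wide(self):
        n = np.arange(5, 31, dtype=float)
        obs, r2 = fit_prior(dict(zip(n, n)), (0.8, 0.5), prior_sd_bounds=(0.1, 100.0))
        assert obs.prior_sd == pytest.approx(100.0, rel=0.01)
        assert r2 > 0.999

    def test_matches_fine_grid_search(self):
        """1-D optimizer optimum agrees with 0.01-resolution brute force."""
        data, spec = self._mapping_data(5.0)
        # perturb so the optimum is not exactly the generator value
        data = {k: v + 0.3 * np.sin(k) for k, v in data.items()}
        n = np.array(sorted(data))
        r = np.array([data[k] for k in n])
        s_r = spec[0] * n ** spec[1]
        grid = np.arange(0.5, 30.0, 0.01)
        rss = [
            np.sum((r - posterior_mean(n, 15.0, sd, s_r)) ** 2) for sd in grid
        ]
        best_grid = grid[int(np.argmin(rss))]
        obs, _ = fit_prior(data, spec)
        assert abs(obs.prior_sd - best_grid) <= 0.01 + 1e-9

    def test_degenerate_data_rejected(self):
        n = np.arange(5, 31, dtype=float)
        with pytest.raises(ValueError):
            fit_prior(dict(zip(n, np.full_like(n, 15.0))), (0.8, 0.5))
        with pytest.raises(ValueError):
            fit_prior({5.0: 6.0, 10.0: 10.0, 15.0: 14.0}, (0.8, 0.5))  # < 4 points

    def test_prior_mean_modes(self):
        data, spec = self._mapping_data(5.0)
        mid, _ = fit_prior(data, spec, prior_mean_mode="fixed_midpoint")
        assert mid.prior_mean == 17.5
        free, _ = fit_prior(data, spec, prior_mean_mode="free")
        assert free.prior_mean == pytest.approx(15.0, abs=0.5)
        with pytest.raises(ValueError):
            fit_prior(data, spec, prior_mean_mode="bogus")


class TestNonlinearityNoiseCurve:
    def test_noiseless_limit(self):
        curve = nonlinearity_vs_noise_curve(
            17.0, [1e-9], np.arange(5, 31), n_sim=100, seed=0
        )
        noise, exponent = curve[0]
        assert noise == pytest.approx(0.0, abs=1e-6)
        assert exponent == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_exponent_decreases_with_weber_fraction(self, seed):
        from scipy.stats import spearmanr

        grid = np.arange(0.05, 0.55, 0.1)
        curve = nonlinearity_vs_noise_curve(
            17.0, grid, np.arange(5, 31), n_sim=300, seed=seed
        )
        rho, _ = spearmanr(grid, [c[1] for c in curve])
        assert rho <= 0

    def test_prior_sd_17_curve_is_compressive(self):
        grid = np.arange(0.1, 0.55, 0.1)
        curve = nonlinearity_vs_noise_curve(
            17.0, grid, np.arange(5, 31), n_sim=400, seed=1
        )
        assert all(c[1] < 1.0 for c in curve)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nonlinearity_vs_noise_curve(17.0, [-0.1], np.arange(5, 31), n_sim=100)
        with pytest.raises(ValueError):
            nonlinearity_vs_noise_curve(17.0, [0.1], np.arange(5, 31), n_sim=10)
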