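"""Variational-Laplace inversion: objective, recovery, determinism."""

import numpy as np
import pytest

from gammadcm.microcircuit import ConfigurationError, default_parameters
from gammadcm.spectral import PowerSpectrum, predict_spectrum
from gammadcm.inversion import (
    DEFAULT_FREE_NAMES,
    PriorSpec,
    Posterior,
    SpectralDCM,
    apply_theta,
    free_energy,
    invert,
)


class TestPriorSpec:
    def test_default_free_set(self):
        pri = PriorSpec()
        couplings = [n for n in pri.names if n.startswith("g") and n[1:].isdigit()]
        assert couplings == ["g4", "g5", "g6", "g7", "g8", "g9", "g11", "g12"]
        assert {"input_alpha", "input_beta", "noise_alpha", "noise_beta",
                "obs_gain"} <= set(pri.names)

    def test_default_variances(self):
        pri = PriorSpec()
        v = dict(zip(pri.names, pri.variance))
        assert v["g4"] == pytest.approx(1 / 16)
        assert v["obs_gain"] == pytest.approx(1 / 8)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            PriorSpec(names=("g13",))
        with pytest.raises(ConfigurationError):
            PriorSpec(names=("g4",), variance=np.array([0.0]))


class TestApplyTheta:
    def test_coupling_and_scale_semantics(self, prior_params):
        pri = PriorSpec(names=("g4", "obs_gain"))
        p = apply_theta(prior_params, pri.names, np.array([0.3, np.log(2.0)]))
        assert p.gamma[3] == pytest.approx(0.3)
        assert p.obs_gain == pytest.approx(2.0 * prior_params.obs_gain)


class TestFreeEnergy:
    def test_maximal_at_generator(self, prior_spectrum, prior_params):
        pri = PriorSpec()
        theta0 = np.zeros(len(pri.names))
        f0 = free_energy(prior_spectrum, theta0, pri)
        for j in (0, 6, 8):
            th = theta0.copy()
            th[j] = 0.2
            assert free_energy(prior_spectrum, th, pri) < f0

    def test_matches_independent_evaluation(self, prior_params):
        # evaluate the documented objective by hand on a perturbed fixture
        pri = PriorSpec()
        p = default_parameters({"g4": -0.2})
        obs = predict_spectrum(p)
        theta = np.zeros(len(pri.names))
        theta[0] = -0.1
        model = SpectralDCM(obs, pri)
        m = model.predict_log_power(theta)
        r = np.log(obs.power) - m
        n = len(r)
        lam = (pri.noise_shape + 0.5 * n) / (pri.noise_rate + 0.5 * r @ r)
        expected = (-0.5 * lam * r @ r + 0.5 * n * np.log(lam / (2 * np.pi))
                    - 0.5 * theta @ pri.precision @ theta)
        assert free_energy(obs, theta, pri) == pytest.approx(expected, rel=1e-12)

    def test_unstable_point_returns_minus_inf(self, prior_spectrum):
        pri = PriorSpec(names=("g3", "g9"))
        assert free_energy(prior_spectrum, np.array([3.0, 3.0]), pri) == -np.inf


class TestInvert:
    def test_noiseless_prior_data_recovers_prior(self, prior_spectrum):
        post = invert(prior_spectrum)
        assert np.max(np.abs(post.mean)) < 0.05
        assert post.converged

    def test_recovers_single_perturbed_coupling(self, prior_params):
        # high-SNR spectra generated with gamma_4 = -0.4, all others at prior
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(10):
            p = default_parameters({"g4": -0.4})
            obs = predict_spectrum(p)
            noisy = PowerSpectrum(
                obs.freqs, obs.power * np.exp(rng.normal(0, 0.05, len(obs))),
                {"kind": "synthetic"})
            post = invert(noisy)
            g4 = post.mean[list(post.names).index("g4")]
            hits += abs(g4 - (-0.4)) < 0.15
        assert hits >= 8

    def test_deterministic_given_inputs(self, prior_params):
        p = default_parameters({"g11": 0.25})
        obs = predict_spectrum(p)
        a = invert(obs, seed=1)
        b = invert(obs, seed=1)
        assert np.array_equal(a.mean, b.mean)
        assert a.free_energy == b.free_energy

    def test_fit_improves_on_prior_start(self, prior_params):
        pri = PriorSpec()
        p = default_parameters({"g9": 0.3, "g4": -0.3})
        obs = predict_spectrum(p)
        model = SpectralDCM(obs, pri)
        res = model.fit()
        n = len(obs)
        lam = res.posterior.noise_precision
        f_start = model._objective(np.zeros(len(pri.names)), lam)
        f_end = model._objective(res.posterior.mean, lam)
        assert f_end > f_start

    def test_posterior_covariance_is_symmetric_psd(self, prior_spectrum):
        post = invert(prior_spectrum)
        assert np.allclose(post.cov, post.cov.T)
        assert np.min(np.linalg.eigvalsh(post.cov)) > 0

    def test_nonpositive_power_rejected(self, grid):
        spec = PowerSpectrum(grid, np.r_[0.0, np.ones(len(grid) - 1)])
        with pytest.raises(ConfigurationError):
            SpectralDCM(spec)


class TestModelComparison:
    def test_generating_free_set_beats_wrong_free_set(self):
        # the free-energy bound should prefer the free set that actually
        # generated the data over a deliberately wrong one (only G10 free)
        rng = np.random.default_rng(11)
        wins = 0
        n_rep = 5
        for i in range(n_rep):
            p = default_parameters()
            p.gamma[[3, 8, 10]] = rng.normal(0, 0.25, 3)
            obs = predict_spectrum(p)
            noisy = PowerSpectrum(
                obs.freqs, obs.power * np.exp(rng.normal(0, 0.05, len(obs))),
                {"kind": "synthetic"})
            f_true = invert(noisy).free_energy
            f_wrong = invert(noisy, PriorSpec(
                names=("g10", "input_alpha", "input_beta", "noise_alpha",
                       "noise_beta", "obs_gain"))).free_energy
            wins += f_true > f_wrong
        assert wins >= 0.8 * n_rep


class TestResultsApi:
    def test_summary_and_serialization(self, prior_spectrum):
        res = SpectralDCM(prior_spectrum).fit()
        text = res.summary()
        assert "free energy" in text and "g4" in text
        back = Posterior.from_json(res.posterior.to_json())
        assert np.allclose(back.mean, res.posterior.mean)
        assert back.names == res.posterior.names

    def test_predicted_spectrum_matches_observation_shape(self, prior_spectrum):
        res = SpectralDCM(prior_spectrum).fit()
        pred = res.predicted_spectrum()
        assert len(pred) == len(prior_spectrum)
        assert np.all(pred.power > 0)
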