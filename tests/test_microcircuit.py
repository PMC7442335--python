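"""Microcircuit dynamics: edge table, sigmoid, derivatives, integration."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from gammadcm.microcircuit import (
    CMCParameters,
    ConfigurationError,
    DEFAULT_EDGES,
    Edge,
    EdgeTable,
    InstabilityError,
    default_parameters,
    firing_rate,
    firing_rate_gain,
    integrate,
    state_derivative,
)
from gammadcm.spectral import fixed_point

from conftest import draw_stable_params


class TestEdgeTable:
    def test_named_edges_match_their_roles(self):
        by_index = {e.index: e for e in DEFAULT_EDGES}
        assert (by_index[4].source, by_index[4].target, by_index[4].sign) == ("II", "II", -1)
        assert (by_index[6].source, by_index[6].target, by_index[6].sign) == ("DP", "II", +1)
        assert (by_index[7].source, by_index[7].target, by_index[7].sign) == ("SP", "SP", -1)
        assert (by_index[11].source, by_index[11].target, by_index[11].sign) == ("II", "SP", -1)

    def test_all_twelve_indices_present_and_self_edges_inhibitory(self):
        assert sorted(e.index for e in DEFAULT_EDGES) == list(range(1, 13))
        for e in DEFAULT_EDGES:
            if e.source == e.target:
                assert e.sign == -1

    def test_duplicate_or_missing_indices_rejected(self):
        edges = [Edge("SS", "SP", 1, k, 1.0) for k in range(1, 12)]
        with pytest.raises(ConfigurationError):
            EdgeTable(edges)

    def test_excitatory_self_edge_rejected(self):
        edges = list(DEFAULT_EDGES.edges)
        edges[0] = Edge("SS", "SS", +1, 1, 8.0)
        with pytest.raises(ConfigurationError):
            EdgeTable(edges)

    def test_json_round_trip(self):
        restored = EdgeTable.from_json(DEFAULT_EDGES.to_json())
        assert restored == DEFAULT_EDGES


class TestParameters:
    def test_defaults_are_identity_scalings(self):
        p = default_parameters()
        assert np.all(p.gamma == 0)
        assert np.allclose(p.coupling, p.edges.gbar)

    def test_override_scales_coupling_exponentially(self):
        p = default_parameters({"gamma_4": 0.3})
        assert p.coupling[3] == pytest.approx(p.edges.gbar[3] * np.exp(0.3))

    def test_default_free_set_has_eight_couplings(self):
        from gammadcm.microcircuit import DEFAULT_FREE_COUPLINGS

        assert len(DEFAULT_FREE_COUPLINGS) == 8
        assert set(DEFAULT_FREE_COUPLINGS) == {4, 5, 6, 7, 8, 9, 11, 12}

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            default_parameters({"gamma_13": 0.1})
        with pytest.raises(ConfigurationError):
            default_parameters({"not_a_param": 1.0})

    def test_json_round_trip_full_precision(self, rng):
        p = draw_stable_params(rng)
        p.input_alpha = 1.2345678901234567
        q = CMCParameters.from_json(p.to_json())
        assert np.array_equal(q.gamma, p.gamma)
        assert q.input_alpha == p.input_alpha
        assert q.edges == p.edges


class TestFiringRate:
    def test_rest_centred(self):
        assert firing_rate(0.0) == 0.0

    def test_saturation_bounds(self):
        assert firing_rate(1e3) == pytest.approx(0.5)
        assert firing_rate(-1e3) == pytest.approx(-0.5)

    def test_matches_documented_closed_form(self):
        # logistic with resting value subtracted, evaluated independently
        v, slope = 1.0, 2.0
        expected = 1.0 / (1.0 + np.exp(-slope * v)) - 0.5
        assert firing_rate(v, slope) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert firing_rate(lo) <= firing_rate(hi)

    def test_gain_is_derivative(self):
        v = 0.7
        h = 1e-6
        fd = (firing_rate(v + h) - firing_rate(v - h)) / (2 * h)
        assert firing_rate_gain(v) == pytest.approx(fd, rel=1e-6)


class TestStateDerivative:
    def test_rest_is_fixed_point(self, prior_params):
        assert np.all(state_derivative(np.zeros(8), prior_params) == 0)

    def test_drive_enters_spiny_stellate_only(self, prior_params):
        p = prior_params.copy()
        p.gamma[:] = -50.0          # effectively zero all couplings
        dx = state_derivative(np.zeros(8), p, drive=1.0)
        # only the SS current equation moves
        assert dx[4] != 0
        assert np.allclose(np.delete(dx, 4), 0.0, atol=1e-10)

    def test_matches_independent_rhs(self, rng, prior_params):
        # independent transcription of the second-order synaptic kernel
        def rhs(x, p, drive):
            v, i = x[:4], x[4:]
            kappa = p.kappa
            u = np.zeros(4)
            pops = {"SS": 0, "SP": 1, "II": 2, "DP": 3}
            for e in p.edges:
                s = expit(p.slope * v[pops[e.source]]) - 0.5
                u[pops[e.target]] += e.sign * e.gbar * np.exp(p.gamma[e.index - 1]) * s
            u[0] += drive
            return np.r_[i, kappa * (u - 2 * i) - kappa**2 * v]

        for _ in range(5):
            x = rng.normal(0, 1, 8)
            assert np.allclose(state_derivative(x, prior_params, 0.3),
                               rhs(x, prior_params, 0.3), rtol=1e-12)

    def test_nonfinite_state_raises(self, prior_params):
        x = np.zeros(8)
        x[0] = np.nan
        with pytest.raises(FloatingPointError):
            state_derivative(x, prior_params)


class TestInhibitionSignRespect:
    def test_more_inhibition_never_raises_target_firing(self, prior_params):
        # G4 is the inhibitory self-connection of the interneurons; under
        # constant positive drive, scaling it up must not raise II firing.
        rates = []
        for g in np.linspace(-1.0, 1.0, 9):
            p = prior_params.copy()
            p.gamma[3] = g
            state = fixed_point(p, drive_mean=0.05)
            rates.append(firing_rate(state[2], p.slope))
        assert np.all(np.diff(rates) <= 1e-12)


class TestIntegrate:
    def test_zero_drive_stays_at_rest(self, prior_params):
        v = integrate(prior_params, None, dt=1e-3, duration=1.0)
        assert np.allclose(v, 0.0)

    def test_same_seed_identical(self, prior_params):
        a = integrate(prior_params, "scale_free", dt=1e-3, duration=1.0, seed=42)
        b = integrate(prior_params, "scale_free", dt=1e-3, duration=1.0, seed=42)
        assert np.array_equal(a, b)

    def test_instability_reported_with_parameters(self, prior_params):
        # the saturating sigmoid bounds coupling-driven activity, so the
        # divergence guard is exercised with a pathological drive
        with pytest.raises(InstabilityError, match="gamma"):
            integrate(prior_params, 5e5, dt=5e-4, duration=1.0)

    def test_preconditions(self, prior_params):
        with pytest.raises(ConfigurationError):
            integrate(prior_params, None, dt=2e-3, duration=1.0)
        with pytest.raises(ConfigurationError):
            integrate(prior_params, None, dt=1e-3, duration=0.5)

    def test_fixed_point_input_stays_stationary(self, prior_params):
        state = fixed_point(prior_params, drive_mean=0.05)
        v = integrate(prior_params, 0.05, dt=1e-3, duration=1.0,
                      initial_state=state)
        assert np.allclose(v, state[:4], atol=1e-6)
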