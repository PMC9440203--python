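"""Unit tests for the sigmoid, synaptic kernel, summation and model assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btcmodel.model_core import (
    EXCITATORY,
    INHIBITORY,
    ModelValidationError,
    ModelState,
    POPULATION_ORDER,
    SigmoidParams,
    SynapticKinetics,
    TOPOLOGY,
    build_btc_model,
    connectivity_key,
    drift,
    membrane_potential,
    psp_derivatives,
    sigmoid,
)

SIG = SigmoidParams(e0=2.5, v0=6.0, sigma=0.56)


class TestSigmoid:
    def test_threshold_gives_half_maximum(self):
        assert sigmoid(SIG.v0, SIG) == pytest.approx(SIG.e0)

    def test_saturation_limits(self):
        assert sigmoid(1e6, SIG) == pytest.approx(2 * SIG.e0)
        assert sigmoid(-1e6, SIG) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_at_ln3_over_sigma(self):
        # 2e0 / (1 + exp(-ln 3)) = 2e0 / (4/3) = 1.5 e0
        v = SIG.v0 + math.log(3.0) / SIG.sigma
        assert sigmoid(v, SIG) == pytest.approx(1.5 * SIG.e0, rel=1e-12)

    def test_rejects_non_finite_potential(self):
        with pytest.raises(FloatingPointError):
            sigmoid(float("nan"), SIG)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        e0=st.floats(0.1, 50.0),
        v0=st.floats(-20.0, 20.0),
        sigma=st.floats(0.05, 5.0),
        v=st.floats(-100.0, 100.0),
        dv=st.floats(1e-3, 10.0),
    )
    def test_monotone_and_bounded(self, e0, v0, sigma, v, dv):
        p = SigmoidParams(e0=e0, v0=v0, sigma=sigma)
        lo, hi = sigmoid(v, p), sigmoid(v + dv, p)
        assert 0.0 <= lo <= hi <= 2 * e0
        if abs(sigma * (v0 - v)) < 30 and abs(sigma * (v0 - v - dv)) < 30:
            assert lo < hi  # strictly increasing away from float saturation
        assert sigmoid(v0, p) == pytest.approx(e0, rel=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ModelValidationError):
            SigmoidParams(e0=-1.0, v0=6.0, sigma=0.56)
        with pytest.raises(ModelValidationError):
            SigmoidParams(e0=2.5, v0=6.0, sigma=0.0)


class TestMembranePotential:
    def test_zero_psps_give_zero(self, model):
        psp = {p: 0.0 for p in POPULATION_ORDER}
        assert membrane_potential("t", psp, model.connectivity) == 0.0

    def test_single_excitatory_edge_is_linear(self, model):
        conn = model.connectivity
        psp = {p: 0.0 for p in POPULATION_ORDER}
        psp["d"] = 1.0
        assert membrane_potential("t", psp, conn) == pytest.approx(conn.weight("t", "d"))
        psp["d"] = 2.5
        assert membrane_potential("t", psp, conn) == pytest.approx(2.5 * conn.weight("t", "d"))

    def test_signed_summation(self, model):
        conn = model.connectivity
        psp = {p: 0.0 for p in POPULATION_ORDER}
        psp["d"], psp["i"] = 1.0, 1.0  # PNN excites TRC, IN inhibits it
        expected = conn.weight("t", "d") - conn.weight("t", "i")
        assert membrane_potential("t", psp, conn) == pytest.approx(expected)

    def test_missing_source_raises(self, model):
        with pytest.raises(KeyError):
            membrane_potential("t", {"d": 1.0}, model.connectivity)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(-5.0, 5.0), x=st.floats(-3.0, 3.0))
    def test_linearity_in_each_input(self, model, scale, x):
        conn = model.connectivity
        base = {p: 0.7 for p in POPULATION_ORDER}
        v0 = membrane_potential("t", base, conn)
        bumped = dict(base)
        bumped["n"] = base["n"] + scale * x
        v1 = membrane_potential("t", bumped, conn)
        # TRN -> TRC is inhibitory: response is -weight * delta
        assert v1 - v0 == pytest.approx(-conn.weight("t", "n") * scale * x, abs=1e-9)


class TestPspKinetics:
    K = SynapticKinetics(gain=3.25, tau=0.01)

    def test_rest_is_fixed_point(self):
        assert psp_derivatives(0.0, 0.0, 0.0, self.K) == (0.0, 0.0)

    def test_steady_state_under_constant_rate(self):
        phi = 4.0
        x_star = self.K.gain * self.K.tau * phi
        dx, dy = psp_derivatives(x_star, 0.0, phi, self.K)
        assert dx == 0.0
        assert dy == pytest.approx(0.0, abs=1e-12)

    def test_impulse_response_matches_alpha_function(self):
        # analytic solution from rest with a unit rate impulse:
        # x(t) = (A / tau) * t * exp(-t / tau), peak A/e at t = tau
        k = self.K
        dt = 1e-4
        steps = int(5 * k.tau / dt)
        x, y = 0.0, k.gain / k.tau  # impulse sets the derivative
        ts, xs = [0.0], [0.0]

        def f(state):
            return np.array(psp_derivatives(state[0], state[1], 0.0, k))

        s = np.array([x, y])
        for i in range(steps):
            k1 = f(s)
            k2 = f(s + 0.5 * dt * k1)
            k3 = f(s + 0.5 * dt * k2)
            k4 = f(s + dt * k3)
            s = s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            ts.append((i + 1) * dt)
            xs.append(s[0])
        ts, xs = np.array(ts), np.array(xs)
        analytic = (k.gain / k.tau) * ts * np.exp(-ts / k.tau)
        mask = analytic > 1e-3 * analytic.max()
        rel = np.abs(xs[mask] - analytic[mask]) / analytic.max()
        assert rel.max() < 1e-3
        # peak value A * e^-1 at t = tau
        i_pk = int(np.argmax(xs))
        assert ts[i_pk] == pytest.approx(k.tau, rel=1e-2)
        assert xs[i_pk] == pytest.approx(k.gain * math.exp(-1.0), rel=1e-3)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ModelValidationError):
            SynapticKinetics(gain=3.25, tau=0.0)


class TestBuildModel:
    def test_default_topology_has_32_signed_edges(self, model):
        assert len(TOPOLOGY) == 32
        signs = list(TOPOLOGY.values())
        assert signs.count(EXCITATORY) == 22
        assert signs.count(INHIBITORY) == 10
        assert set(model.connectivity.weights) == set(TOPOLOGY)

    def test_cholinergic_pnn_edge_signs(self, model):
        conn = model.connectivity
        # M1/M3 excitatory to relay nucleus; M2 inhibitory to IN and TRN
        assert conn.sign("t", "d") == EXCITATORY
        assert conn.sign("i", "d") == INHIBITORY
        assert conn.sign("n", "d") == INHIBITORY
        outgoing = [(t, s) for (t, s) in TOPOLOGY if s == "d"]
        assert sorted(outgoing) == [("i", "d"), ("n", "d"), ("s", "d"), ("t", "d")]

    def test_edge_outside_topology_rejected(self, config):
        bad = {k: dict(v) if isinstance(v, dict) else v for k, v in config.items()}
        bad["connectivity"] = dict(config["connectivity"])
        bad["connectivity"]["C_pni"] = 10.0  # TRN -> PY does not exist
        with pytest.raises(ModelValidationError):
            build_btc_model(bad)

    def test_negative_weight_rejected(self, config):
        bad = {k: dict(v) if isinstance(v, dict) else v for k, v in config.items()}
        bad["connectivity"] = dict(config["connectivity"])
        bad["connectivity"]["C_tde"] = -1.0
        with pytest.raises(ModelValidationError):
            build_btc_model(bad)

    def test_missing_edge_rejected(self, config):
        bad = {k: dict(v) if isinstance(v, dict) else v for k, v in config.items()}
        bad["connectivity"] = dict(config["connectivity"])
        del bad["connectivity"]["C_tde"]
        with pytest.raises(ModelValidationError, match="C_tde"):
            build_btc_model(bad)

    def test_unknown_population_rejected(self, config):
        bad = dict(config)
        bad["populations"] = dict(config["populations"])
        bad["populations"]["z"] = {"gain": 1.0, "tau": 0.01}
        with pytest.raises(ModelValidationError):
            build_btc_model(bad)

    def test_connectivity_key_roundtrip(self):
        assert connectivity_key("t", "d") == "C_tde"
        assert connectivity_key("i", "d") == "C_idi"
        assert connectivity_key("n", "d") == "C_ndi"
        assert connectivity_key("d", "p") == "C_dpe"
        with pytest.raises(ModelValidationError):
            connectivity_key("p", "n")  # TRN -> PY not in topology


class TestDrift:
    def test_x_derivative_equals_y(self, model):
        rng = np.random.default_rng(0)
        state = ModelState(x=rng.normal(size=11), y=rng.normal(size=11))
        d = drift(state, 11.0, 220.0, model)
        np.testing.assert_array_equal(d.x, state.y)

    def test_near_rest_with_high_threshold(self, config):
        cfg = {k: dict(v) if isinstance(v, dict) else v for k, v in config.items()}
        cfg["sigmoid"] = {"e0": 2.5, "v0": 60.0, "sigma": 0.56}
        m = build_btc_model(cfg)
        d = drift(ModelState(), 0.0, 0.0, m)
        assert np.abs(d.x).max() == 0.0
        assert np.abs(d.y).max() < 1e-9

    def test_decoupled_noise_channels_reach_a_tau_mu(self, config):
        # all weights zero, constant noise at the means: each noise-driven
        # channel settles at x* = A * tau * mu
        cfg = {k: dict(v) if isinstance(v, dict) else v for k, v in config.items()}
        cfg["connectivity"] = {k: 0.0 for k in config["connectivity"]}
        cfg["sigmoid"] = {"e0": 2.5, "v0": 60.0, "sigma": 0.56}  # neural channels silent
        m = build_btc_model(cfg)
        mu1, mu2 = m.noise.mu1, m.noise.mu2
        state = ModelState()
        dt = 1e-4  # 0.3 s = 30 kernel time constants: fully settled
        for _ in range(3000):
            d = drift(state, mu1, mu2, m)
            state = ModelState(x=state.x + dt * d.x, y=state.y + dt * d.y)
        gains, taus = m.kinetics_arrays()
        idx = m.index
        for pid, mu in (("r", mu1), ("c", mu2)):
            i = idx[pid]
            assert state.x[i] == pytest.approx(gains[i] * taus[i] * mu, rel=1e-3)
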