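import numpy as np
import pytest

from conftest import benettin_flow_lle, scalar_weights
from driftcast.lyapunov import lle_flow, lle_map, lle_profile, reservoir_jacobian
from driftcast.model import TrainedModel
from driftcast.readout import Readout
from driftcast.reservoir import FastReservoirConfig, init_fast_reservoir
from driftcast.systems import SystemSpec


def fake_model(W, w_in, w_out, b=0.0, b_out=0.0, w_param=0.0, leak=0.8,
               n=1):
    """Minimal TrainedModel carrying only what the LLE machinery touches."""
    weights = scalar_weights("fast", 0, 0, 0, 0, leak=leak)
    weights.W = np.atleast_2d(np.asarray(W, dtype=float))
    weights.w_in = np.full(n, w_in, dtype=float) if np.isscalar(w_in) else np.asarray(w_in)
    weights.w_param = (np.full(n, w_param, dtype=float) if np.isscalar(w_param)
                       else np.asarray(w_param))
    weights.b = np.full(n, b, dtype=float) if np.isscalar(b) else np.asarray(b)
    readout = Readout(
        w_out=np.full(n, w_out, dtype=float) if np.isscalar(w_out) else np.asarray(w_out),
        b_out=b_out, beta=0.0)
    return TrainedModel(
        slow_cfg=None, fast_cfg=None, sdp_cfg=None, train_cfg=None,
        slow_weights=None, fast_weights=weights, sdp_weights=None,
        slow_nodes=None, scores=None, u_tilde=None, h=None,
        fast_readout=readout, sdp_readout=None,
        u_fast_end=np.zeros(weights.n_nodes), u_sdp_end=None,
        beta=0.0, y_train_ptp=0.0)


class TestJacobian:
    def test_zero_weights_literal_and_leaky_limits(self):
        m = fake_model(W=[[0.0]], w_in=0.0, w_out=0.0, leak=0.8)
        J_lit = reservoir_jacobian(m.fast_weights, m.fast_readout,
                                   np.zeros(1), 0.0, literal_no_leak=True)
        assert J_lit[0, 0] == 0.0
        J = reservoir_jacobian(m.fast_weights, m.fast_readout, np.zeros(1), 0.0)
        assert J[0, 0] == pytest.approx(0.8)

    def test_scalar_hand_derivative(self):
        W, win, wout, bout, b, ifast, wp = 0.7, 0.4, 1.3, 0.2, 0.1, 0.5, 0.6
        u = np.array([0.3])
        m = fake_model(W=[[W]], w_in=win, w_out=wout, b=b, b_out=bout, w_param=wp)
        r = W * u[0] + win * (wout * u[0] + bout) + wp * ifast + b
        expected_lit = (1 - np.tanh(r) ** 2) * (W + win * wout)
        J = reservoir_jacobian(m.fast_weights, m.fast_readout, u, ifast,
                               literal_no_leak=True)
        assert J[0, 0] == pytest.approx(expected_lit, abs=1e-12)
        J2 = reservoir_jacobian(m.fast_weights, m.fast_readout, u, ifast)
        assert J2[0, 0] == pytest.approx(0.8 + 0.2 * expected_lit, abs=1e-12)

    @pytest.mark.parametrize("literal", [True, False])
    def test_matches_central_finite_differences(self, literal):
        cfg = FastReservoirConfig(n_nodes=10, sparsity=0.5, seed=4,
                                  input_scale=0.3, bias_scale=0.5, param_scale=0.2)
        w = init_fast_reservoir(cfg)
        rng = np.random.default_rng(0)
        readout = Readout(w_out=rng.standard_normal(10) * 0.2,
                          b_out=0.1, beta=0.0)
        u = rng.uniform(-0.5, 0.5, 10)
        i_fast = 0.3
        J = reservoir_jacobian(w, readout, u, i_fast, literal_no_leak=literal)

        def step(uv):
            y = readout.w_out @ uv + readout.b_out
            pre = w.W @ uv + w.w_in * y + w.w_param * i_fast + w.b
            t = np.tanh(pre)
            return t if literal else w.leak_rate * uv + (1 - w.leak_rate) * t

        eps = 1e-6
        J_fd = np.empty((10, 10))
        for j in range(10):
            e = np.zeros(10)
            e[j] = eps
            J_fd[:, j] = (step(u + e) - step(u - e)) / (2 * eps)
        assert np.abs(J - J_fd).max() < 1e-6


class TestMapLLE:
    def test_contraction_map_log_half(self):
        # u -> tanh(0.5 u) has fixed point 0 with multiplier exactly 0.5
        m = fake_model(W=[[0.5]], w_in=0.0, w_out=0.0, leak=None)
        est = lle_map(m, 0.0, u0=np.zeros(1), n_transient=10, n_steps=100,
                      literal_no_leak=True)
        assert est.value == pytest.approx(np.log(0.5), abs=1e-12)

    def test_identity_map_zero_exponent(self):
        m = fake_model(W=[[1.0]], w_in=0.0, w_out=0.0, leak=None)
        est = lle_map(m, 0.0, u0=np.zeros(1), n_transient=10, n_steps=100,
                      literal_no_leak=True)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_doubling_map_log_two(self):
        m = fake_model(W=[[2.0]], w_in=0.0, w_out=0.0, leak=None)
        est = lle_map(m, 0.0, u0=np.zeros(1), n_transient=10, n_steps=100,
                      literal_no_leak=True)
        assert est.value == pytest.approx(np.log(2.0), abs=1e-12)

    def test_renormalization_interval_invariance(self):
        m = fake_model(W=[[0.5]], w_in=0.0, w_out=0.0, leak=None)
        a = lle_map(m, 0.0, u0=np.zeros(1), n_transient=5, n_steps=100,
                    renorm_interval=1, literal_no_leak=True)
        b = lle_map(m, 0.0, u0=np.zeros(1), n_transient=5, n_steps=100,
                    renorm_interval=2, literal_no_leak=True)
        assert a.value == pytest.approx(b.value, rel=1e-9)

    def test_tangent_lle_matches_two_trajectory_oracle_on_chaotic_map(self):
        """A random expanding tanh network is chaotic; the Jacobian-propagated
        exponent must agree with a finite-perturbation (Benettin) estimate."""
        rng = np.random.default_rng(11)
        n = 50
        W = rng.standard_normal((n, n)) * (2.0 / np.sqrt(n))  # gain 2 -> chaos
        m = fake_model(W=W, w_in=np.zeros(n), w_out=np.zeros(n),
                       b=rng.uniform(-0.1, 0.1, n), leak=None, n=n)
        u0 = rng.uniform(-0.5, 0.5, n)
        est = lle_map(m, 0.0, u0=u0, n_transient=500, n_steps=8000,
                      literal_no_leak=True)
        assert est.value > 0

        # independent oracle: evolve a tiny finite perturbation, renormalizing
        def step(u):
            return np.tanh(W @ u + m.fast_weights.b)

        u = u0.copy()
        for _ in range(500):
            u = step(u)
        d0 = 1e-9
        v = rng.standard_normal(n)
        up = u + v * (d0 / np.linalg.norm(v))
        total = 0.0
        n_steps = 8000
        for k in range(n_steps):
            u, up = step(u), step(up)
            if (k + 1) % 5 == 0:
                d = np.linalg.norm(up - u)
                total += np.log(d / d0)
                up = u + (up - u) * (d0 / d)
        oracle = total / n_steps
        assert est.value == pytest.approx(oracle, rel=0.10)


class TestFlowLLE:
    def test_stable_origin_regime_is_negative(self):
        spec = SystemSpec.lorenz()
        est = lle_flow(spec, 0.5, t_transient=5.0, t_total=50.0)
        assert est.value < 0

    def test_chaotic_lorenz_matches_divergence_oracle(self):
        spec = SystemSpec.lorenz()
        est = lle_flow(spec, 28.0, t_transient=20.0, t_total=400.0)
        oracle = benettin_flow_lle(spec, 28.0, t_total=400.0)
        assert est.value == pytest.approx(oracle, rel=0.05)
        assert est.value == pytest.approx(0.9, rel=0.15)  # literature ballpark

    def test_rossler_standard_regime_is_chaotic(self):
        spec = SystemSpec.rossler()
        est = lle_flow(spec, 0.2, t_transient=100.0, t_total=1500.0)
        assert est.value > 0

    def test_flow_renormalization_invariance(self):
        spec = SystemSpec.lorenz()
        a = lle_flow(spec, 28.0, t_transient=20.0, t_total=150.0,
                     renorm_interval=0.5)
        b = lle_flow(spec, 28.0, t_transient=20.0, t_total=150.0,
                     renorm_interval=0.25)
        assert a.value == pytest.approx(b.value, rel=0.01)


class TestProfile:
    def test_constant_input_gives_constant_profile(self):
        m = fake_model(W=[[0.5]], w_in=0.0, w_out=0.0, leak=None)
        df = lle_profile(m, np.full(10, 0.3), states=np.zeros((10, 1)),
                         stride=3, n_transient=5, n_steps=50,
                         literal_no_leak=True)
        assert len(df) == 4
        assert df["lle"].nunique() == 1

    def test_stride_equal_length_single_estimate(self):
        m = fake_model(W=[[0.5]], w_in=0.0, w_out=0.0, leak=None)
        df = lle_profile(m, np.full(7, 0.1), states=np.zeros((7, 1)),
                         stride=7, n_transient=5, n_steps=50,
                         literal_no_leak=True)
        assert len(df) == 1
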