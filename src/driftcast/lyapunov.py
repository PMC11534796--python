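"""Largest Lyapunov exponent (LLE) estimators.

Two settings are covered:

* the learned autonomous fast-reservoir map at a *frozen* slow input — the
  readout feedback is substituted into the update, one tangent vector is
  propagated through the analytic Jacobian and renormalized periodically
  (Benettin-style), and the mean log growth per step is reported;
* the true continuous flows at a fixed parameter value — the variational
  equation is integrated jointly with the flow (analytic state Jacobian),
  giving the exponent per model time unit.

Only the largest exponent is computed: a single tangent vector with repeated
normalization converges to the leading direction, which is all the
bifurcation diagnostics need (positive = chaos, negative = stable fixed
point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TrainedModel
from .readout import Readout
from .reservoir import ReservoirWeights
from .schedules import ConstantSchedule
from .systems import SystemSpec

__all__ = [
    "LLEEstimate",
    "reservoir_jacobian",
    "lle_map",
    "lle_flow",
    "lle_profile",
]


@dataclass
class LLEEstimate:
    value: float               # per step (maps) or per model time unit (flows)
    n_transient: int
    n_steps: int
    renorm_interval: float

    def __post_init__(self):
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if not np.isfinite(self.value):
            raise ValueError("LLE estimate must be finite")


def _closed_loop_pre(w: ReservoirWeights, r: Readout, u: np.ndarray,
                     i_fast: float) -> np.ndarray:
    """tanh argument of the feedback-substituted fast-reservoir map."""
    y = r.w_out @ u + r.b_out
    return w.W @ u + w.w_in * y + w.w_param * i_fast + w.b


def reservoir_jacobian(weights: ReservoirWeights, readout: Readout,
                       u: np.ndarray, i_fast: float,
                       literal_no_leak: bool = False) -> np.ndarray:
    """Analytic Jacobian of the closed-loop fast-reservoir map at state ``u``.

    The leakless form is ``diag(1 - tanh^2(r)) (W + w_in w_out^T)``; the leaky
    form (the map actually iterated by default) is
    ``alpha I + (1 - alpha) diag(1 - tanh^2(r)) (W + w_in w_out^T)``.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (weights.n_nodes,):
        raise ValueError("state dimension does not match the reservoir")
    pre = _closed_loop_pre(weights, readout, u, i_fast)
    d = 1.0 - np.tanh(pre) ** 2
    W = weights.W.toarray() if hasattr(weights.W, "toarray") else np.asarray(weights.W)
    M = W + np.outer(weights.w_in, readout.w_out)
    J = d[:, None] * M
    if literal_no_leak:
        return J
    a = weights.leak_rate
    J = (1.0 - a) * J
    J[np.diag_indices_from(J)] += a
    return J


def lle_map(model: TrainedModel, i_fast: float, u0: np.ndarray | None = None,
            n_transient: int = 500, n_steps: int = 5000,
            renorm_interval: int = 1, seed: int = 0,
            literal_no_leak: bool = False,
            divergence_bound: float = 1e6) -> LLEEstimate:
    """LLE of the learned closed-loop map with the slow input frozen.

    ``u0`` defaults to the fast-reservoir state recorded at the switch step;
    pass the recorded closed-loop state at the step whose slow input is being
    frozen to keep the tangent dynamics on the relevant attractor.  The
    tangent vector is propagated matrix-free (Jacobian-vector products).
    """
    w, r = model.fast_weights, model.fast_readout
    alpha = w.leak_rate
    u = (model.u_fast_end if u0 is None else np.asarray(u0, dtype=float)).copy()

    def step(uv):
        pre = _closed_loop_pre(w, r, uv, i_fast)
        t = np.tanh(pre)
        nxt = t if literal_no_leak else alpha * uv + (1.0 - alpha) * t
        return nxt, pre

    for _ in range(n_transient):
        u, _ = step(u)
    if not np.all(np.isfinite(u)) or np.max(np.abs(u)) > divergence_bound:
        raise RuntimeError("closed-loop map diverged during the LLE transient")

    rng = np.random.default_rng(seed)
    v = rng.standard_normal(w.n_nodes)
    v /= np.linalg.norm(v)
    total = 0.0
    for k in range(n_steps):
        nxt, pre = step(u)
        d = 1.0 - np.tanh(pre) ** 2
        jv = d * (w.W @ v + w.w_in * (r.w_out @ v))
        v = jv if literal_no_leak else alpha * v + (1.0 - alpha) * jv
        u = nxt
        if (k + 1) % renorm_interval == 0:
            norm = np.linalg.norm(v)
            if norm == 0.0 or not np.isfinite(norm):
                raise RuntimeError("tangent vector degenerated during LLE estimation")
            total += np.log(norm)
            v /= norm
    if not np.all(np.isfinite(u)):
        raise RuntimeError("closed-loop map diverged during LLE accumulation")
    return LLEEstimate(value=total / n_steps, n_transient=n_transient,
                       n_steps=n_steps, renorm_interval=renorm_interval)


def lle_flow(spec: SystemSpec, lambda_fixed: float, t_transient: float = 20.0,
             t_total: float = 200.0, renorm_interval: float = 0.5,
             seed: int = 0) -> LLEEstimate:
    """LLE of the continuous flow at constant parameter, per model time unit.

    Integrates the flow and its variational equation jointly with RK4 at the
    spec's internal step, renormalizing the tangent at fixed time intervals.
    """
    h = spec.dt_int
    sched = ConstantSchedule(lambda_fixed)
    lam = float(sched.value(0.0, spec.dt))
    x = np.asarray(spec.x0, dtype=float).copy()

    def rk4_state(xk):
        k1 = spec.rhs(xk, lam)
        k2 = spec.rhs(xk + 0.5 * h * k1, lam)
        k3 = spec.rhs(xk + 0.5 * h * k2, lam)
        k4 = spec.rhs(xk + h * k3, lam)
        return xk + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    n_tr = int(round(t_transient / h))
    for _ in range(n_tr):
        x = rk4_state(x)
    if not np.all(np.isfinite(x)):
        raise RuntimeError("flow diverged during the LLE transient")

    rng = np.random.default_rng(seed)
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)

    def rk4_joint(xk, vk):
        def f(xx, vv):
            return spec.rhs(xx, lam), spec.jacobian(xx, lam) @ vv
        k1x, k1v = f(xk, vk)
        k2x, k2v = f(xk + 0.5 * h * k1x, vk + 0.5 * h * k1v)
        k3x, k3v = f(xk + 0.5 * h * k2x, vk + 0.5 * h * k2v)
        k4x, k4v = f(xk + h * k3x, vk + h * k3v)
        return (xk + (h / 6.0) * (k1x + 2 * k2x + 2 * k3x + k4x),
                vk + (h / 6.0) * (k1v + 2 * k2v + 2 * k3v + k4v))

    n_total = int(round(t_total / h))
    n_renorm = max(1, int(round(renorm_interval / h)))
    total = 0.0
    for k in range(n_total):
        x, v = rk4_joint(x, v)
        if (k + 1) % n_renorm == 0:
            norm = np.linalg.norm(v)
            total += np.log(norm)
            v /= norm
    # account for growth since the last renormalization
    rem = n_total % n_renorm
    if rem:
        norm = np.linalg.norm(v)
        total += np.log(norm)
    return LLEEstimate(value=total / (n_total * h), n_transient=n_tr,
                       n_steps=n_total, renorm_interval=renorm_interval)


def lle_profile(model: TrainedModel, h_series: np.ndarray,
                states: np.ndarray | None = None, stride: int = 500,
                n0: int = 0, **lle_kwargs):
    """Batch :func:`lle_map` along a slow-input series.

    ``h_series`` is the slow input per step (training-phase ``h`` or
    closed-loop predicted feature) and ``states`` the matching fast-reservoir
    state trace used to seed each frozen-input estimate; ``n0`` is the
    absolute step of index 0.  Returns a pandas DataFrame with columns
    ``n``, ``i_fast`` and ``lle``.
    """
    import pandas as pd

    h_series = np.asarray(h_series, dtype=float)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = []
    for idx in range(0, len(h_series), stride):
        u0 = None if states is None else states[idx]
        est = lle_map(model, float(h_series[idx]), u0=u0, **lle_kwargs)
        rows.append({"n": n0 + idx, "i_fast": float(h_series[idx]),
                     "lle": est.value})
    return pd.DataFrame(rows)
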