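"""Two-phase protocol: teacher-forced training, then autonomous closed loop.

Training phase (open loop): the observation drives the slow reservoir; the
slow feature is extracted and smoothed; the fast reservoir is driven by the
observation plus the smoothed slow feature, the slow dynamics predictor (SDP)
by the slow feature alone; finally both readouts are ridge-fit for one-step
prediction on the training window.

Prediction phase (closed loop): at the switch step the reservoir states are
carried over unchanged and every external input is replaced by the model's
own readout output, so the whole system becomes a single autonomous map.  The
closed-loop code path receives only the trained model — it has no access to
the ground-truth observation, slow feature or parameter.

One bookkeeping convention used throughout: the state with index ``n`` is the
state *after* consuming input ``n - 1``, so the readout maps state ``n`` to
the value at step ``n`` — one-step-ahead prediction relative to the inputs
consumed.

The printed closed-loop map omits the fast reservoir's leak term while the
training map includes it (leak 0.8).  Changing the dynamics between phases
would invalidate the trained readout, so by default the leak is kept in both
phases; ``literal_no_leak=True`` reproduces the leakless printed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .readout import Readout, build_design, fit_readout, predict_readout
from .reservoir import (
    FastReservoirConfig,
    ReservoirWeights,
    SDPConfig,
    SlowReservoirConfig,
    drive,
    init_fast_reservoir,
    init_sdp_reservoir,
    init_slow_reservoir,
)
from .slow_feature import (
    SlowNodeSet,
    extract_slow_feature,
    fluctuation_scores,
    select_slow_nodes,
    smooth,
)
from .systems import ObservationSeries

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "PredictionTrace",
    "run_training_phase",
    "run_closed_loop",
    "detect_oscillation_death",
    "delay_embed",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Windows and hyper-parameters of the training phase.

    The readouts are fit on the ``(n_transient, n_train_end]`` pairs only;
    everything before ``n_transient`` is treated as reservoir transient.

    ``ridge_beta`` regularizes the fast readout; ``sdp_ridge_beta`` the slow
    dynamics predictor's.  Both are numerical regularization rather than
    shrinkage: the state columns are strongly collinear, and the SDP's useful
    signal subspace in particular is tiny (the slow feature enters at scale
    5e-3), so its coefficient must stay far below the fast reservoir's or the
    trend-following direction is shrunk away and the closed-loop slow input
    relaxes to the training mean instead of continuing its drift.

    ``washout_replays`` replays the first ``n_transient`` observation samples
    that many times through the slow reservoir before the main pass, purely
    to wash out the zero initial state: at recurrent spectral radius 1 the
    slow reservoir's own relaxation outlasts the discarded prefix, and the
    leftover drift would masquerade as slow-feature trend.
    """

    n_transient: int = 1500
    n_train_end: int = 5500
    n_window: int = 100
    node_fraction: float = 0.10
    tau_f: float = 200.0
    ridge_beta: float = 1e-5
    sdp_ridge_beta: float = 1e-10
    washout_replays: int = 2

    def __post_init__(self):
        if not 0 <= self.n_transient < self.n_train_end:
            raise ValueError("need 0 <= n_transient < n_train_end (non-empty window)")

    @property
    def n_train(self) -> int:
        return self.n_train_end - self.n_transient


@dataclass
class TrainedModel:
    """Everything needed to run (and re-run) the autonomous closed loop."""

    slow_cfg: SlowReservoirConfig
    fast_cfg: FastReservoirConfig
    sdp_cfg: SDPConfig
    train_cfg: TrainingConfig
    slow_weights: ReservoirWeights
    fast_weights: ReservoirWeights
    sdp_weights: ReservoirWeights
    slow_nodes: SlowNodeSet
    scores: np.ndarray
    u_tilde: np.ndarray            # extracted slow feature, steps 0..n_train_end
    h: np.ndarray                  # smoothed slow feature, same range
    fast_readout: Readout
    sdp_readout: Readout
    u_fast_end: np.ndarray         # fast state at the switch step
    u_sdp_end: np.ndarray          # SDP state at the switch step
    beta: float
    y_train_ptp: float             # peak-to-peak of y over the training window
    train_rmse: float = np.nan     # in-sample one-step RMSE of the fast readout
    train_fit: np.ndarray | None = None    # in-sample one-step fit of y
    fast_trace: np.ndarray | None = field(default=None, repr=False)
    sdp_trace: np.ndarray | None = field(default=None, repr=False)
    slow_trace: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_switch(self) -> int:
        return self.train_cfg.n_train_end

    def training_report(self) -> dict:
        """Summary of the readout fits: residual, ridge coefficients, window."""
        return {
            "window": [self.train_cfg.n_transient, self.train_cfg.n_train_end],
            "beta_fast": self.beta,
            "beta_sdp": self.sdp_readout.beta,
            "train_rmse": float(self.train_rmse),
            "n_slow_nodes": int(len(self.slow_nodes.indices)),
        }


@dataclass
class PredictionTrace:
    """Autonomous closed-loop output starting at the switch step.

    ``y_pred[k]`` / ``h_pred[k]`` are the model outputs at absolute step
    ``n0 + k``; index 0 holds the readout applied to the carried-over states.
    If the trajectory left the configured bound the trace is truncated and
    ``diverged_at`` records the offending relative step.
    """

    y_pred: np.ndarray
    h_pred: np.ndarray
    n0: int
    fast_states: np.ndarray | None = field(default=None, repr=False)
    sdp_states: np.ndarray | None = field(default=None, repr=False)
    diverged_at: int | None = None

    @property
    def steps(self) -> np.ndarray:
        return self.n0 + np.arange(len(self.y_pred))


def run_training_phase(y: ObservationSeries | np.ndarray,
                       slow_cfg: SlowReservoirConfig | None = None,
                       fast_cfg: FastReservoirConfig | None = None,
                       sdp_cfg: SDPConfig | None = None,
                       train_cfg: TrainingConfig | None = None,
                       keep_traces: bool = True) -> TrainedModel:
    """Open-loop training of all three reservoirs on the observation prefix."""
    yv = np.asarray(y.y if isinstance(y, ObservationSeries) else y, dtype=float)
    slow_cfg = slow_cfg or SlowReservoirConfig()
    fast_cfg = fast_cfg or FastReservoirConfig(seed=slow_cfg.seed)
    sdp_cfg = sdp_cfg or SDPConfig(seed=slow_cfg.seed)
    train_cfg = train_cfg or TrainingConfig()
    n_end = train_cfg.n_train_end
    n_tr = train_cfg.n_transient
    if len(yv) < n_end + 1:
        raise ValueError(
            f"observation series too short: need at least {n_end + 1} samples, "
            f"got {len(yv)}")

    slow_w = init_slow_reservoir(slow_cfg)
    fast_w = init_fast_reservoir(fast_cfg)
    sdp_w = init_sdp_reservoir(sdp_cfg)

    # 1-2) drive the slow reservoir over the prefix, score and select nodes
    u0_slow = None
    if train_cfg.washout_replays > 0 and n_tr > 0:
        washout = np.tile(yv[:n_tr], train_cfg.washout_replays)
        u0_slow = drive(slow_w, (washout,))[-1]
    slow_trace = drive(slow_w, (yv[:n_end],), u0=u0_slow)
    scores = fluctuation_scores(slow_trace, train_cfg.n_window, (n_tr, n_end + 1))
    nodes = select_slow_nodes(scores, train_cfg.node_fraction)

    # 3) extract and smooth the slow feature
    u_tilde = extract_slow_feature(slow_trace, nodes)
    h = smooth(u_tilde, train_cfg.tau_f)

    # 4) teacher-force the fast reservoir and the SDP
    fast_trace = drive(fast_w, (yv[:n_end], h[:n_end]))
    sdp_trace = drive(sdp_w, (h[:n_end],))

    # 5) ridge-fit both readouts on the training window
    beta = train_cfg.ridge_beta
    window = (n_tr + 1, n_end + 1)
    U_fast = build_design(fast_trace, window)
    fast_readout = fit_readout(U_fast, yv[n_tr + 1:n_end + 1], beta)
    U_sdp = build_design(sdp_trace, window)
    sdp_readout = fit_readout(U_sdp, h[n_tr + 1:n_end + 1],
                              train_cfg.sdp_ridge_beta)

    train_fit = predict_readout(fast_readout, fast_trace[n_tr + 1:n_end + 1])
    train_rmse = float(np.sqrt(np.mean((train_fit - yv[n_tr + 1:n_end + 1]) ** 2)))
    y_ptp = float(np.ptp(yv[n_tr:n_end + 1]))

    return TrainedModel(
        slow_cfg=slow_cfg, fast_cfg=fast_cfg, sdp_cfg=sdp_cfg,
        train_cfg=train_cfg,
        slow_weights=slow_w, fast_weights=fast_w, sdp_weights=sdp_w,
        slow_nodes=nodes, scores=scores.scores,
        u_tilde=u_tilde, h=h,
        fast_readout=fast_readout, sdp_readout=sdp_readout,
        u_fast_end=fast_trace[n_end].copy(), u_sdp_end=sdp_trace[n_end].copy(),
        beta=beta, y_train_ptp=y_ptp, train_rmse=train_rmse,
        train_fit=train_fit,
        fast_trace=fast_trace if keep_traces else None,
        sdp_trace=sdp_trace if keep_traces else None,
        slow_trace=slow_trace if keep_traces else None,
    )


def run_closed_loop(model: TrainedModel, n_steps: int,
                    literal_no_leak: bool = False,
                    divergence_bound: float = 1e6,
                    keep_states: bool = True) -> PredictionTrace:
    """Iterate the fully autonomous system for ``n_steps`` from the switch.

    States at the switch step are carried over unchanged; only the inputs are
    replaced by the model's own outputs.  On divergence (|output| above
    ``divergence_bound`` or non-finite state) the trace is truncated and the
    relative step recorded — no exception is raised.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be nonnegative")
    fw, sw = model.fast_weights, model.sdp_weights
    alpha = fw.leak_rate
    u_f = model.u_fast_end.copy()
    u_s = model.u_sdp_end.copy()

    y_pred = np.empty(n_steps + 1)
    h_pred = np.empty(n_steps + 1)
    y_pred[0] = predict_readout(model.fast_readout, u_f)
    h_pred[0] = predict_readout(model.sdp_readout, u_s)
    f_states = np.empty((n_steps + 1, fw.n_nodes)) if keep_states else None
    s_states = np.empty((n_steps + 1, sw.n_nodes)) if keep_states else None
    if keep_states:
        f_states[0] = u_f
        s_states[0] = u_s

    diverged_at = None
    last = n_steps
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            u_s = np.tanh(sw.W @ u_s + sw.w_param * h_pred[k] + sw.b)
            h_pred[k + 1] = predict_readout(model.sdp_readout, u_s)
            pre = fw.W @ u_f + fw.w_in * y_pred[k] + fw.w_param * h_pred[k] + fw.b
            if literal_no_leak:
                u_f = np.tanh(pre)
            else:
                u_f = alpha * u_f + (1.0 - alpha) * np.tanh(pre)
            y_pred[k + 1] = predict_readout(model.fast_readout, u_f)
            if keep_states:
                f_states[k + 1] = u_f
                s_states[k + 1] = u_s
            if (not np.isfinite(y_pred[k + 1]) or not np.isfinite(h_pred[k + 1])
                    or abs(y_pred[k + 1]) > divergence_bound):
                diverged_at = k + 1
                last = k + 1
                break

    sl = slice(0, last + 1)
    return PredictionTrace(
        y_pred=y_pred[sl], h_pred=h_pred[sl], n0=model.n_switch,
        fast_states=f_states[sl] if keep_states else None,
        sdp_states=s_states[sl] if keep_states else None,
        diverged_at=diverged_at,
    )


def detect_oscillation_death(series: np.ndarray, window: int = 200,
                             threshold: float | None = None,
                             reference_ptp: float | None = None) -> int | None:
    """First step from which the rolling peak-to-peak amplitude stays small.

    The amplitude at position ``i`` is the peak-to-peak range of
    ``series[i:i + window]``.  Returns the first ``i`` such that every later
    amplitude is below ``threshold`` (default: 5% of ``reference_ptp``), or
    ``None`` if the oscillation never dies.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    x = np.asarray(series, dtype=float)
    if len(x) < window:
        return None
    if threshold is None:
        if reference_ptp is None:
            raise ValueError("give threshold or reference_ptp")
        threshold = 0.05 * reference_ptp
    sw = np.lib.stride_tricks.sliding_window_view(x, window)
    amp = sw.max(axis=1) - sw.min(axis=1)
    quiet = amp < threshold
    if not quiet[-1]:
        return None
    # first index from which all remaining windows are quiet
    not_quiet = np.nonzero(~quiet)[0]
    return int(not_quiet[-1] + 1) if len(not_quiet) else 0


def delay_embed(series: np.ndarray, dim: int = 3, lag: int = 2) -> np.ndarray:
    """Delay-coordinate vectors (y(n), y(n-lag), ..., y(n-(dim-1)lag)).

    Returns an array of shape ``(len(series) - (dim - 1) * lag, dim)``.
    """
    if dim < 1 or lag < 1:
        raise ValueError("dim and lag must be >= 1")
    x = np.asarray(series, dtype=float)
    m = (dim - 1) * lag
    if len(x) <= m:
        raise ValueError("series too short for the requested embedding")
    cols = [x[m - j * lag: len(x) - j * lag] for j in range(dim)]
    return np.column_stack(cols)
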