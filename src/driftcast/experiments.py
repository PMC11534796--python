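"""End-to-end study protocols: slow-feature extraction sweep and bifurcation prediction.

Experiment 1 drives the slow reservoir with a triangular-parameter chaotic
series and sweeps the leak rate, measuring the Pearson correlation between
the true drifting parameter and the sign-aligned extracted slow feature.
Experiment 2 trains the full three-reservoir model on pre-bifurcation chaos
of a ramp-parameter Lorenz series, switches to the autonomous closed loop and
quantifies whether the predicted trajectory exhibits oscillation death with a
negative terminal Lyapunov exponent, across an ablation of training lengths.

The synthetic data is deterministic (fixed initial condition, parameter an
explicit function of time), so the seed indexes reservoir realizations only.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .lyapunov import lle_map
from .model import (
    TrainingConfig,
    detect_oscillation_death,
    run_closed_loop,
    run_training_phase,
)
from .reservoir import (
    FastReservoirConfig,
    SDPConfig,
    SlowReservoirConfig,
    drive,
    init_slow_reservoir,
)
from .schedules import LinearRampSchedule, TriangularSchedule
from .slow_feature import (
    extract_slow_feature,
    fluctuation_scores,
    select_slow_nodes,
    sign_align,
)
from .systems import (
    SystemSpec,
    integrate_nonstationary,
    lambda_on_observation_grid,
    observe,
)

__all__ = [
    "Experiment1Config",
    "Experiment1Report",
    "Experiment2Config",
    "Experiment2Report",
    "pearson_r",
    "run_experiment1",
    "run_experiment2",
    "make_experiment1_data",
    "make_experiment2_data",
]


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two samples")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Experiment 1: leak-rate sweep for unsupervised parameter extraction

@dataclass(frozen=True)
class Experiment1Config:
    system: str = "lorenz"
    lambda_min: float = 64.0
    lambda_max: float = 100.0
    period_steps: int = 10000
    n_steps: int = 20000
    n_transient: int = 1500
    n_window: int = 100
    node_fraction: float = 0.10
    leak_rates: tuple = (0.5, 0.99, 0.995, 0.999, 0.9999)
    seeds: tuple = tuple(range(10))
    n_nodes: int = 500


@dataclass
class Experiment1Report:
    config: Experiment1Config
    r_by_seed: dict            # seed -> {alpha: aligned Pearson r}
    best_alpha_by_seed: dict   # seed -> argmax alpha
    majority_alpha: float

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "r_by_seed": {str(k): {str(a): v for a, v in d.items()}
                          for k, d in self.r_by_seed.items()},
            "best_alpha_by_seed": {str(k): v for k, v in self.best_alpha_by_seed.items()},
            "majority_alpha": self.majority_alpha,
        }


def make_experiment1_data(cfg: Experiment1Config):
    """Triangular-parameter series and the true parameter on the same grid."""
    if cfg.system == "lorenz":
        spec = SystemSpec.lorenz()
    elif cfg.system == "rossler":
        spec = SystemSpec.rossler()
    else:
        raise ValueError(f"unknown system {cfg.system!r}")
    sched = TriangularSchedule(cfg.lambda_min, cfg.lambda_max, cfg.period_steps)
    traj = integrate_nonstationary(spec, sched, t_end=cfg.n_steps * spec.dt)
    y = observe(traj)
    lam = lambda_on_observation_grid(traj)
    return y, lam, spec


def _slow_cfg_for(cfg: Experiment1Config, alpha: float, seed: int) -> SlowReservoirConfig:
    if cfg.system == "rossler":
        return SlowReservoirConfig.for_rossler(
            n_nodes=cfg.n_nodes, leak_rate=alpha, seed=seed)
    return SlowReservoirConfig(n_nodes=cfg.n_nodes, leak_rate=alpha, seed=seed)


def extract_aligned_feature(y: np.ndarray, lam: np.ndarray,
                            slow_cfg: SlowReservoirConfig,
                            n_transient: int, n_window: int,
                            node_fraction: float = 0.10):
    """Drive, select, extract and sign-align; returns (r, aligned u_tilde)."""
    w = init_slow_reservoir(slow_cfg)
    trace = drive(w, (y,))
    scores = fluctuation_scores(trace, n_window, (n_transient, len(trace)))
    nodes = select_slow_nodes(scores, node_fraction)
    u_tilde = extract_slow_feature(trace, nodes)
    # state n is the state at time dt*n; compare on the common step range
    stop = min(len(u_tilde), len(lam))
    feat = u_tilde[n_transient:stop]
    ref = lam[n_transient:stop]
    s = sign_align(feat, ref)
    r = pearson_r(s * feat, ref)
    return r, s * u_tilde


def run_experiment1(cfg: Experiment1Config | None = None) -> Experiment1Report:
    """Leak-rate sweep: correlation of the extracted feature with the truth."""
    cfg = cfg or Experiment1Config()
    y, lam, _ = make_experiment1_data(cfg)
    yv = y.y
    r_by_seed: dict = {}
    best: dict = {}
    for seed in cfg.seeds:
        r_by_seed[seed] = {}
        for alpha in cfg.leak_rates:
            r, _ = extract_aligned_feature(
                yv, lam, _slow_cfg_for(cfg, alpha, seed),
                cfg.n_transient, cfg.n_window, cfg.node_fraction)
            r_by_seed[seed][alpha] = r
        best[seed] = max(r_by_seed[seed], key=r_by_seed[seed].get)
    votes = list(best.values())
    majority = max(set(votes), key=votes.count)
    return Experiment1Report(config=cfg, r_by_seed=r_by_seed,
                             best_alpha_by_seed=best, majority_alpha=majority)


# ---------------------------------------------------------------------------
# Experiment 2: closed-loop bifurcation prediction with training-length ablation

@dataclass(frozen=True)
class Experiment2Config:
    lambda_start: float = 64.0
    lambda_end: float = 32.0 / 3.0   # ramp crosses the chaos-loss region (lam=24) at step 7500
    n_ramp_start: int = 0
    n_ramp_end: int = 10000
    n_total: int = 10000
    n_switch: int = 5500
    n_predict: int = 4000
    train_lengths: tuple = (4000, 2500, 1200, 1000)
    seeds: tuple = tuple(range(10))
    n_window: int = 100
    tau_f: float = 200.0
    death_window: int = 200
    death_fraction: float = 0.05
    # chaotic-phase LLE probe: at the switch step, measuring finite-time
    # expansion along the trajectory's own state (no discard) with a probe
    # shorter than typical transient-chaos lifetimes near the boundary
    # crisis; the terminal probe is longer to confirm asymptotic stability
    lle_chaotic_step: int = 5500
    lle_chaotic_transient: int = 0
    lle_chaotic_steps: int = 1000
    lle_transient: int = 500
    lle_steps: int = 5000


@dataclass
class Experiment2Report:
    config: Experiment2Config
    rows: list = field(default_factory=list)
    # each row: {seed, train_length, death_step, lle_chaotic, lle_terminal,
    #            diverged, success}

    def success_rate(self, train_length: int) -> float:
        sel = [r for r in self.rows if r["train_length"] == train_length]
        if not sel:
            raise ValueError(f"no rows for training length {train_length}")
        return float(np.mean([r["success"] for r in sel]))

    def to_dict(self) -> dict:
        return {"config": asdict(self.config), "rows": self.rows}


def make_experiment2_data(cfg: Experiment2Config):
    """Ramp-parameter Lorenz series crossing the oscillation-death boundary."""
    spec = SystemSpec.lorenz()
    sched = LinearRampSchedule(cfg.lambda_start, cfg.lambda_end,
                               cfg.n_ramp_start, cfg.n_ramp_end)
    traj = integrate_nonstationary(spec, sched, t_end=cfg.n_total * spec.dt)
    y = observe(traj)
    lam = lambda_on_observation_grid(traj)
    return y, lam, spec


def run_experiment2_single(y: np.ndarray, cfg: Experiment2Config, seed: int,
                           train_length: int) -> dict:
    """One seed / one training length: train, predict, quantify the bifurcation."""
    n_tr = cfg.n_switch - train_length
    if n_tr < 0:
        raise ValueError("training length exceeds the switch step")
    train_cfg = TrainingConfig(n_transient=n_tr, n_train_end=cfg.n_switch,
                               n_window=cfg.n_window, tau_f=cfg.tau_f)
    model = run_training_phase(
        y,
        slow_cfg=SlowReservoirConfig(seed=seed),
        fast_cfg=FastReservoirConfig(seed=seed),
        sdp_cfg=SDPConfig(seed=seed),
        train_cfg=train_cfg,
        keep_traces=False,
    )
    pred = run_closed_loop(model, cfg.n_predict)
    death_rel = detect_oscillation_death(
        pred.y_pred, window=cfg.death_window,
        threshold=cfg.death_fraction * model.y_train_ptp)
    death_step = None if death_rel is None else pred.n0 + death_rel

    row = {"seed": seed, "train_length": train_length,
           "death_step": death_step, "diverged": pred.diverged_at is not None,
           "lle_chaotic": np.nan, "lle_terminal": np.nan}
    try:
        k_ch = cfg.lle_chaotic_step - pred.n0
        if 0 <= k_ch < len(pred.h_pred):
            row["lle_chaotic"] = lle_map(
                model, float(pred.h_pred[k_ch]), u0=pred.fast_states[k_ch],
                n_transient=cfg.lle_chaotic_transient,
                n_steps=cfg.lle_chaotic_steps, seed=seed).value
        k_end = len(pred.h_pred) - 1
        row["lle_terminal"] = lle_map(
            model, float(pred.h_pred[k_end]), u0=pred.fast_states[k_end],
            n_transient=cfg.lle_transient, n_steps=cfg.lle_steps,
            seed=seed).value
    except RuntimeError:
        pass  # divergence inside the LLE probe counts as failure below

    in_window = (death_step is not None
                 and cfg.n_switch <= death_step <= cfg.n_switch + cfg.n_predict)
    row["success"] = bool(in_window and np.isfinite(row["lle_terminal"])
                          and row["lle_terminal"] < 0.0)
    return row


def run_experiment2(cfg: Experiment2Config | None = None) -> Experiment2Report:
    """Full ablation: every seed crossed with every training length."""
    cfg = cfg or Experiment2Config()
    if cfg.n_switch >= cfg.n_total:
        raise ValueError("n_switch must fall inside the generated series")
    y, _, _ = make_experiment2_data(cfg)
    report = Experiment2Report(config=cfg)
    for seed in cfg.seeds:
        for L in cfg.train_lengths:
            report.rows.append(run_experiment2_single(y.y, cfg, seed, L))
    return report
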