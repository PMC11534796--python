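"""The three fixed random recurrent networks and their update maps.

Three echo-state-style reservoirs cooperate:

* **slow reservoir** — leaky-integrator units with leak rate close to 1 and
  recurrent spectral radius exactly 1, used as an unsupervised extractor of
  the slow component hidden in the input;
* **fast reservoir** — a larger, sparse leaky reservoir that learns one-step
  prediction of the observation, conditioned on a slow input channel;
* **slow dynamics predictor (SDP)** — a standard (leakless) echo state
  network that learns one-step prediction of the extracted slow feature.

Leaky update (slow / fast):

    u(n+1) = alpha * u(n) + (1 - alpha) * tanh(W u(n) + W_in y(n) [+ W_param I(n)] + b)

SDP update:

    u(n+1) = tanh(W u(n) + W_param h(n) + b)

Only the linear readouts are ever trained; all weights here stay fixed.
Each weight matrix draws from its own seeded child stream so that changing
one scale never shifts another matrix's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "SlowReservoirConfig",
    "FastReservoirConfig",
    "SDPConfig",
    "ReservoirWeights",
    "init_slow_reservoir",
    "init_fast_reservoir",
    "init_sdp_reservoir",
    "step_slow",
    "step_fast",
    "step_sdp",
    "drive",
    "spectral_radius",
]

# fixed labels for per-matrix child RNG streams
_STREAMS = {"recurrent": 0, "input": 1, "param": 2, "bias": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SlowReservoirConfig:
    """Slow-timescale extractor; scales follow the driven system's amplitude."""

    n_nodes: int = 500
    leak_rate: float = 0.995
    input_scale: float = 0.5       # 0.5 for Lorenz, 15 for Rossler
    bias_scale: float = 5.0        # 5 for Lorenz, 150 for Rossler
    spectral_radius: float = 1.0
    activation: str = "tanh"       # "identity" gives the linear control
    seed: int = 0

    def __post_init__(self):
        _check_common(self)
        if self.activation not in ("tanh", "identity"):
            raise ValueError("activation must be 'tanh' or 'identity'")

    @classmethod
    def for_rossler(cls, **kw) -> "SlowReservoirConfig":
        kw.setdefault("input_scale", 15.0)
        kw.setdefault("bias_scale", 150.0)
        return cls(**kw)


@dataclass(frozen=True)
class FastReservoirConfig:
    n_nodes: int = 2000
    leak_rate: float = 0.8
    input_scale: float = 0.75
    param_scale: float = 0.15
    bias_scale: float = 15.0
    sparsity: float = 0.02         # exact non-zero fraction of W
    spectral_radius: float = 0.95
    seed: int = 0

    def __post_init__(self):
        _check_common(self)
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in (0, 1]")


@dataclass(frozen=True)
class SDPConfig:
    """Standard (leakless) echo state network forecasting the slow feature."""

    n_nodes: int = 500
    param_scale: float = 5e-3
    bias_scale: float = 5e-3
    spectral_radius: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.param_scale < 0 or self.bias_scale < 0 or self.spectral_radius <= 0:
            raise ValueError("scales must be nonnegative, spectral radius positive")


def _check_common(cfg):
    if cfg.n_nodes < 1:
        raise ValueError("n_nodes must be positive")
    if not 0.0 <= cfg.leak_rate <= 1.0:
        raise ValueError("leak rate must lie in [0, 1]")
    if cfg.input_scale < 0 or cfg.bias_scale < 0:
        raise ValueError("scales must be nonnegative")
    if cfg.spectral_radius <= 0:
        raise ValueError("spectral radius target must be positive")


@dataclass
class ReservoirWeights:
    """Frozen weight set of one reservoir.

    ``W`` is dense (slow, SDP) or CSR sparse (fast); ``w_in`` / ``w_param``
    are per-node input weights for the scalar channels (absent where the
    reservoir has no such channel).
    """

    kind: str                       # "slow" | "fast" | "sdp"
    W: object                      # ndarray or scipy.sparse.csr_array
    w_in: np.ndarray | None
    w_param: np.ndarray | None
    b: np.ndarray
    leak_rate: float | None
    activation: str = "tanh"
    seed: int = 0

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


def spectral_radius(W, seed: int = 0) -> float:
    """Largest absolute eigenvalue (ARPACK for sparse, dense eigvals otherwise)."""
    n = W.shape[0]
    if sp.issparse(W):
        if n <= 3:
            return float(np.max(np.abs(np.linalg.eigvals(W.toarray()))))
        vals = spla.eigs(W.astype(float), k=1, which="LM",
                         v0=np.ones(n), return_eigenvectors=False)
        return float(np.abs(vals[0]))
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(W, dtype=float)))))


def _normalize_radius(W, target: float):
    rho = spectral_radius(W)
    if rho == 0.0 or not np.isfinite(rho):
        raise RuntimeError("recurrent matrix has zero/invalid spectral radius")
    return W * (target / rho)


def init_slow_reservoir(cfg: SlowReservoirConfig) -> ReservoirWeights:
    """Gaussian recurrent matrix rescaled to spectral radius 1 (default)."""
    W = _rng(cfg.seed, "recurrent").standard_normal((cfg.n_nodes, cfg.n_nodes))
    W = _normalize_radius(W, cfg.spectral_radius)
    w_in = _rng(cfg.seed, "input").uniform(-cfg.input_scale, cfg.input_scale, cfg.n_nodes)
    b = _rng(cfg.seed, "bias").uniform(-cfg.bias_scale, cfg.bias_scale, cfg.n_nodes)
    return ReservoirWeights("slow", W, w_in, None, b,
                            leak_rate=cfg.leak_rate, activation=cfg.activation,
                            seed=cfg.seed)


def init_fast_reservoir(cfg: FastReservoirConfig) -> ReservoirWeights:
    """Sparse uniform recurrent matrix: exactly round(sparsity * N^2) edges."""
    n = cfg.n_nodes
    k = int(round(cfg.sparsity * n * n))
    rng = _rng(cfg.seed, "recurrent")
    flat = rng.choice(n * n, size=k, replace=False)
    rows, cols = np.divmod(flat, n)
    vals = rng.uniform(0.0, 1.0, k)
    W = sp.csr_array((vals, (rows, cols)), shape=(n, n))
    W = _normalize_radius(W, cfg.spectral_radius)
    w_in = _rng(cfg.seed, "input").uniform(-cfg.input_scale, cfg.input_scale, n)
    w_param = _rng(cfg.seed, "param").uniform(-cfg.param_scale, cfg.param_scale, n)
    b = _rng(cfg.seed, "bias").uniform(-cfg.bias_scale, cfg.bias_scale, n)
    return ReservoirWeights("fast", W, w_in, w_param, b,
                            leak_rate=cfg.leak_rate, seed=cfg.seed)


def init_sdp_reservoir(cfg: SDPConfig) -> ReservoirWeights:
    W = _rng(cfg.seed, "recurrent").standard_normal((cfg.n_nodes, cfg.n_nodes))
    W = _normalize_radius(W, cfg.spectral_radius)
    w_param = _rng(cfg.seed, "param").uniform(-cfg.param_scale, cfg.param_scale, cfg.n_nodes)
    b = _rng(cfg.seed, "bias").uniform(-cfg.bias_scale, cfg.bias_scale, cfg.n_nodes)
    return ReservoirWeights("sdp", W, None, w_param, b,
                            leak_rate=None, seed=cfg.seed)


def _activation(name: str):
    if name == "tanh":
        return np.tanh
    if name == "identity":
        return lambda x: x
    raise ValueError(f"unknown activation {name!r}")


def _check_scalar(x, name):
    if not np.isfinite(x):
        raise ValueError(f"non-finite {name} input to reservoir update")


def step_slow(w: ReservoirWeights, u: np.ndarray, y: float,
              alpha: float | None = None) -> np.ndarray:
    """One leaky update of the slow reservoir."""
    _check_scalar(y, "observation")
    a = w.leak_rate if alpha is None else alpha
    act = _activation(w.activation)
    pre = w.W @ u + w.w_in * y + w.b
    return a * u + (1.0 - a) * act(pre)


def step_fast(w: ReservoirWeights, u: np.ndarray, y: float, i_fast: float,
              alpha: float | None = None) -> np.ndarray:
    """One leaky update of the fast reservoir (extra slow-input channel)."""
    _check_scalar(y, "observation")
    _check_scalar(i_fast, "slow-channel")
    a = w.leak_rate if alpha is None else alpha
    wp = 0.0 if w.w_param is None else w.w_param
    pre = w.W @ u + w.w_in * y + wp * i_fast + w.b
    return a * u + (1.0 - a) * np.tanh(pre)


def step_sdp(w: ReservoirWeights, u: np.ndarray, h: float) -> np.ndarray:
    """One leakless update of the slow dynamics predictor."""
    _check_scalar(h, "slow-feature")
    return np.tanh(w.W @ u + w.w_param * h + w.b)


def drive(w: ReservoirWeights, inputs, u0: np.ndarray | None = None,
          alpha: float | None = None) -> np.ndarray:
    """Teacher-forced (open-loop) run over full input sequences.

    ``inputs`` is a tuple of equal-length scalar sequences: ``(y,)`` for the
    slow reservoir, ``(y, i_fast)`` for the fast reservoir, ``(h,)`` for the
    SDP.  Returns the state trace of shape ``(T + 1, N)`` whose row ``n`` is
    the state *after* consuming the first ``n`` inputs (row 0 is ``u0``).
    """
    seqs = [np.asarray(s, dtype=float) for s in inputs]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("input sequences must have equal length")
    for s in seqs:
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite values in drive inputs")
    expected = {"slow": 1, "fast": 2, "sdp": 1}[w.kind]
    if len(seqs) != expected:
        raise ValueError(f"{w.kind} reservoir expects {expected} input sequence(s)")

    n = w.n_nodes
    u = np.zeros(n) if u0 is None else np.asarray(u0, dtype=float).copy()
    T = len(seqs[0]) if seqs else 0
    trace = np.empty((T + 1, n))
    trace[0] = u

    if w.kind == "slow":
        a = w.leak_rate if alpha is None else alpha
        act = _activation(w.activation)
        y = seqs[0]
        W, w_in, b = w.W, w.w_in, w.b
        for t in range(T):
            u = a * u + (1.0 - a) * act(W @ u + w_in * y[t] + b)
            trace[t + 1] = u
    elif w.kind == "fast":
        a = w.leak_rate if alpha is None else alpha
        y, i_fast = seqs
        W, w_in, w_param, b = w.W, w.w_in, w.w_param, w.b
        for t in range(T):
            u = a * u + (1.0 - a) * np.tanh(
                W @ u + w_in * y[t] + w_param * i_fast[t] + b)
            trace[t + 1] = u
    else:  # sdp
        h = seqs[0]
        W, w_param, b = w.W, w.w_param, w.b
        for t in range(T):
            u = np.tanh(W @ u + w_param * h[t] + b)
            trace[t + 1] = u
    return trace
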