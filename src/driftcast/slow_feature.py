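"""Unsupervised extraction of the slow feature from the slow-reservoir trace.

The heuristic: score every reservoir node by the standard deviation of its
state around its own causal moving average over the training window, keep the
fraction (default 10%) of nodes with the *smallest* score — those are the
ones whose activity drifts slowly rather than tracking the fast input — and
average their absolute values per step.  Taking absolute values first matters:
roughly half the slow nodes mirror the drifting parameter and half anti-mirror
it (the tanh nonlinearity and weight distributions are centrally symmetric),
so a plain average would cancel.  A first-order low-pass filter

    h(n+1) = (1 - 1/tau_f) h(n) + u_tilde(n) / tau_f

smooths the extracted feature before it is handed to downstream reservoirs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FluctuationScores",
    "SlowNodeSet",
    "SlowFeatureSeries",
    "moving_average",
    "fluctuation_scores",
    "select_slow_nodes",
    "extract_slow_feature",
    "smooth",
    "sign_align",
]


@dataclass
class FluctuationScores:
    scores: np.ndarray          # (N,), nonnegative
    n_window: int
    window: tuple               # (start, stop) step range scored


@dataclass
class SlowNodeSet:
    indices: np.ndarray         # sorted ascending
    fraction: float


@dataclass
class SlowFeatureSeries:
    u_tilde: np.ndarray         # mean of absolute values over selected nodes
    h: np.ndarray               # low-pass filtered feature
    tau_f: float
    sign: int = 1               # display alignment only; never used in prediction


def moving_average(series, n_window: int) -> np.ndarray:
    """Causal moving average over the most recent ``n_window`` samples.

    For the first ``n_window - 1`` samples the average runs over the available
    prefix.  Works along axis 0 for 2-D input (time x nodes).
    """
    if n_window < 1:
        raise ValueError("n_window must be >= 1")
    x = np.asarray(series, dtype=float)
    if n_window == 1:
        return x.copy()
    c = np.cumsum(x, axis=0)
    out = np.empty_like(x)
    w = min(n_window, len(x))
    counts = np.arange(1, w + 1, dtype=float)
    if x.ndim > 1:
        counts = counts.reshape(-1, *([1] * (x.ndim - 1)))
    out[:w] = c[:w] / counts
    if len(x) > n_window:
        out[n_window:] = (c[n_window:] - c[:-n_window]) / n_window
    return out


def fluctuation_scores(trace: np.ndarray, n_window: int,
                       window: tuple) -> FluctuationScores:
    """Per-node SD of state minus causal moving average, over ``window``.

    ``window`` is a half-open ``(start, stop)`` step range within the trace;
    the moving average itself is computed causally on the full trace so early
    window samples see genuine history.  Population SD (divide by count).
    """
    trace = np.asarray(trace, dtype=float)
    start, stop = window
    if not (0 <= start < stop <= len(trace)):
        raise ValueError("scoring window must be a non-empty range within the trace")
    if stop - start <= n_window:
        raise ValueError("scoring window must be longer than the averaging window")
    resid = trace - moving_average(trace, n_window)
    scores = resid[start:stop].std(axis=0, ddof=0)
    return FluctuationScores(scores=scores, n_window=n_window, window=(start, stop))


def select_slow_nodes(scores: FluctuationScores | np.ndarray,
                      fraction: float = 0.10) -> SlowNodeSet:
    """Indices of the ``round(fraction * N)`` smallest scores (ties by index)."""
    vals = scores.scores if isinstance(scores, FluctuationScores) else np.asarray(scores)
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(round(fraction * len(vals)))
    if k < 1:
        raise ValueError("fraction selects zero nodes")
    order = np.argsort(vals, kind="stable")
    return SlowNodeSet(indices=np.sort(order[:k]), fraction=fraction)


def extract_slow_feature(trace: np.ndarray, nodes: SlowNodeSet) -> np.ndarray:
    """Per-step mean of absolute values over the selected nodes (nonnegative)."""
    idx = nodes.indices if isinstance(nodes, SlowNodeSet) else np.asarray(nodes)
    if len(idx) == 0:
        raise ValueError("empty slow-node set")
    return np.abs(np.asarray(trace, dtype=float)[:, idx]).mean(axis=1)


def smooth(u_tilde: np.ndarray, tau_f: float = 200.0,
           h0: float | None = None) -> np.ndarray:
    """First-order low-pass recursion; DC gain exactly 1.

    ``h0`` defaults to the first input sample, which avoids a spurious
    relaxation ramp at the start of the filtered series.
    """
    if tau_f < 1:
        raise ValueError("tau_f must be >= 1")
    u = np.asarray(u_tilde, dtype=float)
    h = np.empty_like(u)
    if len(u) == 0:
        return h
    h[0] = u[0] if h0 is None else float(h0)
    a = 1.0 - 1.0 / tau_f
    inv = 1.0 / tau_f
    for n in range(len(u) - 1):
        h[n + 1] = a * h[n] + u[n] * inv
    return h


def sign_align(feature: np.ndarray, reference: np.ndarray) -> int:
    """Sign (+1/-1) maximizing Pearson correlation with the reference.

    Evaluation convenience only: the prediction pipeline never consults the
    ground truth, so this sign plays no role there.
    """
    f = np.asarray(feature, dtype=float)
    r = np.asarray(reference, dtype=float)
    if len(f) != len(r):
        raise ValueError("sequences must have equal length")
    fc = f - f.mean()
    rc = r - r.mean()
    cov = float(fc @ rc)
    return 1 if cov >= 0 else -1
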