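"""Ridge-regression training of the linear readouts.

Only the affine readout of each reservoir is trained.  With the design
matrix ``U`` holding one state column per training step plus a constant-1
row, the regularized least-squares solution is the closed form

    (w_out, b_out) = (U U^T + beta I)^(-1) U y

solved here through a Cholesky factorization of the regularized Gram matrix
rather than an explicit inverse.  The bias enters the design as the ones row
and is regularized along with the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "Readout",
    "build_design",
    "fit_readout",
    "predict_readout",
    "supervised_lambda_fit",
]


@dataclass
class Readout:
    w_out: np.ndarray      # (N,)
    b_out: float
    beta: float

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("ridge coefficient must be nonnegative")
        if not (np.all(np.isfinite(self.w_out)) and np.isfinite(self.b_out)):
            raise ValueError("readout weights must be finite")


def build_design(trace: np.ndarray, window: tuple) -> np.ndarray:
    """States in the half-open ``(start, stop)`` step range, ones row appended.

    Output shape ``(N + 1, T)`` with the last row identically 1.
    """
    trace = np.asarray(trace, dtype=float)
    start, stop = window
    if not (0 <= start < stop <= len(trace)):
        raise ValueError("design window must be a non-empty range within the trace")
    states = trace[start:stop]
    return np.vstack([states.T, np.ones((1, len(states)))])


def fit_readout(U: np.ndarray, targets: np.ndarray, beta: float) -> Readout:
    """Solve the ridge problem ``(U U^T + beta I)^(-1) U y`` for one readout.

    The solution is computed through the equivalent augmented least-squares
    system ``[U^T; sqrt(beta) I] w ~ [y; 0]`` by QR factorization, which
    avoids squaring the condition number of the design; the reservoir state
    columns are highly collinear and the accuracy of this solve directly
    limits closed-loop fidelity.  ``beta = 0`` is allowed only on full-rank
    designs; a rank-deficient system raises with advice to use ``beta > 0``.
    """
    U = np.asarray(U, dtype=float)
    y = np.asarray(targets, dtype=float)
    if U.ndim != 2 or U.shape[1] != len(y):
        raise ValueError("targets length must match the number of design columns")
    if beta < 0:
        raise ValueError("ridge coefficient must be nonnegative")
    p = U.shape[0]
    if beta > 0:
        A = np.vstack([U.T, np.sqrt(beta) * np.eye(p)])
        b = np.concatenate([y, np.zeros(p)])
    else:
        A, b = U.T, y
    coef, _, rank, _ = scipy.linalg.lstsq(A, b, lapack_driver="gelsy")
    if beta == 0 and rank < p:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {p}); use beta > 0")
    if not np.all(np.isfinite(coef)):
        raise np.linalg.LinAlgError("singular ridge system; use beta > 0")
    return Readout(w_out=coef[:-1], b_out=float(coef[-1]), beta=float(beta))


def predict_readout(r: Readout, u: np.ndarray) -> float | np.ndarray:
    """Affine map ``w_out . u + b_out``; accepts a state vector or (T, N) trace."""
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        return float(r.w_out @ u + r.b_out)
    return u @ r.w_out + r.b_out


def ridge_objective(r: Readout, U: np.ndarray, targets: np.ndarray) -> float:
    """Value of the trained objective: residual^2 + beta * ||(w, b)||^2."""
    coef = np.concatenate([r.w_out, [r.b_out]])
    resid = np.asarray(targets, dtype=float) - coef @ np.asarray(U, dtype=float)
    return float(resid @ resid + r.beta * (coef @ coef))


def supervised_lambda_fit(trace: np.ndarray, lambda_series: np.ndarray,
                          beta: float, window: tuple | None = None
                          ) -> tuple[Readout, float]:
    """Supervised control: ridge-fit the true parameter from reservoir states.

    Fits lambda(dt * n) from the (slow-)reservoir state trace with the same
    machinery as the prediction readouts and returns the in-sample RMSE.  With
    a tanh slow reservoir this fit is expected to be accurate; with the
    identity-activation (linear) control it is expected to fail, which is the
    point of the comparison.
    """
    trace = np.asarray(trace, dtype=float)
    lam = np.asarray(lambda_series, dtype=float)
    if window is None:
        window = (0, min(len(trace), len(lam)))
    start, stop = window
    U = build_design(trace, (start, stop))
    targets = lam[start:stop]
    r = fit_readout(U, targets, beta)
    pred = predict_readout(r, trace[start:stop])
    rmse = float(np.sqrt(np.mean((pred - targets) ** 2)))
    return r, rmse
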