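"""Shared fixtures and independent oracles used across the suite."""

import numpy as np
import pytest

from driftcast.reservoir import ReservoirWeights
from driftcast.schedules import TriangularSchedule
from driftcast.systems import SystemSpec, integrate_nonstationary, observe


def scalar_weights(kind: str, W: float, w_in: float | None, w_param: float | None,
                   b: float, leak: float | None, activation: str = "tanh"):
    """One-node reservoir with hand-set weights, for pencil-and-paper checks."""
    return ReservoirWeights(
        kind=kind,
        W=np.array([[W]]),
        w_in=None if w_in is None else np.array([w_in]),
        w_param=None if w_param is None else np.array([w_param]),
        b=np.array([b]),
        leak_rate=leak,
        activation=activation,
    )


def power_iteration_radius(W, n_iter: int = 5000, seed: int = 1234) -> float:
    """Independent spectral-radius oracle by power iteration.

    Valid when the dominant eigenvalue is real and simple — in particular for
    the nonnegative (Perron-Frobenius) fast-reservoir matrix.
    """
    rng = np.random.default_rng(seed)
    n = W.shape[0]
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    growth = 0.0
    for _ in range(n_iter):
        v = W @ v
        nv = np.linalg.norm(v)
        growth = nv
        v /= nv
    return float(growth)


def arnoldi_radius(W, seed: int = 1234) -> float:
    """Independent spectral-radius oracle via ARPACK Arnoldi iteration.

    Handles complex dominant eigenvalue pairs (Gaussian recurrent matrices),
    where plain real power iteration fails to converge in norm.
    """
    import scipy.sparse.linalg as spla

    n = W.shape[0]
    rng = np.random.default_rng(seed)
    vals = spla.eigs(spla.aslinearoperator(W), k=3, which="LM",
                     v0=rng.standard_normal(n), return_eigenvectors=False,
                     ncv=min(n, 40), maxiter=20000, tol=1e-13)
    return float(np.max(np.abs(vals)))


def benettin_flow_lle(spec: SystemSpec, lam: float, t_total: float = 200.0,
                      t_transient: float = 20.0, d0: float = 1e-8,
                      renorm_every: int = 50, seed: int = 7) -> float:
    """Two-trajectory finite-perturbation LLE oracle for the constant-lambda flow.

    Integrates a reference and a perturbed trajectory with the same RK4
    stepper, renormalizing the separation back to ``d0`` at fixed intervals.
    Entirely independent of the variational-equation estimator it checks.
    """
    h = spec.dt_int
    rng = np.random.default_rng(seed)

    def step(x):
        k1 = spec.rhs(x, lam)
        k2 = spec.rhs(x + 0.5 * h * k1, lam)
        k3 = spec.rhs(x + 0.5 * h * k2, lam)
        k4 = spec.rhs(x + h * k3, lam)
        return x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    x = np.asarray(spec.x0, dtype=float)
    for _ in range(int(round(t_transient / h))):
        x = step(x)
    pert = rng.standard_normal(3)
    pert *= d0 / np.linalg.norm(pert)
    xp = x + pert
    total = 0.0
    n = int(round(t_total / h))
    for k in range(n):
        x = step(x)
        xp = step(xp)
        if (k + 1) % renorm_every == 0:
            d = np.linalg.norm(xp - x)
            total += np.log(d / d0)
            xp = x + (xp - x) * (d0 / d)
    return total / (n * h)


@pytest.fixture(scope="session")
def lorenz28_observation():
    """Stationary chaotic Lorenz series (lambda=28), 3000 samples."""
    from driftcast.schedules import ConstantSchedule

    spec = SystemSpec.lorenz()
    traj = integrate_nonstationary(spec, ConstantSchedule(28.0), t_end=3000 * spec.dt)
    return observe(traj), spec


@pytest.fixture(scope="session")
def exp1_lorenz_data():
    """Triangular-parameter Lorenz data at the leak-sweep study conditions."""
    from driftcast.experiments import Experiment1Config, make_experiment1_data

    cfg = Experiment1Config()
    y, lam, spec = make_experiment1_data(cfg)
    return cfg, y, lam
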