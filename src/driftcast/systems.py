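"""Non-stationary chaotic signal sources: Lorenz and Rossler flows.

The generators integrate a three-dimensional flow whose bifurcation parameter
``lambda`` drifts on a much slower timescale than the state, then discretize
the first state component at a fixed sampling interval ``dt`` to produce the
scalar observation ``y(n) = x1(dt * n)``.  Integration is fixed-step classical
Runge-Kutta (RK4) with the schedule evaluated at each sub-stage time, i.e. the
drift is treated as a genuine non-autonomous term.

The Lorenz variant used here is the standard Lorenz-63 system with the usual
Rayleigh parameter playing the role of lambda::

    dx1/dt = a (x2 - x1)
    dx2/dt = -x2 + x1 (lambda - x3)
    dx3/dt = -b x3 + x1 x2

and the Rossler variant drifts the usual ``b`` parameter::

    dx1/dt = -x2 - x3
    dx2/dt = x1 + a x2
    dx3/dt = lambda + x3 (x1 - c)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schedules import ParameterSchedule, evaluate_schedule

__all__ = [
    "SystemSpec",
    "Trajectory",
    "ObservationSeries",
    "IntegrationDivergedError",
    "integrate_nonstationary",
    "observe",
]


class IntegrationDivergedError(RuntimeError):
    """Raised when the fixed-step integration produces a non-finite state."""


@dataclass(frozen=True)
class SystemSpec:
    """Which flow to integrate, its static parameters and sampling grid.

    ``dt`` is the observation sampling interval, ``dt_int`` the internal RK4
    step; ``dt`` must be a positive integer multiple of ``dt_int``.
    """

    system: str  # "lorenz" | "rossler"
    a: float
    b: float  # Lorenz dissipation (unused for Rossler)
    c: float  # Rossler fold parameter (unused for Lorenz)
    dt: float
    dt_int: float
    x0: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.system not in ("lorenz", "rossler"):
            raise ValueError(f"unknown system {self.system!r}")
        if self.dt <= 0 or self.dt_int <= 0:
            raise ValueError("dt and dt_int must be positive")
        ratio = self.dt / self.dt_int
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ValueError("dt must be an integer multiple of dt_int")
        if not np.all(np.isfinite([self.a, self.b, self.c])):
            raise ValueError("static parameters must be finite")

    @classmethod
    def lorenz(cls, a: float = 10.0, b: float = 8.0 / 3.0, dt: float = 0.05,
               dt_int: float | None = None, x0=(1.0, 1.0, 1.0)) -> "SystemSpec":
        return cls("lorenz", a=a, b=b, c=0.0, dt=dt,
                   dt_int=dt / 5.0 if dt_int is None else dt_int, x0=tuple(x0))

    @classmethod
    def rossler(cls, a: float = 0.2, c: float = 5.7, dt: float = 0.7,
                dt_int: float | None = None, x0=(1.0, 1.0, 1.0)) -> "SystemSpec":
        return cls("rossler", a=a, b=0.0, c=c, dt=dt,
                   dt_int=dt / 5.0 if dt_int is None else dt_int, x0=tuple(x0))

    @property
    def stride(self) -> int:
        return int(round(self.dt / self.dt_int))

    def rhs(self, x: np.ndarray, lam: float) -> np.ndarray:
        """Vector field at state ``x`` and parameter value ``lam``."""
        x1, x2, x3 = x
        if self.system == "lorenz":
            return np.array([
                self.a * (x2 - x1),
                -x2 + x1 * (lam - x3),
                -self.b * x3 + x1 * x2,
            ])
        return np.array([
            -x2 - x3,
            x1 + self.a * x2,
            lam + x3 * (x1 - self.c),
        ])

    def jacobian(self, x: np.ndarray, lam: float) -> np.ndarray:
        """State Jacobian of the vector field (for variational integration)."""
        x1, x2, x3 = x
        if self.system == "lorenz":
            return np.array([
                [-self.a, self.a, 0.0],
                [lam - x3, -1.0, -x1],
                [x2, x1, -self.b],
            ])
        return np.array([
            [0.0, -1.0, -1.0],
            [1.0, self.a, 0.0],
            [x3, 0.0, x1 - self.c],
        ])

    def fixed_points(self, lam: float) -> np.ndarray:
        """Analytic equilibria at constant ``lam`` (Lorenz only)."""
        if self.system != "lorenz":
            raise NotImplementedError("analytic fixed points provided for Lorenz only")
        pts = [np.zeros(3)]
        if lam > 1.0:
            r = np.sqrt(self.b * (lam - 1.0))
            pts.append(np.array([r, r, lam - 1.0]))
            pts.append(np.array([-r, -r, lam - 1.0]))
        return np.array(pts)


@dataclass
class Trajectory:
    """Dense integrator output: uniform grid, 3-component state, lambda series."""

    t: np.ndarray          # (n+1,) model time
    x: np.ndarray          # (n+1, 3)
    lam: np.ndarray        # (n+1,)
    spec: SystemSpec
    schedule: ParameterSchedule = field(repr=False, default=None)

    def __post_init__(self):
        if not (len(self.t) == len(self.x) == len(self.lam)):
            raise ValueError("trajectory arrays must share a length")


@dataclass
class ObservationSeries:
    """Scalar observation ``y(n) = x1(dt * n)`` on the sampling grid."""

    y: np.ndarray
    dt: float

    @property
    def n_steps(self) -> int:
        return len(self.y)

    def __len__(self) -> int:
        return len(self.y)


def integrate_nonstationary(spec: SystemSpec, schedule: ParameterSchedule,
                            t_end: float) -> Trajectory:
    """Integrate the flow under a drifting parameter with fixed-step RK4.

    The schedule is evaluated at every RK4 sub-stage time.  Raises
    :class:`IntegrationDivergedError` naming the failure time if the state
    leaves the finite range.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    h = spec.dt_int
    n = int(round(t_end / h))
    t = np.arange(n + 1) * h
    # lambda at stage times: grid points and half steps, evaluated in bulk
    lam_full = evaluate_schedule(schedule, t, spec.dt)
    lam_half = evaluate_schedule(schedule, t[:-1] + 0.5 * h, spec.dt)
    lam_full = np.atleast_1d(np.asarray(lam_full, dtype=float))
    lam_half = np.atleast_1d(np.asarray(lam_half, dtype=float))

    x = np.empty((n + 1, 3))
    x[0] = spec.x0
    rhs = spec.rhs
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n):
            xk = x[k]
            l0, lh, l1 = lam_full[k], lam_half[k], lam_full[k + 1]
            k1 = rhs(xk, l0)
            k2 = rhs(xk + 0.5 * h * k1, lh)
            k3 = rhs(xk + 0.5 * h * k2, lh)
            k4 = rhs(xk + h * k3, l1)
            xk1 = xk + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.all(np.isfinite(xk1)):
                raise IntegrationDivergedError(
                    f"integration diverged at t={t[k + 1]:g} "
                    f"(step {k + 1} of {n})"
                )
            x[k + 1] = xk1
    return Trajectory(t=t, x=x, lam=lam_full, spec=spec, schedule=schedule)


def observe(traj: Trajectory, dt: float | None = None) -> ObservationSeries:
    """Sample the first state component every ``dt`` (default: spec.dt)."""
    if dt is None:
        dt = traj.spec.dt
    grid = traj.spec.dt_int
    ratio = dt / grid
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-9 * max(ratio, 1.0):
        raise ValueError(
            f"sampling interval {dt} is not a multiple of the grid spacing {grid}"
        )
    return ObservationSeries(y=traj.x[::stride, 0].copy(), dt=dt)


def lambda_on_observation_grid(traj: Trajectory, dt: float | None = None) -> np.ndarray:
    """The ground-truth lambda series on the observation sampling grid."""
    if dt is None:
        dt = traj.spec.dt
    stride = int(round(dt / traj.spec.dt_int))
    return traj.lam[::stride].copy()
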