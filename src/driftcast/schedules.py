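"""Piecewise-linear time courses of the drifting bifurcation parameter.

The driven systems treat the bifurcation parameter ``lambda`` as an explicit,
slowly varying function of continuous model time ``t``.  Three shapes cover the
study conditions: a constant value, a triangular (symmetric zig-zag) wave, and
a clamped linear ramp.  Schedules are specified in *observation steps* (the
sampling grid of the scalar observation), so evaluation always takes both the
continuous time and the sampling interval ``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterSchedule",
    "ConstantSchedule",
    "TriangularSchedule",
    "LinearRampSchedule",
    "evaluate_schedule",
]


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("schedule evaluation requires t >= 0")
    return t


class ParameterSchedule:
    """Base class: a continuous, piecewise-linear map t -> lambda(t)."""

    kind: str = "abstract"

    def value(self, t, dt: float):
        raise NotImplementedError

    def __call__(self, t, dt: float):
        return self.value(t, dt)


@dataclass(frozen=True)
class ConstantSchedule(ParameterSchedule):
    lambda_value: float

    kind = "constant"

    def value(self, t, dt: float):
        t = _check_time(t)
        out = np.full_like(t, float(self.lambda_value))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TriangularSchedule(ParameterSchedule):
    """Zig-zag between ``lambda_min`` and ``lambda_max``.

    Starts at the minimum at t=0, reaches the maximum after half a period and
    returns; the period is ``period_steps`` observation steps, i.e.
    ``period_steps * dt`` model time units.
    """

    lambda_min: float
    lambda_max: float
    period_steps: int

    kind = "triangular"

    def value(self, t, dt: float):
        if self.period_steps <= 0:
            raise ValueError("period_steps must be positive")
        t = _check_time(t)
        period = self.period_steps * dt
        phase = np.mod(t / period, 1.0)
        lam = self.lambda_min + (self.lambda_max - self.lambda_min) * (
            1.0 - np.abs(2.0 * phase - 1.0)
        )
        return float(lam) if lam.ndim == 0 else lam


@dataclass(frozen=True)
class LinearRampSchedule(ParameterSchedule):
    """Linear ramp from ``lambda_start`` to ``lambda_end``, clamped outside.

    Constant at ``lambda_start`` before step ``n_start`` and at ``lambda_end``
    after step ``n_end``.
    """

    lambda_start: float
    lambda_end: float
    n_start: int
    n_end: int

    kind = "linear_ramp"

    def value(self, t, dt: float):
        if self.n_end <= self.n_start:
            raise ValueError("n_end must exceed n_start")
        t = _check_time(t)
        lam = np.interp(
            t,
            [self.n_start * dt, self.n_end * dt],
            [self.lambda_start, self.lambda_end],
        )
        return float(lam) if lam.ndim == 0 else lam


def evaluate_schedule(schedule: ParameterSchedule, t, dt: float):
    """Evaluate ``lambda(t)`` for scalar or array ``t`` (model time units)."""
    return schedule.value(t, dt)
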