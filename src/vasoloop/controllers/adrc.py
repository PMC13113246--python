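"""Active disturbance rejection control (ADRC) of the infusion rate.

Three standard blocks run at the controller tick:

* a tracking differentiator (TD) — here a critically damped linear
  second-order tracker — turns the MAP setpoint into a smoothed reference
  ``v1`` and its derivative ``v2``;
* a third-order extended state observer (ESO) estimates the MAP ``z1``, its
  rate ``z2`` and a lumped disturbance ``z3`` (unmodelled dynamics, the
  hemorrhage, plant nonlinearity) from the measured MAP and the applied
  infusion rate, treating the plant as a disturbed double integrator
  ``ÿ = f + b·u``;
* the feedback law ``u = (kp·(v1 − z1) − kd·z2 − z3)/b`` cancels the
  estimated disturbance, with ``kp`` scaled up monotonically with the
  absolute tracking error to speed up large-deviation transients.

A per-tick rate limiter plus trend-aware logic guard the output: increases
are blocked while MAP is rising faster than a threshold slope, and decreases
are halved while MAP is falling steeply (to preserve perfusion support).
ESO gains follow the usual bandwidth parameterization
``β = (3ω, 3ω², ω³)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["AdrcTuning", "AdrcController", "td_step", "eso_step"]


def td_step(v1: float, v2: float, setpoint: float, dt: float,
            speed: float) -> tuple[float, float]:
    """Critically damped second-order tracker step (natural frequency ``speed``).

    Uses the exact discretization (matrix exponential of the critically
    damped system, which has the closed form below), so the tracker is
    stable for any ``speed`` and collapses onto the setpoint in one tick as
    ``speed -> inf``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if speed <= 0:
        raise ValueError("speed must be > 0")
    x1, x2 = v1 - setpoint, v2
    decay = math.exp(-speed * dt) if speed * dt < 700 else 0.0
    new_x1 = decay * ((1.0 + speed * dt) * x1 + dt * x2)
    new_x2 = decay * (-speed * speed * dt * x1 + (1.0 - speed * dt) * x2)
    return setpoint + new_x1, new_x2


def eso_step(z1: float, z2: float, z3: float, measured: float, u: float,
             dt: float, beta: tuple[float, float, float],
             b: float) -> tuple[float, float, float]:
    """Canonical third-order extended state observer update.

    For the disturbed double-integrator model the control input enters the
    ``z2`` (rate) equation; at steady state ``z3`` then converges to
    ``−b·u``, which is what gives the control law its integral action
    (placing ``b·u`` in the ``z1`` equation instead leaves a proportional
    steady-state error).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    e = z1 - measured
    return (z1 + dt * (z2 - beta[0] * e),
            z2 + dt * (z3 - beta[1] * e + b * u),
            z3 + dt * (-beta[2] * e))


@dataclass(frozen=True)
class AdrcTuning:
    kp: float                    # s^-2
    kd: float                    # s^-1
    b: float                     # (mmHg/s^2) per (mL/min); must be non-zero
    eso_bandwidth: float         # rad/s; beta = (3w, 3w^2, w^3)
    td_speed: float              # rad/s
    max_rate_step: float         # mL/min per tick
    rate_max: float = 5.0
    adapt_gain: float = 1.0      # kp multiplier grows to (1 + adapt_gain)
    adapt_ref: float = 20.0      # mmHg error at which the adaptation saturates
    trend_limit: float = 4.0     # mmHg/min slope triggering trend-aware limits

    def __post_init__(self) -> None:
        if self.b == 0:
            raise ValueError("system gain b must be non-zero")
        if self.eso_bandwidth <= 0:
            raise ValueError("eso_bandwidth must be > 0")

    @property
    def beta(self) -> tuple[float, float, float]:
        w = self.eso_bandwidth
        return (3.0 * w, 3.0 * w * w, w ** 3)


@dataclass
class AdrcController:
    tuning: AdrcTuning
    dt: float
    initial_rate: float = 0.0

    v1: float | None = field(init=False, default=None)
    v2: float = field(init=False, default=0.0)
    z1: float = field(init=False, default=0.0)
    z2: float = field(init=False, default=0.0)
    z3: float = field(init=False, default=0.0)
    current_rate: float = field(init=False)

    def __post_init__(self) -> None:
        self.current_rate = self.initial_rate

    def reset(self) -> None:
        self.v1 = None
        self.v2 = self.z2 = self.z3 = 0.0
        self.current_rate = self.initial_rate

    def control(self, v1: float) -> float:
        """Disturbance-cancelling feedback law (before limiting), mL/min."""
        t = self.tuning
        err = v1 - self.z1
        kp_eff = t.kp * (1.0 + t.adapt_gain * min(abs(err) / t.adapt_ref, 1.0))
        return (kp_eff * err - t.kd * self.z2 - self.z3) / t.b

    def tick(self, measured: float, target: float) -> float:
        t = self.tuning
        if self.v1 is None:  # start reference and observer at the first reading
            self.v1 = measured
            self.z1 = measured
        self.v1, self.v2 = td_step(self.v1, self.v2, target, self.dt, t.td_speed)
        self.z1, self.z2, self.z3 = eso_step(
            self.z1, self.z2, self.z3, measured, self.current_rate,
            self.dt, t.beta, t.b)

        u = self.control(self.v1)
        delta = max(-t.max_rate_step, min(t.max_rate_step, u - self.current_rate))
        slope = self.z2 * 60.0  # estimated MAP slope, mmHg/min
        if slope > t.trend_limit:          # rapidly rising: no further increases
            delta = min(delta, 0.0)
        elif slope < -t.trend_limit:       # steep decline: restrain tapering
            delta = max(delta, -t.max_rate_step / 2.0)
        self.current_rate = max(0.0, min(t.rate_max, self.current_rate + delta))
        return self.current_rate
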