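"""PID vasopressor controller with delay compensation and anti-windup.

The error is formed against a first-order delayed estimate of MAP,
``P_delayed += (dt/τ)(P_measured − P_delayed)`` with τ = 15 s, modelling the
physiological latency between a dose change and the pressure response. Sign
convention: error = target − P_delayed, so a positive error drives the
infusion rate up (the inverse convention is pure bookkeeping).

Anti-windup is twofold: near the setpoint (|error| < 5 mmHg) the integral
accumulator is decayed each tick instead of accumulating, and away from it
integration is frozen while the commanded change exceeds the slew limit,
so the accumulator cannot wind up during a rate-limited climb. The
derivative is a backward difference; a rate limiter bounds the change in
infusion rate per tick — larger for the aggressive profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PidTuning", "PidController", "delay_filter_step"]


def delay_filter_step(p_delayed: float, p_measured: float, dt: float,
                      tau: float) -> float:
    """One step of the first-order delay filter; fixed point at ``p_measured``."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    return p_delayed + (dt / tau) * (p_measured - p_delayed)


@dataclass(frozen=True)
class PidTuning:
    kp: float                      # mL/min per mmHg
    ki: float                      # mL/min per mmHg·s
    kd: float                      # mL/min per mmHg/s
    max_rate_step: float           # mL/min per tick
    antiwindup_band: float = 5.0   # mmHg
    antiwindup_decay: float = 0.95 # fraction kept per tick inside the band
    rate_max: float = 5.0          # mL/min
    delay_tau: float = 15.0        # s

    def __post_init__(self) -> None:
        if not 0 < self.antiwindup_decay < 1:
            raise ValueError("antiwindup_decay must be in (0, 1)")
        if self.max_rate_step <= 0 or self.rate_max <= 0:
            raise ValueError("rate limits must be > 0")


@dataclass
class PidController:
    tuning: PidTuning
    dt: float                      # controller tick, s
    initial_rate: float = 0.0

    p_delayed: float | None = field(init=False, default=None)
    integral: float = field(init=False, default=0.0)   # mmHg·s
    prev_error: float = field(init=False, default=0.0)
    current_rate: float = field(init=False)

    def __post_init__(self) -> None:
        self.current_rate = self.initial_rate
        self._saturated = False

    def reset(self) -> None:
        self.p_delayed = None
        self.integral = 0.0
        self.prev_error = 0.0
        self.current_rate = self.initial_rate
        self._saturated = False

    def tick(self, measured: float, target: float) -> float:
        t = self.tuning
        if self.p_delayed is None:
            self.p_delayed = measured
            self.prev_error = target - measured
        self.p_delayed = delay_filter_step(self.p_delayed, measured, self.dt,
                                           t.delay_tau)
        error = target - self.p_delayed
        if abs(error) < t.antiwindup_band:
            self.integral *= t.antiwindup_decay
        elif not self._saturated:
            # conditional integration: freeze while the commanded change is
            # slew-limited, so the accumulator cannot wind up during the climb
            self.integral += error * self.dt
        derivative = (error - self.prev_error) / self.dt
        self.prev_error = error

        command = t.kp * error + t.ki * self.integral + t.kd * derivative
        self._saturated = abs(command - self.current_rate) > t.max_rate_step
        delta = command - self.current_rate
        delta = max(-t.max_rate_step, min(t.max_rate_step, delta))
        self.current_rate = max(0.0, min(t.rate_max, self.current_rate + delta))
        return self.current_rate
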