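"""Patient-following controller: step the dose only when the current dose's
effect has saturated.

The MAP signal is smoothed with a rolling-average window and converted to a
relative error ``e = (target − MAP)/target`` (0 at target, negative on
overshoot). The error gradient is the least-squares slope of the last five
``e`` samples. After each dose change the most negative gradient is tracked
as the local minimum, replaced only by values ≤ 1.05× the current minimum
(a tolerance against jitter). As the dose's effect saturates the gradient
relaxes back toward zero; when it stays above ``θ·grad_min`` for five
consecutive samples — and MAP is still more than 1% below target — the dose
is increased by a fixed increment and the tracker resets. Only the ramping
phase is implemented: doses never decrease, and no increment fires at or
above target.

Tuning (conservative / aggressive): smoothing window 10 / 5 samples,
increment 0.25 / 0.5 mL/min, threshold θ 0.5 / 0.9.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PfcTuning", "PfcController", "relative_error", "error_gradient",
           "update_grad_min"]

GRADIENT_SAMPLES = 5
CONSECUTIVE_REQUIRED = 5
GRAD_MIN_TOLERANCE = 1.05
TARGET_DEADBAND_FRAC = 0.01


def relative_error(smoothed_map: float, target: float) -> float:
    """Dimensionless error, 0 at target, negative on overshoot."""
    if target <= 0:
        raise ValueError("target must be > 0")
    return (target - smoothed_map) / target


def error_gradient(buffer, tick: float) -> float:
    """Least-squares slope (per second) of the last five error samples."""
    if len(buffer) != GRADIENT_SAMPLES:
        raise ValueError(f"gradient needs exactly {GRADIENT_SAMPLES} samples")
    t = np.arange(GRADIENT_SAMPLES) * tick
    return float(np.polyfit(t, np.asarray(buffer, dtype=float), 1)[0])


def update_grad_min(grad_min: float | None, grad: float) -> float:
    """Track the local gradient minimum with a 5% replacement tolerance."""
    if grad_min is None:
        return grad
    return grad if grad <= GRAD_MIN_TOLERANCE * grad_min else grad_min


@dataclass(frozen=True)
class PfcTuning:
    smooth_window: int         # samples (10 conservative / 5 aggressive)
    dose_increment: float      # mL/min (0.25 / 0.5)
    threshold_frac: float      # θ (0.5 / 0.9)
    rate_max: float = 5.0

    def __post_init__(self) -> None:
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not 0 < self.threshold_frac < 1:
            raise ValueError("threshold_frac must be in (0, 1)")
        if self.dose_increment <= 0:
            raise ValueError("dose_increment must be > 0")


@dataclass
class PfcController:
    tuning: PfcTuning
    dt: float
    initial_rate: float = 0.13  # first step of the dosing ladder

    current_rate: float = field(init=False)

    def __post_init__(self) -> None:
        self.current_rate = self.initial_rate
        self._map_window: deque = deque(maxlen=self.tuning.smooth_window)
        self._e_buffer: deque = deque(maxlen=GRADIENT_SAMPLES)
        self.grad_min: float | None = None
        self.consec_count = 0

    def reset(self) -> None:
        self.__post_init__()

    def tick(self, measured: float, target: float) -> float:
        t = self.tuning
        self._map_window.append(measured)
        smoothed = float(np.mean(self._map_window))
        e = relative_error(smoothed, target)
        self._e_buffer.append(e)
        if len(self._e_buffer) < GRADIENT_SAMPLES:
            return self.current_rate  # no decision until the buffer fills

        grad = error_gradient(self._e_buffer, self.dt)
        self.grad_min = update_grad_min(self.grad_min, grad)

        qualifying = grad > t.threshold_frac * self.grad_min
        self.consec_count = self.consec_count + 1 if qualifying else 0

        below_target = measured < target * (1.0 - TARGET_DEADBAND_FRAC)
        if self.consec_count >= CONSECUTIVE_REQUIRED and below_target:
            self.current_rate = min(self.current_rate + t.dose_increment,
                                    t.rate_max)
            self.grad_min = None
            self.consec_count = 0
        return self.current_rate
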