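"""Step-FIS: Sugeno rule-based controller with unit-step output logic.

The measured MAP is low-pass filtered (first-order Butterworth), converted
to a signed percent-of-target error (negative = below target) and its rate
of change. A five-rule Sugeno inference over {Negative, Zero, Positive}
memberships maps the pair to a crisp output in [-1, 1]:

    1. error Negative, rate Zero     -> Increase (+1)
    2. error Negative, rate Negative -> Increase (+1)
    3. rate Positive (any error)     -> Maintain (0)
    4. error Positive (any rate)     -> Decrease (-1), weight 0.75
    5. error Zero (any rate)         -> Maintain (0)

Rule firing strength is the minimum of the antecedent memberships ("Any"
contributes 1); the rule weight attenuates the consequent, so a lone firing
of the Decrease rule yields -0.75 — the attenuated plateau of the control
surface that makes dose withdrawal gentler than dose escalation.

The output is thresholded at ±1/3 into increase / hold / decrease of the
infusion rate by the current step size. The base step (0.035 mL/min
aggressive, 0.025 conservative) doubles when |error| exceeds 30% of target
and halves below 3%.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import signal

__all__ = [
    "MembershipSet", "FuzzyRule", "ButterworthFilter",
    "StepFisTuning", "StepFisController",
    "fis_output", "adapt_step", "load_rule_base",
]

log = logging.getLogger(__name__)

DECISION_THRESHOLD = 1.0 / 3.0
STEP_DOUBLE_ABOVE_PCT = 30.0
STEP_HALVE_BELOW_PCT = 3.0

_CONSEQUENT = {"Increase": 1.0, "Maintain": 0.0, "Decrease": -1.0}


def _zmf(x: float, a: float, b: float) -> float:
    """Linear Z-shape: 1 below ``a``, falling to 0 at ``b``."""
    if x <= a:
        return 1.0
    if x >= b:
        return 0.0
    return (b - x) / (b - a)


def _smf(x: float, a: float, b: float) -> float:
    """Linear S-shape: 0 below ``a``, rising to 1 at ``b``."""
    return 1.0 - _zmf(x, a, b)


def _trimf(x: float, a: float, b: float, c: float) -> float:
    if x <= a or x >= c:
        return 0.0
    if x <= b:
        return (x - a) / (b - a)
    return (c - x) / (c - b)


@dataclass(frozen=True)
class MembershipSet:
    """Negative (Z), Zero (triangular) and Positive (S) memberships."""

    negative: tuple[float, float]          # (a, b): 1 up to a, 0 from b
    zero: tuple[float, float, float]       # triangle breakpoints
    positive: tuple[float, float]          # (a, b): 0 up to a, 1 from b

    def grade(self, x: float) -> dict[str, float]:
        return {
            "Negative": _zmf(x, *self.negative),
            "Zero": _trimf(x, *self.zero),
            "Positive": _smf(x, *self.positive),
            "Any": 1.0,
        }


@dataclass(frozen=True)
class FuzzyRule:
    error: str       # Negative | Zero | Positive | Any
    rate: str
    consequent: float  # +1 increase, 0 maintain, -1 decrease
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError("rule weight must be in (0, 1]")


def load_rule_base() -> tuple[FuzzyRule, ...]:
    """The packaged five-rule base."""
    text = resources.files("vasoloop.data").joinpath("stepfis_rules.csv").read_text()
    rows = [r for r in csv.reader(text.splitlines())
            if r and not r[0].startswith("#")]
    return tuple(
        FuzzyRule(error=e, rate=r, consequent=_CONSEQUENT[out], weight=float(w))
        for _, e, r, out, w in rows[1:]
    )


def fis_output(error: float, error_rate: float, rules: tuple[FuzzyRule, ...],
               error_mf: MembershipSet, rate_mf: MembershipSet) -> float:
    """Weighted Sugeno inference; crisp output in [-1, 1].

    Firing strength = min over antecedent memberships; the rule weight
    scales the consequent; normalization uses the unweighted strengths. If
    nothing fires (a gap between membership supports) the action defaults to
    Maintain (0).
    """
    e_grades = error_mf.grade(error)
    r_grades = rate_mf.grade(error_rate)
    num = den = 0.0
    for rule in rules:
        strength = min(e_grades[rule.error], r_grades[rule.rate])
        num += strength * rule.weight * rule.consequent
        den += strength
    if den == 0.0:
        log.debug("no rule fired at error=%.3f rate=%.4f; maintaining",
                  error, error_rate)
        return 0.0
    return num / den


def adapt_step(base_step: float, abs_error: float) -> float:
    """Step-size adaptation: 2x above 30% |error|, half below 3%."""
    if abs_error < 0:
        raise ValueError("abs_error must be >= 0")
    if abs_error > STEP_DOUBLE_ABOVE_PCT:
        return 2.0 * base_step
    if abs_error < STEP_HALVE_BELOW_PCT:
        return base_step / 2.0
    return base_step


class ButterworthFilter:
    """Streaming first-order Butterworth low-pass (DC gain 1)."""

    def __init__(self, cutoff_hz: float, fs_hz: float):
        if not 0 < cutoff_hz < fs_hz / 2:
            raise ValueError("cutoff must lie in (0, Nyquist)")
        self._b, self._a = signal.butter(1, cutoff_hz, fs=fs_hz)
        self._zi: np.ndarray | None = None

    def step(self, x: float) -> float:
        if self._zi is None:  # settle at the first sample, not at zero
            self._zi = signal.lfilter_zi(self._b, self._a) * x
        y, self._zi = signal.lfilter(self._b, self._a, [x], zi=self._zi)
        return float(y[0])

    def reset(self) -> None:
        self._zi = None


@dataclass(frozen=True)
class StepFisTuning:
    base_step: float                      # mL/min (0.035 agg / 0.025 cons)
    cutoff_hz: float = 0.05
    rate_max: float = 5.0
    error_mf: MembershipSet = MembershipSet(
        negative=(-20.0, -1.0), zero=(-4.0, 0.0, 4.0), positive=(1.0, 20.0))
    rate_mf: MembershipSet = MembershipSet(
        negative=(-0.12, -0.03), zero=(-0.06, 0.0, 0.06),
        positive=(0.03, 0.12))


@dataclass
class StepFisController:
    tuning: StepFisTuning
    dt: float
    initial_rate: float = 0.0

    current_rate: float = field(init=False)
    _filter: ButterworthFilter = field(init=False)
    _prev_error: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.current_rate = self.initial_rate
        self._rules = load_rule_base()
        self._filter = ButterworthFilter(self.tuning.cutoff_hz, 1.0 / self.dt)

    def reset(self) -> None:
        self.current_rate = self.initial_rate
        self._filter.reset()
        self._prev_error = None

    def tick(self, measured: float, target: float) -> float:
        if target <= 0:
            raise ValueError("target must be > 0")
        filtered = self._filter.step(measured)
        error = 100.0 * (filtered - target) / target  # negative = below target
        if self._prev_error is None:
            self._prev_error = error
        error_rate = (error - self._prev_error) / self.dt
        self._prev_error = error

        out = fis_output(error, error_rate, self._rules,
                         self.tuning.error_mf, self.tuning.rate_mf)
        step = adapt_step(self.tuning.base_step, abs(error))
        if out > DECISION_THRESHOLD:
            self.current_rate += step
        elif out < -DECISION_THRESHOLD:
            self.current_rate -= step
        self.current_rate = max(0.0, min(self.tuning.rate_max, self.current_rate))
        return self.current_rate
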