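"""Virtual hemorrhaging patient.

A software stand-in for a hardware flow-loop test platform: mean arterial
pressure (MAP) responds to norepinephrine infusion-rate changes with the four
characteristic features observed in vivo — a lag between a dose change and the
pressure response, an optional transient overshoot before settling, a
saturating steady-state dose–response (``Emax`` form), and a first-order
responsiveness time constant — while a continuous hemorrhage drags MAP down.

The governing model (a design choice; the hardware platform's internal
transfer functions are not public) is

.. math::

    \\dot m = \\frac{(B - H(t)) + E(d) + s(t) - m}{\\tau} - \\dot H(t)

where ``B`` is the baseline MAP, ``H(t)`` the cumulative hemorrhage-induced
pressure deficit (volume-to-pressure slope × bleed rate × time, applied to
both the state and the attractor so that the zero-dose drift is exactly the
bleed-rate term), ``E(d) = Emax·d/(d50 + d)`` the dose effect of the infusion
rate ``d`` active after the lag, and ``s(t)`` a decaying overshoot transient
injected at each effective dose change.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "PlantParams",
    "Plant",
    "DoseTable",
    "steady_state_map",
    "rate_to_dose",
    "load_dose_table",
]

#: Hard physiological clamp applied to the simulated MAP, mmHg.
MAP_BOUNDS = (5.0, 200.0)


@dataclass(frozen=True)
class PlantParams:
    """Parameters of the virtual patient.

    Attributes
    ----------
    baseline_map:
        Unsupported (zero-dose, zero-loss) MAP, mmHg. Scenarios set this to
        the starting pressure (35, 45 or 55 mmHg).
    lag_time:
        Delay between a commanded infusion-rate change and its hemodynamic
        effect, s.
    responsiveness_tau:
        First-order time constant of the pressure rise, s.
    overshoot_frac:
        Fractional transient peak above the steady-state change after a dose
        step; 0 gives a monotone first-order response.
    overshoot_tau:
        Decay time constant of the overshoot transient, s.
    max_effect:
        Asymptote of the dose–response, mmHg.
    half_effect_dose:
        Infusion rate producing half of ``max_effect``, mL/min.
    hemorrhage_rate:
        Continuous bleed rate, mL/min.
    hemorrhage_map_slope:
        Volume-to-pressure sensitivity, mmHg per mL lost.
    noise_sd:
        Standard deviation of the Gaussian measurement/process noise added
        per unit time (mmHg·s^-1/2); 0 disables noise.
    pulse_amplitude:
        Optional pulsatile overlay amplitude, mmHg (display only; never fed
        to controllers).
    """

    baseline_map: float = 35.0
    lag_time: float = 15.0
    responsiveness_tau: float = 60.0
    overshoot_frac: float = 0.10
    overshoot_tau: float = 120.0
    max_effect: float = 60.0
    half_effect_dose: float = 1.5
    hemorrhage_rate: float = 10.0
    hemorrhage_map_slope: float = 0.03
    noise_sd: float = 0.0
    pulse_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.responsiveness_tau <= 0:
            raise ValueError("responsiveness_tau must be > 0")
        if self.max_effect <= 0 or self.half_effect_dose <= 0:
            raise ValueError("max_effect and half_effect_dose must be > 0")
        for name in ("lag_time", "overshoot_frac", "hemorrhage_rate", "noise_sd",
                     "pulse_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def steady_state_map(dose: float, params: PlantParams) -> float:
    """Steady-state MAP at a constant infusion rate, hemorrhage aside.

    ``baseline + Emax·dose/(d50 + dose)``: monotone, saturating at
    ``baseline + Emax``.
    """
    if dose < 0:
        raise ValueError(f"infusion rate must be >= 0, got {dose}")
    return params.baseline_map + params.max_effect * dose / (
        params.half_effect_dose + dose
    )


def _dose_effect(dose: float, params: PlantParams) -> float:
    return params.max_effect * dose / (params.half_effect_dose + dose)


@dataclass
class Plant:
    """Stateful simulator; advance with :meth:`step`, dose via :meth:`apply_dose`."""

    params: PlantParams
    seed: int | None = None

    time: float = field(init=False, default=0.0)
    map_true: float = field(init=False)
    current_dose: float = field(init=False, default=0.0)  # commanded (record-keeping)
    cumulative_blood_loss: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        self.map_true = self.params.baseline_map
        self._active_dose = 0.0  # dose that has taken hemodynamic effect
        self._pending: list[tuple[float, float]] = []  # (effective_time, dose)
        self._overshoot = 0.0
        self._hem_offset = 0.0
        self._rng = np.random.default_rng(self.seed)
        self._held_map = self.map_true
        self._last_sample_time = 0.0

    # -- dosing -----------------------------------------------------------

    def apply_dose(self, new_dose: float) -> None:
        """Command a new infusion rate; it takes effect after ``lag_time``."""
        if new_dose < 0:
            raise ValueError(f"infusion rate must be >= 0, got {new_dose}")
        if new_dose == self.current_dose:
            return
        self.current_dose = new_dose
        self._pending.append((self.time + self.params.lag_time, new_dose))
        self._pending.sort(key=lambda p: p[0])

    @property
    def pending_dose_changes(self) -> list[tuple[float, float]]:
        return list(self._pending)

    # -- dynamics ---------------------------------------------------------

    def step(self, dt: float) -> float:
        """Advance the plant by ``dt`` seconds (explicit Euler); returns MAP."""
        if not 0 < dt <= 1.0:
            raise ValueError("dt must be in (0, 1] s")
        p = self.params
        self.time += dt

        while self._pending and self._pending[0][0] <= self.time:
            _, dose = self._pending.pop(0)
            delta = _dose_effect(dose, p) - _dose_effect(self._active_dose, p)
            self._active_dose = dose
            if p.overshoot_frac > 0:
                self._overshoot += p.overshoot_frac * delta

        # hemorrhage lowers state and attractor together: pure drift at dose 0
        drift = p.hemorrhage_map_slope * p.hemorrhage_rate * dt / 60.0
        self._hem_offset += drift
        self.cumulative_blood_loss += p.hemorrhage_rate * dt / 60.0
        self.map_true -= drift

        attractor = (p.baseline_map - self._hem_offset
                     + _dose_effect(self._active_dose, p) + self._overshoot)
        self.map_true += (attractor - self.map_true) * dt / p.responsiveness_tau
        if p.overshoot_frac > 0:
            self._overshoot *= np.exp(-dt / p.overshoot_tau)

        if p.noise_sd > 0:
            self.map_true += p.noise_sd * np.sqrt(dt) * self._rng.standard_normal()

        self.map_true = float(np.clip(self.map_true, *MAP_BOUNDS))
        return self.map_true

    def sample(self, sample_period: float) -> float:
        """Zero-order-hold measurement at the given cadence, s.

        Returns the MAP value captured at the most recent sample instant;
        between instants the held value is repeated, emulating down-sampled
        (e.g. non-invasive) pressure measurement.
        """
        if self.time - self._last_sample_time >= sample_period or self.time == 0.0:
            observed = self.map_true
            if self.params.pulse_amplitude > 0:
                observed += self.params.pulse_amplitude * np.sin(
                    2 * np.pi * self.time)
            self._held_map = observed
            self._last_sample_time = self.time
        return self._held_map


# -- dose table ------------------------------------------------------------


@dataclass(frozen=True)
class DoseTable:
    """Discrete norepinephrine dosing ladder at a fixed drug concentration."""

    steps: tuple[tuple[int, float, float], ...]  # (step, dose mcg/min, rate mL/min)
    concentration: float = 4.0  # mcg/mL

    def __post_init__(self) -> None:
        rates = [r for _, _, r in self.steps]
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("dose-table rates must be strictly increasing")

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(r for _, _, r in self.steps)


def rate_to_dose(rate: float, table: DoseTable) -> float:
    """Delivered drug dose (mcg/min) for an infusion rate (mL/min)."""
    if rate < 0:
        raise ValueError(f"infusion rate must be >= 0, got {rate}")
    return rate * table.concentration


def load_dose_table() -> DoseTable:
    """The packaged dosing ladder (0.13–5 mL/min at 4.0 mcg/mL)."""
    text = resources.files("vasoloop.data").joinpath("dose_table.csv").read_text()
    rows = [r for r in csv.reader(text.splitlines()) if r and not r[0].startswith("#")]
    steps = tuple((int(s), float(d), float(r)) for s, d, r in rows[1:])
    return DoseTable(steps=steps)
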