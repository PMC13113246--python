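"""Controller performance metrics.

Implements the thirteen-metric evaluation suite applied to one closed-loop
run: the Varvel-style performance-error statistics (MDPE, MDAPE, wobble,
divergence) computed on ``PE = 100·(MAP − target)/target``, target tracking
measures (effectiveness, rise time, overshoot, areas above/below target) and
infusion-signal measures (mean rate, maximum smoothed rate change, windowed
rate variability).

Conventions (documented in the methods note):

* Areas integrate fractional performance error (``PE/100``, dimensionless)
  over minutes via a left Riemann sum, so a 4-minute plateau at +5% gives
  exactly 0.20 min. ``area_below`` is restricted to times after the target
  was first reached and is reported non-positive.
* ``mdape_ss`` restricts MDAPE to times after the rise time; if 90% of
  target is never reached it falls back to the final third of the run.
* ``divergence`` keeps its sign here; the scoring stage takes the absolute
  value during normalization.
* ``var_inf_rate`` is the median over sliding 2-minute windows of the
  within-window population standard deviation of the infusion rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["Trace", "MetricSet", "compute_all_metrics", "performance_error"]

EFFECTIVENESS_BAND_MMHG = 5.0
RISE_FRACTION = 0.9
RATE_SMOOTH_WINDOW_S = 180.0
VAR_WINDOW_S = 120.0
DIVERGENCE_TAIL_FRACTION = 0.1


@dataclass(frozen=True)
class Trace:
    """One closed-loop run: uniformly ticked MAP and infusion-rate series."""

    times: np.ndarray          # s, uniform spacing
    map_values: np.ndarray     # mmHg
    infusion_rates: np.ndarray # mL/min
    target: float              # mmHg

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.map_values, dtype=float)
        r = np.asarray(self.infusion_rates, dtype=float)
        if not (len(t) == len(m) == len(r)):
            raise ValueError("trace arrays must have equal length")
        if len(t) < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ValueError("trace times must be uniformly spaced")
        if self.target <= 0:
            raise ValueError("target must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "map_values", m)
        object.__setattr__(self, "infusion_rates", r)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Run duration in seconds (one tick past the last sample instant)."""
        return float(self.times[-1] - self.times[0] + self.dt)

    # -- I/O --------------------------------------------------------------

    def to_frame(self, sampled: np.ndarray | None = None) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "map_mmhg": self.map_values,
            "map_sampled_mmhg": self.map_values if sampled is None else sampled,
            "infusion_ml_min": self.infusion_rates,
        })

    def to_csv(self, path, sampled: np.ndarray | None = None) -> None:
        self.to_frame(sampled).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, target: float) -> "Trace":
        df = pd.read_csv(path, comment="#")
        return cls(times=df["time_s"].to_numpy(),
                   map_values=df["map_mmhg"].to_numpy(),
                   infusion_rates=df["infusion_ml_min"].to_numpy(),
                   target=target)


@dataclass(frozen=True)
class MetricSet:
    """The thirteen per-run performance metrics."""

    mdpe: float              # %
    mdape: float             # %
    mdape_ss: float          # %
    target_overshoot: float  # %
    effectiveness: float     # %
    wobble: float            # %
    divergence: float        # %/h (signed)
    rise_time: float         # min
    mean_inf: float          # mL/min
    area_above: float        # min (>= 0)
    area_below: float        # min (<= 0)
    max_rate_change: float   # mL/min^2
    var_inf_rate: float      # mL/min

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def performance_error(map_mmhg, target: float):
    """Performance error in percent of target: ``100·(MAP − target)/target``."""
    if target <= 0:
        raise ValueError("target must be > 0")
    return 100.0 * (np.asarray(map_mmhg, dtype=float) - target) / target


# -- individual metrics ----------------------------------------------------


def mdpe(trace: Trace) -> float:
    return float(np.median(performance_error(trace.map_values, trace.target)))


def mdape(trace: Trace) -> float:
    return float(np.median(np.abs(performance_error(trace.map_values, trace.target))))


def wobble(trace: Trace) -> float:
    pe = performance_error(trace.map_values, trace.target)
    return float(np.median(np.abs(pe - np.median(pe))))


def rise_time(trace: Trace) -> float:
    """Minutes until MAP first reaches 90% of target; run duration if never.

    The crossing is linearly interpolated between ticks so that analytically
    constructed ramps evaluate to their exact intersection time.
    """
    threshold = RISE_FRACTION * trace.target
    m = trace.map_values
    above = np.nonzero(m >= threshold)[0]
    if len(above) == 0:
        return trace.duration / 60.0
    i = int(above[0])
    if i == 0:
        return float(trace.times[0]) / 60.0
    t0, t1 = trace.times[i - 1], trace.times[i]
    m0, m1 = m[i - 1], m[i]
    t_cross = t0 + (threshold - m0) / (m1 - m0) * (t1 - t0)
    return float(t_cross) / 60.0


def _steady_state_mask(trace: Trace) -> np.ndarray:
    rt_s = rise_time(trace) * 60.0
    if rt_s >= trace.duration:  # never reached: fall back to the final third
        return trace.times >= trace.times[0] + 2.0 / 3.0 * trace.duration
    return trace.times > rt_s


def mdape_ss(trace: Trace) -> float:
    mask = _steady_state_mask(trace)
    pe = performance_error(trace.map_values[mask], trace.target)
    return float(np.median(np.abs(pe)))


def effectiveness(trace: Trace) -> float:
    within = np.abs(trace.map_values - trace.target) <= EFFECTIVENESS_BAND_MMHG
    return float(100.0 * np.count_nonzero(within) / len(within))


def target_overshoot(trace: Trace) -> float:
    peak = float(np.max(trace.map_values))
    return max(0.0, 100.0 * (peak - trace.target) / trace.target)


def area_above(trace: Trace) -> float:
    pe_frac = performance_error(trace.map_values, trace.target) / 100.0
    return float(np.sum(np.maximum(pe_frac, 0.0)) * trace.dt / 60.0)


def area_below(trace: Trace) -> float:
    mask = _steady_state_mask(trace)
    pe_frac = performance_error(trace.map_values[mask], trace.target) / 100.0
    return float(-np.sum(np.maximum(-pe_frac, 0.0)) * trace.dt / 60.0)


def divergence(trace: Trace) -> float:
    """Least-squares slope of |PE| vs time (hours) over the final 10% of the run."""
    tail = trace.times >= trace.times[-1] - DIVERGENCE_TAIL_FRACTION * trace.duration
    if np.count_nonzero(tail) < 3:
        return float("nan")
    t_h = trace.times[tail] / 3600.0
    ape = np.abs(performance_error(trace.map_values[tail], trace.target))
    slope = np.polyfit(t_h, ape, 1)[0]
    return float(slope)


def mean_inf(trace: Trace) -> float:
    return float(np.mean(trace.infusion_rates))


def max_rate_change(trace: Trace) -> float:
    """Max |d/dt| (per minute) of the 3-min moving-averaged infusion rate."""
    w = max(1, int(round(RATE_SMOOTH_WINDOW_S / trace.dt)))
    smooth = pd.Series(trace.infusion_rates).rolling(w).mean().dropna().to_numpy()
    if len(smooth) < 2:
        return 0.0
    dt_min = trace.dt / 60.0
    return float(np.max(np.abs(np.diff(smooth))) / dt_min)


def var_inf_rate(trace: Trace) -> float:
    """Median over sliding 2-min windows of the within-window rate SD."""
    w = max(2, int(round(VAR_WINDOW_S / trace.dt)))
    sds = pd.Series(trace.infusion_rates).rolling(w).std(ddof=0).dropna().to_numpy()
    if len(sds) == 0:
        return 0.0
    return float(np.median(sds))


def compute_all_metrics(trace: Trace) -> MetricSet:
    """Assemble the full metric set for one run (deterministic)."""
    return MetricSet(
        mdpe=mdpe(trace),
        mdape=mdape(trace),
        mdape_ss=mdape_ss(trace),
        target_overshoot=target_overshoot(trace),
        effectiveness=effectiveness(trace),
        wobble=wobble(trace),
        divergence=divergence(trace),
        rise_time=rise_time(trace),
        mean_inf=mean_inf(trace),
        area_above=area_above(trace),
        area_below=area_below(trace),
        max_rate_change=max_rate_change(trace),
        var_inf_rate=var_inf_rate(trace),
    )
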