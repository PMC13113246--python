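"""Closed-loop orchestration: one run, the 10x3 battery, reference traces.

A run couples the virtual patient (integrated at ``plant_dt``) with a
controller invoked every ``controller_tick`` on the zero-order-held MAP
sample; commanded rates pass through the plant's dose lag. The battery runs
all ten shipped configurations over the three starting-pressure scenarios
(35/45/55 mmHg), computes the metric panels and feeds them to the scoring
pipeline.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from . import __version__
from .config import config_hash, load_config
from .controllers import Controller, make_controller
from .metrics import MetricSet, Trace, compute_all_metrics
from .plant import Plant, PlantParams
from . import scoring

__all__ = ["ScenarioConfig", "RunRecord", "run_closed_loop", "run_battery",
           "BatteryResult", "generate_reference_traces"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioConfig:
    start_map: float
    target_map: float = 65.0
    duration_min: float = 30.0
    hemorrhage_rate: float = 10.0
    controller_tick_s: float = 10.0
    plant_dt_s: float = 0.25
    seed: int = 0
    noise: bool = False

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration must be > 0")
        if self.controller_tick_s < self.plant_dt_s:
            raise ValueError("controller_tick must be >= plant_dt")
        if self.target_map <= self.start_map:
            raise ValueError("target must exceed the starting MAP")


@dataclass(frozen=True)
class RunRecord:
    scenario: ScenarioConfig
    controller_id: str
    trace: Trace
    sampled_map: np.ndarray
    metrics: MetricSet
    config_hash: str
    version: str
    wall_time_s: float


def _plant_params(cfg_plant: dict, scenario: ScenarioConfig) -> PlantParams:
    params = PlantParams(baseline_map=scenario.start_map,
                         hemorrhage_rate=scenario.hemorrhage_rate,
                         **cfg_plant)
    if not scenario.noise:
        params = _dc_replace(params, noise_sd=0.0)
    return params


def run_closed_loop(controller: Controller, scenario: ScenarioConfig,
                    plant_cfg: dict | None = None,
                    controller_id: str = "custom") -> RunRecord:
    """Simulate one controller over one scenario; deterministic under a seed."""
    t0 = _time.perf_counter()
    cfg_plant = dict(plant_cfg or load_config()["plant"])
    params = _plant_params(cfg_plant, scenario)
    plant = Plant(params=params, seed=scenario.seed)
    controller.reset()
    plant.apply_dose(controller.current_rate)

    tick = scenario.controller_tick_s
    n_ticks = int(round(scenario.duration_min * 60.0 / tick))
    steps_per_tick = int(round(tick / scenario.plant_dt_s))

    times = np.empty(n_ticks)
    map_true = np.empty(n_ticks)
    map_sampled = np.empty(n_ticks)
    rates = np.empty(n_ticks)
    try:
        for k in range(n_ticks):
            sampled = plant.sample(tick)
            rate = controller.tick(sampled, scenario.target_map)
            plant.apply_dose(rate)
            times[k] = plant.time
            map_true[k] = plant.map_true
            map_sampled[k] = sampled
            rates[k] = rate
            for _ in range(steps_per_tick):
                plant.step(scenario.plant_dt_s)
    except Exception:
        log.exception("controller %s aborted at t=%.1f s", controller_id,
                      plant.time)
        raise
    trace = Trace(times=times, map_values=map_true, infusion_rates=rates,
                  target=scenario.target_map)
    return RunRecord(
        scenario=scenario, controller_id=controller_id, trace=trace,
        sampled_map=map_sampled, metrics=compute_all_metrics(trace),
        config_hash=config_hash({"plant": cfg_plant, "scenario": vars(scenario)}),
        version=__version__, wall_time_s=_time.perf_counter() - t0)


@dataclass(frozen=True)
class BatteryResult:
    records: list
    panels: dict              # scenario (int) -> metric DataFrame
    terms: dict               # scenario (int) -> term DataFrame
    average_terms: pd.DataFrame
    scores: pd.Series         # study-average overall score per config
    ranking: list

    def summary(self) -> str:
        lines = ["study-average overall scores (lower is better):"]
        for pos, cfg in enumerate(self.ranking, 1):
            lines.append(f"  {pos:2d}. {cfg:24s} {self.scores[cfg]:10.2f}")
        return "\n".join(lines)


def run_battery(config: dict | None = None, seed: int | None = None,
                replicates: int = 1) -> BatteryResult:
    """All registered configurations over the three scenarios, plus scoring.

    With ``replicates > 1`` each (controller, scenario) pair is re-run with
    offset seeds and the per-run metrics are averaged before scoring.
    """
    cfg = config or load_config()
    sc = cfg["scenario"]
    base_seed = sc.get("seed", 0) if seed is None else seed
    records = []
    panels: dict[int, pd.DataFrame] = {}
    for start in sc["start_maps"]:
        rows = {}
        for cid, profile in cfg["controllers"].items():
            metric_rows = []
            for rep in range(replicates):
                scenario = ScenarioConfig(
                    start_map=float(start), target_map=sc["target_map"],
                    duration_min=sc["duration_min"],
                    hemorrhage_rate=sc["hemorrhage_rate"],
                    controller_tick_s=sc["controller_tick_s"],
                    plant_dt_s=sc["plant_dt_s"],
                    seed=base_seed + 1000 * rep,
                    noise=bool(cfg["plant"].get("noise_sd", 0.0)) and replicates > 1)
                controller = make_controller(profile, dt=sc["controller_tick_s"])
                rec = run_closed_loop(controller, scenario,
                                      plant_cfg=cfg["plant"], controller_id=cid)
                records.append(rec)
                metric_rows.append(rec.metrics.to_dict())
            rows[cid] = pd.DataFrame(metric_rows).mean().to_dict()
        panels[int(start)] = pd.DataFrame.from_dict(rows, orient="index")

    terms = {s: scoring.compute_terms(p) for s, p in panels.items()}
    avg_terms = scoring.study_average(terms)
    scores = avg_terms["overall"]
    return BatteryResult(records=records, panels=panels, terms=terms,
                         average_terms=avg_terms, scores=scores,
                         ranking=scoring.rank_configurations(scores))


# -- analytically characterized reference traces ---------------------------


def generate_reference_traces(seed: int = 0, dt_s: float = 10.0,
                              duration_min: float = 30.0,
                              target: float = 65.0) -> dict:
    """Constructed traces with closed-form metric values.

    Returns ``{name: (Trace, expected)}`` where ``expected`` maps metric
    names to analytically derived values (a subset per trace). The traces
    are deterministic; ``seed`` is accepted for interface symmetry with the
    simulation paths.
    """
    del seed  # all reference traces are deterministic
    n = int(round(duration_min * 60.0 / dt_s))
    t = np.arange(n) * dt_s
    t_min = t / 60.0
    out: dict[str, tuple[Trace, dict]] = {}

    # constant at target, constant rate
    rate0 = 0.5
    tr = Trace(times=t, map_values=np.full(n, target),
               infusion_rates=np.full(n, rate0), target=target)
    out["constant_at_target"] = (tr, {
        "mdpe": 0.0, "mdape": 0.0, "mdape_ss": 0.0, "wobble": 0.0,
        "target_overshoot": 0.0, "effectiveness": 100.0, "rise_time": 0.0,
        "area_above": 0.0, "area_below": 0.0, "divergence": 0.0,
        "mean_inf": rate0, "max_rate_change": 0.0, "var_inf_rate": 0.0,
    })

    # linear climb 35 -> target over 10 min, then hold; ramp infusion
    climb_min = 10.0
    slope = (target - 35.0) / climb_min           # mmHg/min
    m = np.where(t_min < climb_min, 35.0 + slope * t_min, target)
    r = 0.01 * t_min                              # mL/min, slope 0.01 / min
    tr = Trace(times=t, map_values=m, infusion_rates=r, target=target)
    out["linear_climb"] = (tr, {
        "rise_time": (0.9 * target - 35.0) / slope,   # line intersection
        "target_overshoot": 0.0, "area_above": 0.0,
        "max_rate_change": 0.01,
        "mean_inf": 0.01 * (t_min[0] + t_min[-1]) / 2.0,
    })

    # plateaus: +5% for 4 min, -10% for 3 min, otherwise at target
    m = np.full(n, target)
    m[(t_min >= 10) & (t_min < 14)] = target * 1.05
    m[(t_min >= 20) & (t_min < 23)] = target * 0.90
    tr = Trace(times=t, map_values=m, infusion_rates=np.full(n, rate0),
               target=target)
    out["plateaus"] = (tr, {
        "target_overshoot": 5.0,
        "area_above": 0.05 * 4.0,     # rectangle: 5% x 4 min
        "area_below": -0.10 * 3.0,    # rectangle: -10% x 3 min (post-rise)
        "rise_time": 0.0,
    })

    # half in band / half out: effectiveness 50
    m = np.where(t_min < duration_min / 2, target, target - 10.0)
    tr = Trace(times=t, map_values=m, infusion_rates=np.full(n, rate0),
               target=target)
    out["half_in_band"] = (tr, {"effectiveness": 50.0})

    # |PE| rising 1 %/6 min through the tail window: divergence +10 %/h
    pe = np.where(t_min < duration_min - 6.0, 1.0,
                  1.0 + (t_min - (duration_min - 6.0)) / 6.0)
    m = target * (1.0 - pe / 100.0)
    tr = Trace(times=t, map_values=m, infusion_rates=np.full(n, rate0),
               target=target)
    out["diverging_tail"] = (tr, {"divergence": 10.0})

    # square-wave infusion, 2-min period, levels 0 / 0.2
    r = np.where((t_min % 2.0) < 1.0, 0.0, 0.2)
    tr = Trace(times=t, map_values=np.full(n, target), infusion_rates=r,
               target=target)
    out["square_wave_rate"] = (tr, {"var_inf_rate": 0.1, "mean_inf": 0.1})

    # overshoot-and-settle: exponential approach with a 10% peak
    peak_t = 8.0
    m = np.where(
        t_min < peak_t, 35.0 + (1.10 * target - 35.0) * (t_min / peak_t),
        target + 0.10 * target * np.exp(-(t_min - peak_t) / 4.0))
    tr = Trace(times=t, map_values=m, infusion_rates=np.full(n, rate0),
               target=target)
    out["overshoot_settle"] = (tr, {"target_overshoot": 10.0})

    return out
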