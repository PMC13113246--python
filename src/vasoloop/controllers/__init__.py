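"""Controller architectures and the profile registry.

Ten shipped configurations: {pid, stepfis, anfis, adrc, pfc} ×
{aggressive, conservative}. Each controller exposes ``reset()`` and
``tick(measured, target) -> infusion rate`` and is constructed from a
profile dictionary (see ``vasoloop.data/default_config.yaml``).
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

from .pid import PidController, PidTuning, delay_filter_step
from .adrc import AdrcController, AdrcTuning, td_step, eso_step
from .stepfis import (StepFisController, StepFisTuning, MembershipSet,
                      FuzzyRule, fis_output, adapt_step, load_rule_base)
from .anfis import (AnfisController, AnfisTuning, AnfisModel, SafeguardParams,
                    anfis_forward, anfis_train, safeguard_scale,
                    load_packaged_model)
from .pfc import PfcController, PfcTuning

__all__ = [
    "Controller", "make_controller",
    "PidController", "PidTuning", "delay_filter_step",
    "AdrcController", "AdrcTuning", "td_step", "eso_step",
    "StepFisController", "StepFisTuning", "MembershipSet", "FuzzyRule",
    "fis_output", "adapt_step", "load_rule_base",
    "AnfisController", "AnfisTuning", "AnfisModel", "SafeguardParams",
    "anfis_forward", "anfis_train", "safeguard_scale", "load_packaged_model",
    "PfcController", "PfcTuning",
]


@runtime_checkable
class Controller(Protocol):
    current_rate: float

    def reset(self) -> None: ...
    def tick(self, measured: float, target: float) -> float: ...


def _mfset(cfg: dict) -> MembershipSet:
    return MembershipSet(negative=tuple(cfg["negative"]),
                         zero=tuple(cfg["zero"]),
                         positive=tuple(cfg["positive"]))


def make_controller(profile: dict, dt: float) -> Controller:
    """Build a controller from a profile dict with a ``type`` key."""
    cfg = dict(profile)
    kind = cfg.pop("type")
    initial_rate = cfg.pop("initial_rate", 0.0)
    if kind == "pid":
        return PidController(PidTuning(**cfg), dt=dt, initial_rate=initial_rate)
    if kind == "adrc":
        return AdrcController(AdrcTuning(**cfg), dt=dt, initial_rate=initial_rate)
    if kind == "stepfis":
        for key in ("error_mf", "rate_mf"):
            if key in cfg:
                cfg[key] = _mfset(cfg[key])
        return StepFisController(StepFisTuning(**cfg), dt=dt,
                                 initial_rate=initial_rate)
    if kind == "anfis":
        safeguard = SafeguardParams(**cfg.pop("safeguard"))
        model = cfg.pop("model", None)
        tuning = AnfisTuning(safeguard=safeguard, model=model, **cfg)
        return AnfisController(tuning, dt=dt, initial_rate=initial_rate)
    if kind == "pfc":
        return PfcController(PfcTuning(**cfg), dt=dt, initial_rate=initial_rate)
    raise ValueError(f"unknown controller type: {kind!r}")
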