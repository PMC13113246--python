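"""AN-FIS: trainable first-order Sugeno dosing network with output safeguards.

Architecture: two inputs (percent-of-target MAP error, positive below
target, and its rate of change), three generalized-bell membership functions
per input, the full 3x3 rule grid (9 rules) and linear consequents
``p·e + q·ė + r``. Firing strengths are products of the two memberships,
normalized to sum to one before mixing the consequents.

Training is the classic hybrid scheme: with premises frozen, the consequent
parameters are solved exactly by least squares (ridge fallback if the system
is rank deficient); premise parameters then take a gradient step (central
finite differences — 18 parameters, so this is cheap). A 70/30 train/test
split is applied internally; training stops when the error stabilizes or at
100 epochs.

The controller wraps a trained model with a safeguard stage: the raw dose is
scaled by ``clamp(1 + gain·error, lo, hi)`` and clamped to dose bounds, so
dosing is proportionally weighted by the deviation from target while the
magnitude of any adjustment stays bounded. Aggressive vs conservative
profiles share the trained network and differ only in safeguard parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "AnfisModel", "SafeguardParams", "AnfisTuning", "AnfisController",
    "anfis_forward", "anfis_train", "safeguard_scale", "load_packaged_model",
    "TrainResult",
]

log = logging.getLogger(__name__)

N_MF = 3          # membership functions per input
N_RULES = N_MF * N_MF
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class AnfisModel:
    """Gbell premise parameters and linear consequents.

    ``premises`` has shape (2, 3, 3): per input, per membership function,
    the gbell triple (a, b, c) with membership ``1/(1+|(x-c)/a|^(2b))``.
    ``consequents`` has shape (9, 3): per rule, (p, q, r).
    """

    premises: np.ndarray
    consequents: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.premises, dtype=float)
        c = np.asarray(self.consequents, dtype=float)
        if p.shape != (2, N_MF, 3):
            raise ValueError(f"premises must have shape (2, {N_MF}, 3)")
        if c.shape != (N_RULES, 3):
            raise ValueError(f"consequents must have shape ({N_RULES}, 3)")
        if np.any(p[:, :, 0] <= 0) or np.any(p[:, :, 1] <= 0):
            raise ValueError("gbell a and b parameters must be > 0")
        object.__setattr__(self, "premises", p)
        object.__setattr__(self, "consequents", c)

    # -- JSON schema -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": SCHEMA_VERSION,
            "premises": self.premises.tolist(),
            "consequents": self.consequents.tolist(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AnfisModel":
        obj = json.loads(text)
        if obj.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        return cls(premises=np.array(obj["premises"]),
                   consequents=np.array(obj["consequents"]))


def _gbell(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return 1.0 / (1.0 + np.abs((x - c) / a) ** (2.0 * b))


def _norm_strengths(premises: np.ndarray, e, edot) -> np.ndarray:
    """Normalized firing strengths, shape (N, 9). Strictly positive for gbell."""
    e = np.atleast_1d(np.asarray(e, dtype=float))
    edot = np.atleast_1d(np.asarray(edot, dtype=float))
    mu_e = np.stack([_gbell(e, *premises[0, i]) for i in range(N_MF)], axis=1)
    mu_d = np.stack([_gbell(edot, *premises[1, j]) for j in range(N_MF)], axis=1)
    w = (mu_e[:, :, None] * mu_d[:, None, :]).reshape(len(e), N_RULES)
    total = w.sum(axis=1, keepdims=True)
    assert np.all(total > 0), "gbell strengths are strictly positive"
    return w / total


def anfis_forward(model: AnfisModel, error, error_rate):
    """Network output (dose, mL/min) for scalar or vector inputs."""
    e = np.atleast_1d(np.asarray(error, dtype=float))
    d = np.atleast_1d(np.asarray(error_rate, dtype=float))
    wbar = _norm_strengths(model.premises, e, d)
    rule_out = (model.consequents[None, :, 0] * e[:, None]
                + model.consequents[None, :, 1] * d[:, None]
                + model.consequents[None, :, 2])
    out = (wbar * rule_out).sum(axis=1)
    return float(out[0]) if np.isscalar(error) or np.ndim(error) == 0 else out


# -- hybrid training -------------------------------------------------------


@dataclass(frozen=True)
class TrainResult:
    model: AnfisModel
    train_rmse: float
    test_rmse: float
    epochs_run: int


def _design_matrix(premises: np.ndarray, X: np.ndarray) -> np.ndarray:
    wbar = _norm_strengths(premises, X[:, 0], X[:, 1])
    feats = np.stack([X[:, 0], X[:, 1], np.ones(len(X))], axis=1)  # (N, 3)
    return (wbar[:, :, None] * feats[:, None, :]).reshape(len(X), N_RULES * 3)


def _solve_consequents(premises: np.ndarray, X: np.ndarray,
                       y: np.ndarray) -> np.ndarray:
    A = _design_matrix(premises, X)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        log.warning("rank-deficient consequent system; using ridge fallback")
        lam = 1e-6
        coef = np.linalg.solve(A.T @ A + lam * np.eye(A.shape[1]), A.T @ y)
    else:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef.reshape(N_RULES, 3)


def _rmse(premises, consequents, X, y) -> float:
    model = AnfisModel(premises=premises, consequents=consequents)
    pred = anfis_forward(model, X[:, 0], X[:, 1])
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def _init_premises(X: np.ndarray) -> np.ndarray:
    """Grid initialization: centers at data quantiles, width = half-spacing."""
    premises = np.empty((2, N_MF, 3))
    for k in range(2):
        qs = np.quantile(X[:, k], [0.1, 0.5, 0.9])
        span = max(qs[-1] - qs[0], 1e-3)
        a = span / (N_MF - 1) / 2 * 1.5
        for i in range(N_MF):
            premises[k, i] = (a, 2.0, qs[i])
    return premises


def anfis_train(data: np.ndarray, seed: int = 0, max_epochs: int = 100,
                lr: float = 0.02, tol: float = 1e-5,
                patience: int = 10) -> TrainResult:
    """Fit a 9-rule model to ``(error, error_rate, dose)`` triples.

    Alternates an exact least-squares consequent solve (premises frozen)
    with a finite-difference gradient step on the 18 premise parameters.
    The least-squares stage can never increase the training RMSE (asserted
    per epoch); early stopping triggers when the best RMSE has not improved
    by ``tol`` for ``patience`` epochs.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3 or len(data) < 30:
        raise ValueError("need >= 30 (error, error_rate, dose) triples")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(data))
    n_train = int(round(0.7 * len(data)))
    train, test = data[idx[:n_train]], data[idx[n_train:]]
    X, y = train[:, :2], train[:, 2]

    premises = _init_premises(X)
    consequents = np.zeros((N_RULES, 3))
    scales = np.array([max(np.std(X[:, k]), 1e-3) for k in range(2)])

    best = np.inf
    stale = 0
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        before = _rmse(premises, consequents, X, y)
        consequents = _solve_consequents(premises, X, y)
        after = _rmse(premises, consequents, X, y)
        assert after <= before + 1e-9, "LS step must not increase training RMSE"

        if after < best - tol:
            best, stale = after, 0
        else:
            stale += 1
            if stale >= patience:
                break

        # central-difference gradient on premise parameters
        grad = np.zeros_like(premises)
        for k in range(2):
            for i in range(N_MF):
                for p in range(3):
                    h = 1e-4 * (scales[k] if p != 1 else 1.0)
                    for sgn in (+1, -1):
                        pert = premises.copy()
                        pert[k, i, p] += sgn * h
                        pert[:, :, 0] = np.maximum(pert[:, :, 0], 1e-6)
                        pert[:, :, 1] = np.maximum(pert[:, :, 1], 0.1)
                        grad[k, i, p] += sgn * _rmse(pert, consequents, X, y)
                    grad[k, i, p] /= 2 * h
        gnorm = np.linalg.norm(grad)
        if gnorm > 0:
            step = lr * np.array([scales[0], scales[1]])[:, None, None]
            premises = premises - step * grad / gnorm
            premises[:, :, 0] = np.maximum(premises[:, :, 0], 1e-6)
            premises[:, :, 1] = np.clip(premises[:, :, 1], 0.1, 10.0)

    consequents = _solve_consequents(premises, X, y)
    model = AnfisModel(premises=premises, consequents=consequents)
    train_rmse = _rmse(premises, consequents, X, y)
    test_rmse = _rmse(premises, consequents, test[:, :2], test[:, 2])
    return TrainResult(model=model, train_rmse=train_rmse,
                       test_rmse=test_rmse, epochs_run=epoch)


# -- reference training data -----------------------------------------------

#: Teacher dosing policy used to label plant-sweep states (mL/min): a smooth
#: logistic escalation in the error, led by the error rate so that a rapidly
#: rising MAP (negative error rate) pulls the commanded dose down before the
#: target is crossed. Calibrated to the virtual patient's equilibrium doses
#: (~0.7 mL/min holding from a 55 mmHg baseline, ~2-3 from 35 mmHg).
TEACHER_DOSE_MAX = 3.5   # mL/min asymptote
TEACHER_E0 = 3.71        # % error at the sigmoid midpoint
TEACHER_ESCALE = 3.5     # % error per logistic unit
TEACHER_RATE_LEAD = 25.0 # s of error-rate lead folded into the error


def teacher_dose(error_pct, error_rate):
    """Label policy for training data (error positive below target)."""
    x = (np.asarray(error_pct) + TEACHER_RATE_LEAD * np.asarray(error_rate)
         - TEACHER_E0) / TEACHER_ESCALE
    return TEACHER_DOSE_MAX / (1.0 + np.exp(-x))


def generate_training_data(seed: int = 0, tick_s: float = 10.0) -> np.ndarray:
    """(error, error_rate, dose) triples from virtual-patient dose sweeps.

    Runs open-loop staircase dose sweeps on the virtual patient across the
    three scenario baselines, records the percent-of-target error and its
    rate at the controller cadence, and labels each state with
    :func:`teacher_dose`. Mild jitter (seeded) spreads the staircase levels
    so the input box is well covered.
    """
    from ..plant import Plant, PlantParams

    rng = np.random.default_rng(seed)
    target = 65.0
    rows = []
    for baseline in (35.0, 45.0, 55.0):
        for top in (1.0, 2.5, 4.5):
            params = PlantParams(baseline_map=baseline)
            plant = Plant(params=params, seed=int(rng.integers(2 ** 31)))
            prev_err = None
            n_ticks = int(round(30 * 60 / tick_s))
            for k in range(n_ticks):
                # staircase up through the dosing range with jitter
                level = top * min(1.0, k / (0.6 * n_ticks))
                plant.apply_dose(max(0.0, level * (1 + 0.1 * rng.standard_normal())))
                for _ in range(int(round(tick_s / 0.25))):
                    plant.step(0.25)
                err = 100.0 * (target - plant.map_true) / target
                if prev_err is not None:
                    edot = (err - prev_err) / tick_s
                    rows.append((err, edot, float(teacher_dose(err, edot))))
                prev_err = err
    return np.asarray(rows)


# -- safeguards and controller ---------------------------------------------


@dataclass(frozen=True)
class SafeguardParams:
    """Error-proportional output scaling with bounded multiplier."""

    gain: float             # per percent of target error
    mult_lo: float = 0.5
    mult_hi: float = 1.5
    dose_min: float = 0.0
    dose_max: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.mult_lo < 1 < self.mult_hi:
            raise ValueError("multiplier bounds must satisfy 0 < lo < 1 < hi")
        if self.dose_min < 0 or self.dose_max <= self.dose_min:
            raise ValueError("invalid dose bounds")


def safeguard_scale(raw_dose: float, error: float,
                    params: SafeguardParams) -> float:
    """Scale the raw dose by ``clamp(1 + gain·error, lo, hi)``; clamp to bounds."""
    if raw_dose < 0:
        raise ValueError("raw_dose must be >= 0")
    mult = min(max(1.0 + params.gain * error, params.mult_lo), params.mult_hi)
    return min(max(raw_dose * mult, params.dose_min), params.dose_max)


@dataclass(frozen=True)
class AnfisTuning:
    safeguard: SafeguardParams
    model: AnfisModel | None = None  # None: load the packaged model
    #: first-order smoothing of the commanded rate (fraction of the new
    #: command blended in per tick); tempers the static policy's loop gain
    #: against the plant's response lag
    smooth_alpha: float = 0.3


def load_packaged_model() -> AnfisModel:
    text = resources.files("vasoloop.data").joinpath("anfis_model.json").read_text()
    return AnfisModel.from_json(text)


@dataclass
class AnfisController:
    tuning: AnfisTuning
    dt: float
    initial_rate: float = 0.0

    current_rate: float = field(init=False)
    _prev_error: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.current_rate = self.initial_rate
        self._model = self.tuning.model or load_packaged_model()

    def reset(self) -> None:
        self.current_rate = self.initial_rate
        self._prev_error = None

    def tick(self, measured: float, target: float) -> float:
        if target <= 0:
            raise ValueError("target must be > 0")
        error = 100.0 * (target - measured) / target  # positive below target
        if self._prev_error is None:
            self._prev_error = error
        error_rate = (error - self._prev_error) / self.dt
        self._prev_error = error

        raw = max(0.0, anfis_forward(self._model, error, error_rate))
        command = safeguard_scale(raw, error, self.tuning.safeguard)
        a = self.tuning.smooth_alpha
        self.current_rate = (1.0 - a) * self.current_rate + a * command
        return self.current_rate
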