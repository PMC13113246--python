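"""Aggregate scoring and ranking of controller configurations.

Per scenario, every metric is normalized to the median of its absolute values
across the ten controller configurations, making each term dimensionless and
robust to poor-performing outliers. The normalized metrics are grouped into
five terms:

* ``stable``       = (MDAPE_SS + Wobble + |Divergence|) / 3
* ``overshoot``    = (TargetOvershoot + AreaAbove) / 3
* ``undershoot``   = (RiseTime + |AreaBelow|) / 3
* ``infusion``     = (MeanInf + MaxRateChange + VarInfRate) / 3
* ``effectiveness_term`` = MDAPE / Effectiveness

and combined into

    overall = (stable + overshoot + undershoot + infusion) × effectiveness_term

where lower is better. The divisor for the two-metric overshoot/undershoot
terms is 3 by default: the published benchmark term values are reproducible
only under that convention, although the term definitions are sometimes
written with a divisor of 2 (available via ``divisor_two_metric=2``).

Scores are computed per scenario (starting MAP 35/45/55 mmHg) and averaged
across the three scenarios for the study-level ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CONFIG_IDS",
    "SCENARIOS",
    "WeightSet",
    "normalize_to_median",
    "compute_terms",
    "overall_score",
    "study_average",
    "rank_configurations",
    "sensitivity_analysis",
    "load_reference_panel",
    "load_reference_terms",
]

log = logging.getLogger(__name__)

CONFIG_IDS = (
    "pid_aggressive", "pid_conservative",
    "stepfis_aggressive", "stepfis_conservative",
    "anfis_aggressive", "anfis_conservative",
    "adrc_aggressive", "adrc_conservative",
    "pfc_aggressive", "pfc_conservative",
)
SCENARIOS = (35, 45, 55)

METRIC_COLUMNS = (
    "mdpe", "mdape", "mdape_ss", "target_overshoot", "effectiveness",
    "wobble", "divergence", "rise_time", "mean_inf", "area_above",
    "area_below", "max_rate_change", "var_inf_rate",
)

TERM_COLUMNS = ("stable", "overshoot", "undershoot", "infusion",
                "effectiveness_term", "overall")


@dataclass(frozen=True)
class WeightSet:
    """Positive weights for the five aggregate terms (default all 1)."""

    stable: float = 1.0
    overshoot: float = 1.0
    undershoot: float = 1.0
    infusion: float = 1.0
    effectiveness: float = 1.0

    def __post_init__(self) -> None:
        if min(self.stable, self.overshoot, self.undershoot,
               self.infusion, self.effectiveness) <= 0:
            raise ValueError("weights must be strictly positive")


def normalize_to_median(values: pd.Series | np.ndarray) -> pd.Series:
    """Normalize |values| by the median of |values| across configurations.

    If the median is zero (a metric every controller nearly avoids, e.g. area
    above target in conservative panels), zeros map to 0 and non-zeros are
    normalized by the smallest non-zero absolute value instead.
    """
    v = pd.Series(values, dtype=float).abs()
    med = float(v.median())
    if med > 0:
        return v / med
    nonzero = v[v > 0]
    if nonzero.empty:
        log.warning("all-zero metric vector: normalized values set to 0")
        return v
    log.info("zero median in metric vector: using smallest non-zero |value|")
    return v / float(nonzero.min())


def _validate_panel(panel: pd.DataFrame) -> None:
    missing = set(METRIC_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing metrics: {sorted(missing)}")
    if len(panel) < 2:
        raise ValueError("panel needs at least two configurations")
    if panel[list(METRIC_COLUMNS)].isna().any().any():
        raise ValueError("panel contains missing metric values")


def compute_terms(panel: pd.DataFrame, divisor_two_metric: int = 3) -> pd.DataFrame:
    """Aggregate terms for every configuration of one scenario panel.

    Parameters
    ----------
    panel:
        DataFrame indexed by configuration id with the thirteen metric
        columns (one scenario).
    divisor_two_metric:
        Divisor applied to the two-metric overshoot and undershoot sums;
        3 (default) matches the published benchmark values.

    Returns
    -------
    DataFrame indexed like ``panel`` with columns ``stable``, ``overshoot``,
    ``undershoot``, ``infusion``, ``effectiveness_term`` and ``overall``
    (equal-weight overall score).
    """
    _validate_panel(panel)
    if divisor_two_metric not in (2, 3):
        raise ValueError("divisor_two_metric must be 2 or 3")
    n = normalize_to_median
    stable = (n(panel["mdape_ss"]) + n(panel["wobble"]) + n(panel["divergence"])) / 3
    overshoot = (n(panel["target_overshoot"]) + n(panel["area_above"])) / divisor_two_metric
    undershoot = (n(panel["rise_time"]) + n(panel["area_below"])) / divisor_two_metric
    infusion = (n(panel["mean_inf"]) + n(panel["max_rate_change"])
                + n(panel["var_inf_rate"])) / 3
    eff = n(panel["mdape"]) / n(panel["effectiveness"])
    terms = pd.DataFrame({
        "stable": stable, "overshoot": overshoot, "undershoot": undershoot,
        "infusion": infusion, "effectiveness_term": eff,
    })
    terms["overall"] = terms.apply(lambda r: overall_score(r), axis=1)
    return terms


def overall_score(terms, weights: WeightSet = WeightSet()) -> float:
    """Weighted aggregate score: (sum of four additive terms) × effectiveness."""
    additive = (weights.stable * terms["stable"]
                + weights.overshoot * terms["overshoot"]
                + weights.undershoot * terms["undershoot"]
                + weights.infusion * terms["infusion"])
    return float(additive * weights.effectiveness * terms["effectiveness_term"])


def study_average(per_scenario: dict[int, pd.Series | pd.DataFrame]):
    """Arithmetic mean across the three scenarios (scores or full term tables)."""
    if set(per_scenario) != set(SCENARIOS):
        raise ValueError(f"expected scenarios {SCENARIOS}, got {sorted(per_scenario)}")
    stacked = [pd.DataFrame(per_scenario[s]) for s in SCENARIOS]
    out = sum(stacked[1:], start=stacked[0].copy()) / len(stacked)
    return out.squeeze(axis=1) if out.shape[1] == 1 else out


def rank_configurations(scores: pd.Series) -> list[str]:
    """Configuration ids sorted ascending by score (ties: lexicographic id)."""
    df = scores.rename("score").rename_axis("config").reset_index()
    df = df.sort_values(["score", "config"], kind="mergesort")
    return df["config"].tolist()


def scores_from_terms(terms_by_scenario: dict[int, pd.DataFrame],
                      weights: WeightSet = WeightSet()) -> pd.Series:
    """Study-average overall score per configuration under given weights."""
    per = {
        s: t.apply(lambda r: overall_score(r, weights), axis=1)
        for s, t in terms_by_scenario.items()
    }
    return study_average(per)


def sensitivity_analysis(terms_by_scenario: dict[int, pd.DataFrame],
                         factors=(0.5, 1.0, 2.0)) -> pd.DataFrame:
    """Re-rank under per-term weight perturbations.

    Each of the five term weights is independently set to each factor (others
    held at 1); rankings are recomputed from the study-average scores. Returns
    a tidy frame with one row per (term, factor, rank position).
    """
    rows = []
    baseline = rank_configurations(scores_from_terms(terms_by_scenario))
    for term in ("stable", "overshoot", "undershoot", "infusion", "effectiveness"):
        for f in factors:
            w = WeightSet(**{term: f})
            ranking = rank_configurations(scores_from_terms(terms_by_scenario, w))
            for pos, cfg in enumerate(ranking, start=1):
                rows.append({
                    "term": term, "factor": f, "rank": pos, "config": cfg,
                    "changed": cfg != baseline[pos - 1],
                })
    return pd.DataFrame(rows)


# -- packaged reference fixtures -------------------------------------------


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("vasoloop.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_reference_panel(scenario: int) -> pd.DataFrame:
    """Packaged benchmark metric panel for one scenario, indexed by config id."""
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    df = _read_packaged(f"reference_panel_{scenario}mmhg.csv")
    return df.set_index("config")


def load_reference_terms() -> pd.DataFrame:
    """Packaged benchmark aggregate terms (per scenario and study average).

    Indexed by (scenario, term) where scenario is 35/45/55 or 'avg'; one
    column per configuration. See the file's comments for a caveat on the
    45/55 mmHg stable-term cells.
    """
    df = _read_packaged("reference_terms.csv")
    df["scenario"] = [int(s) if str(s).isdigit() else s
                      for s in df["scenario"]]
    return df.set_index(["scenario", "term"])
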