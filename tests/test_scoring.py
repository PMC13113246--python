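"""Median normalization, aggregate terms, ranking, sensitivity."""

import numpy as np
import pandas as pd
import pytest

from vasoloop import scoring
from vasoloop.scoring import (WeightSet, compute_terms, normalize_to_median,
                              overall_score, rank_configurations,
                              sensitivity_analysis, study_average)


class TestNormalization:
    def test_hand_computed_example(self, reference_panels):
        col = reference_panels[35]["mdape"]
        assert col.abs().median() == pytest.approx(0.54)
        normalized = normalize_to_median(col)
        assert normalized["pid_aggressive"] == pytest.approx(1.90 / 0.54)
        assert normalized["pid_aggressive"] == pytest.approx(3.52, abs=0.005)

    def test_equal_values_normalize_to_one(self):
        out = normalize_to_median(pd.Series([3.0] * 6))
        assert np.allclose(out, 1.0)

    def test_sign_invariance(self):
        a = normalize_to_median(pd.Series([1.0, -2.0, 3.0, -4.0]))
        b = normalize_to_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert np.allclose(a, b)

    def test_zero_median_guard(self):
        out = normalize_to_median(pd.Series([0.0, 0.0, 0.0, 0.2, 0.4]))
        assert list(out[:3]) == [0.0, 0.0, 0.0]
        assert out.iloc[3] == pytest.approx(1.0)   # smallest non-zero
        assert out.iloc[4] == pytest.approx(2.0)

    def test_all_zero_vector(self):
        out = normalize_to_median(pd.Series([0.0, 0.0, 0.0]))
        assert np.allclose(out, 0.0)


class TestTerms:
    def test_median_configuration_term_values(self):
        """A config sitting exactly at every metric median scores 1.0 on the
        three-metric terms and 2/3 on the two-metric terms (divisor 3)."""
        rng = np.random.default_rng(0)
        rows = {f"c{k}": {m: rng.uniform(1, 3)
                          for m in scoring.METRIC_COLUMNS} for k in range(9)}
        panel = pd.DataFrame.from_dict(rows, orient="index")
        panel.loc["median_cfg"] = panel.median()
        terms = compute_terms(panel)
        assert terms.loc["median_cfg", "stable"] == pytest.approx(1.0)
        assert terms.loc["median_cfg", "infusion"] == pytest.approx(1.0)
        assert terms.loc["median_cfg", "overshoot"] == pytest.approx(2 / 3)
        assert terms.loc["median_cfg", "undershoot"] == pytest.approx(2 / 3)
        terms2 = compute_terms(panel, divisor_two_metric=2)
        assert terms2.loc["median_cfg", "overshoot"] == pytest.approx(1.0)
        assert terms2.loc["median_cfg", "undershoot"] == pytest.approx(1.0)

    def test_scale_invariance_per_metric(self, reference_panels):
        panel = reference_panels[35]
        scaled = panel.copy()
        scaled["wobble"] = scaled["wobble"] * 7.0
        pd.testing.assert_frame_equal(compute_terms(panel),
                                      compute_terms(scaled))

    def test_missing_metric_rejected(self, reference_panels):
        broken = reference_panels[35].drop(columns=["wobble"])
        with pytest.raises(ValueError):
            compute_terms(broken)


class TestOverallScore:
    def test_printed_terms_reproduce_printed_score(self):
        terms = pd.Series({"stable": 3.08, "overshoot": 7.02,
                           "undershoot": 0.67, "infusion": 0.93,
                           "effectiveness_term": 3.47})
        assert overall_score(terms) == pytest.approx(40.60, abs=0.005)
        assert overall_score(terms) == pytest.approx(40.61, abs=0.05)

    def test_zero_terms_zero_score(self):
        terms = pd.Series(dict.fromkeys(
            ("stable", "overshoot", "undershoot", "infusion",
             "effectiveness_term"), 0.0))
        assert overall_score(terms) == 0.0

    def test_effectiveness_weight_is_multiplicative(self):
        terms = pd.Series({"stable": 1.0, "overshoot": 2.0, "undershoot": 0.5,
                           "infusion": 1.5, "effectiveness_term": 2.0})
        base = overall_score(terms)
        doubled = overall_score(terms, WeightSet(effectiveness=2.0))
        assert doubled == pytest.approx(2.0 * base)

    def test_weights_must_be_positive(self):
        with pytest.raises(ValueError):
            WeightSet(stable=0.0)


class TestAveragingAndRanking:
    def test_study_average_of_printed_scores(self):
        per = {35: pd.Series({"pid_aggressive": 40.61, "anfis_conservative": 1.29}),
               45: pd.Series({"pid_aggressive": 25.90, "anfis_conservative": 0.60}),
               55: pd.Series({"pid_aggressive": 6.24, "anfis_conservative": 0.12})}
        avg = study_average(per)
        assert avg["pid_aggressive"] == pytest.approx(24.25)
        assert avg["anfis_conservative"] == pytest.approx(0.67)

    def test_identical_scores_average_to_themselves(self):
        per = {s: pd.Series({"a": 2.5}) for s in (35, 45, 55)}
        assert study_average(per)["a"] == pytest.approx(2.5)

    def test_missing_scenario_rejected(self):
        with pytest.raises(ValueError):
            study_average({35: pd.Series({"a": 1.0}), 45: pd.Series({"a": 1.0})})

    def test_ranking_from_printed_averages(self, reference_terms):
        avg = reference_terms.xs("avg", level="scenario").loc["overall"]
        ranking = rank_configurations(avg)
        assert ranking[:3] == ["anfis_conservative", "stepfis_conservative",
                               "adrc_conservative"]
        assert avg[ranking[3]] > 2.0 * avg[ranking[2]]

    def test_ranking_order_independent(self, reference_terms):
        avg = reference_terms.xs("avg", level="scenario").loc["overall"]
        shuffled = avg.sample(frac=1.0, random_state=1)
        assert rank_configurations(avg) == rank_configurations(shuffled)


def terms_by_scenario_from_reference(reference_terms):
    out = {}
    for s in scoring.SCENARIOS:
        block = reference_terms.xs(s, level="scenario").T
        out[s] = block[["stable", "overshoot", "undershoot", "infusion",
                        "effectiveness_term"]]
    return out


class TestSensitivity:
    def test_unit_weights_match_baseline(self, reference_terms):
        terms = terms_by_scenario_from_reference(reference_terms)
        report = sensitivity_analysis(terms, factors=(1.0,))
        assert not report["changed"].any()

    def test_additive_weight_scaling_preserves_ranks(self, reference_terms):
        terms = terms_by_scenario_from_reference(reference_terms)
        base = scoring.rank_configurations(scoring.scores_from_terms(terms))
        w = WeightSet(stable=3.0, overshoot=3.0, undershoot=3.0, infusion=3.0)
        scaled = scoring.rank_configurations(
            scoring.scores_from_terms(terms, w))
        assert scaled == base
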