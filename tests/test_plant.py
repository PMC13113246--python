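"""Virtual-patient dynamics: dose-response, lag, drift, overshoot, noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from vasoloop.plant import (Plant, PlantParams, load_dose_table, rate_to_dose,
                            steady_state_map)


def params(**kw):
    defaults = dict(baseline_map=35.0, lag_time=0.0, overshoot_frac=0.0,
                    hemorrhage_rate=0.0, noise_sd=0.0)
    defaults.update(kw)
    return PlantParams(**defaults)


class TestSteadyState:
    def test_zero_dose_is_baseline(self):
        p = params()
        assert steady_state_map(0.0, p) == p.baseline_map

    def test_half_effect_dose(self):
        p = params(max_effect=40.0, half_effect_dose=1.0)
        assert steady_state_map(1.0, p) == pytest.approx(35.0 + 20.0)

    def test_saturating_form(self):
        p = params(max_effect=40.0, half_effect_dose=1.0)
        assert steady_state_map(3.0, p) == pytest.approx(65.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            steady_state_map(-0.1, params())

    @settings(derandomize=True, max_examples=50)
    @given(d1=st.floats(0, 10), d2=st.floats(0, 10))
    def test_monotone_in_dose(self, d1, d2):
        lo, hi = sorted((d1, d2))
        p = params()
        assert steady_state_map(lo, p) <= steady_state_map(hi, p) + 1e-12
        assert steady_state_map(hi, p) <= p.baseline_map + p.max_effect


class TestDoseScheduling:
    def test_lag_delays_effect(self):
        p = params(lag_time=30.0)
        plant = Plant(params=p)
        plant.apply_dose(2.0)
        for _ in range(119):  # just under 30 s at dt=0.25
            plant.step(0.25)
        assert plant.map_true == pytest.approx(p.baseline_map)
        for _ in range(40):
            plant.step(0.25)
        assert plant.map_true > p.baseline_map

    def test_identical_dose_not_rescheduled(self):
        plant = Plant(params=params(lag_time=10.0))
        plant.apply_dose(1.0)
        plant.apply_dose(1.0)
        assert len(plant.pending_dose_changes) == 1

    def test_pending_changes_ordered(self):
        plant = Plant(params=params(lag_time=10.0))
        plant.apply_dose(1.0)
        for _ in range(20):
            plant.step(0.25)
        plant.apply_dose(2.0)
        times = [t for t, _ in plant.pending_dose_changes]
        assert times == sorted(times)


class TestDynamics:
    def test_hemorrhage_drift_rate(self):
        """At zero dose the drift is exactly slope x bleed-rate per minute."""
        p = params(hemorrhage_rate=10.0, hemorrhage_map_slope=0.05)
        plant = Plant(params=p)
        for _ in range(240):  # one minute
            plant.step(0.25)
        assert plant.map_true == pytest.approx(p.baseline_map - 0.5, abs=1e-9)

    def test_converges_to_steady_state_vs_ode_oracle(self):
        """Euler trajectory matches an independent ODE solve of the model."""
        p = params(responsiveness_tau=60.0)
        target_ss = steady_state_map(2.0, p)
        plant = Plant(params=p)
        plant.apply_dose(2.0)
        for _ in range(4 * 900):  # 15 min
            plant.step(0.25)
        sol = solve_ivp(lambda t, m: (target_ss - m) / 60.0, (0, 900),
                        [p.baseline_map], rtol=1e-10, atol=1e-10)
        assert plant.map_true == pytest.approx(sol.y[0, -1], abs=0.05)
        assert plant.map_true == pytest.approx(target_ss, abs=0.1)

    def test_monotone_approach_without_overshoot(self):
        plant = Plant(params=params(overshoot_frac=0.0))
        plant.apply_dose(2.0)
        maps = [plant.step(0.25) for _ in range(2000)]
        assert np.all(np.diff(maps) >= -1e-12)

    def test_overshoot_transient_peaks_above_steady_state(self):
        p = params(overshoot_frac=0.15)
        plant = Plant(params=p)
        plant.apply_dose(2.0)
        maps = np.array([plant.step(0.25) for _ in range(4 * 1800)])
        ss = steady_state_map(2.0, p)
        step_change = ss - p.baseline_map
        assert maps.max() > ss  # transient peak above the plateau
        assert maps.max() <= ss + p.overshoot_frac * step_change + 1e-9
        assert maps[-1] == pytest.approx(ss, abs=0.2)  # transient decays

    def test_noise_determinism_under_seed(self):
        p = params(noise_sd=1.0)
        runs = []
        for _ in range(2):
            plant = Plant(params=p, seed=123)
            plant.apply_dose(1.0)
            runs.append([plant.step(0.25) for _ in range(200)])
        assert runs[0] == runs[1]

    def test_dt_bounds_enforced(self):
        plant = Plant(params=params())
        with pytest.raises(ValueError):
            plant.step(2.0)


class TestSampling:
    def test_zero_order_hold(self):
        plant = Plant(params=params(hemorrhage_rate=10.0,
                                    hemorrhage_map_slope=0.05))
        held_at_10 = None
        for _ in range(40):  # to t=10 s
            plant.step(0.25)
        held_at_10 = plant.sample(10.0)
        for _ in range(16):  # to t=14 s
            plant.step(0.25)
        assert plant.sample(10.0) == held_at_10
        for _ in range(24):  # to t=20 s
            plant.step(0.25)
        assert plant.sample(10.0) != held_at_10

    def test_noise_free_sample_equals_true_map(self):
        plant = Plant(params=params())
        plant.apply_dose(1.0)
        for _ in range(40):
            plant.step(0.25)
        assert plant.sample(10.0) == plant.map_true


class TestDoseTable:
    def test_rate_to_dose_examples(self):
        table = load_dose_table()
        assert rate_to_dose(0.5, table) == pytest.approx(2.0)
        assert rate_to_dose(0.0, table) == 0.0
        assert rate_to_dose(5.0, table) == pytest.approx(20.0)

    def test_table_rates_strictly_increasing(self):
        rates = load_dose_table().rates
        assert all(b > a for a, b in zip(rates, rates[1:]))
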