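"""ADRC: tracking differentiator, extended state observer, feedback law."""

import numpy as np
import pytest

from vasoloop.controllers.adrc import (AdrcController, AdrcTuning, eso_step,
                                       td_step)
from vasoloop.plant import Plant, PlantParams


def tuning(**kw):
    base = dict(kp=0.006, kd=0.03, b=0.01, eso_bandwidth=0.08, td_speed=0.02,
                max_rate_step=0.1)
    base.update(kw)
    return AdrcTuning(**base)


class TestTrackingDifferentiator:
    def test_equilibrium_is_fixed_point(self):
        v1, v2 = td_step(65.0, 0.0, setpoint=65.0, dt=10.0, speed=0.05)
        assert (v1, v2) == (65.0, 0.0)

    def test_step_response_monotone_without_overshoot(self):
        v1, v2 = 35.0, 0.0
        prev = v1
        for _ in range(200):
            v1, v2 = td_step(v1, v2, setpoint=65.0, dt=10.0, speed=0.02)
            assert prev - 1e-12 <= v1 <= 65.0 + 1e-9
            prev = v1
        assert v1 == pytest.approx(65.0, abs=0.1)
        assert v2 == pytest.approx(0.0, abs=0.01)

    def test_infinitely_fast_tracker_snaps_in_one_tick(self):
        v1, v2 = td_step(35.0, 0.0, setpoint=65.0, dt=10.0, speed=1e6)
        assert v1 == pytest.approx(65.0)

    def test_matches_ode_oracle(self):
        """Discrete update equals dense integration of the tracker ODE."""
        from scipy.integrate import solve_ivp
        w = 0.02
        sol = solve_ivp(
            lambda t, x: [x[1], -w * w * (x[0] - 65.0) - 2 * w * x[1]],
            (0, 100), [35.0, 0.0], rtol=1e-10, atol=1e-12)
        v1, v2 = 35.0, 0.0
        for _ in range(10):
            v1, v2 = td_step(v1, v2, setpoint=65.0, dt=10.0, speed=w)
        assert v1 == pytest.approx(sol.y[0, -1], abs=1e-6)


class TestExtendedStateObserver:
    def test_consistent_states_unchanged(self):
        z = eso_step(60.0, 0.0, 0.0, measured=60.0, u=0.0, dt=10.0,
                     beta=(0.24, 0.0192, 0.000512), b=0.01)
        assert z == (60.0, 0.0, 0.0)

    def test_error_envelope_decays(self):
        """|z1 - y| stays bounded by the initial mismatch and converges.

        A third-order observer with a triple pole carries a polynomial
        factor, so the estimate crosses the measurement once and rebounds
        slightly before settling; the envelope, not the instantaneous
        magnitude, is what decays.
        """
        z1, z2, z3 = 50.0, 0.0, 0.0
        errs = []
        for _ in range(200):
            z1, z2, z3 = eso_step(z1, z2, z3, measured=60.0, u=0.0, dt=1.0,
                                  beta=(0.24, 0.0192, 0.000512), b=0.01)
            errs.append(abs(z1 - 60.0))
        assert max(errs) < 10.0          # never exceeds the initial mismatch
        assert max(errs[50:]) < 1.0      # envelope well down within 50 s
        assert errs[-1] < 0.01           # converged

    def test_independent_of_input_when_b_zero(self):
        za = eso_step(50.0, 1.0, 0.5, measured=60.0, u=0.0, dt=10.0,
                      beta=(0.3, 0.03, 0.001), b=0.0)
        zb = eso_step(50.0, 1.0, 0.5, measured=60.0, u=123.0, dt=10.0,
                      beta=(0.3, 0.03, 0.001), b=0.0)
        assert za == zb

    def test_observer_error_below_one_mmhg_within_60s(self):
        """Tracking a simulated noise-free plant from a 15 mmHg mismatch."""
        plant = Plant(params=PlantParams(baseline_map=50.0, hemorrhage_rate=0.0,
                                         overshoot_frac=0.0, noise_sd=0.0))
        plant.apply_dose(1.0)
        for _ in range(4 * 600):  # let the dose response settle first
            plant.step(0.25)
        t = tuning()
        z1, z2, z3 = plant.map_true - 15.0, 0.0, 0.0  # wrong initial estimate
        for _ in range(6):  # 60 s at the 10 s tick
            for _ in range(40):
                plant.step(0.25)
            z1, z2, z3 = eso_step(z1, z2, z3, plant.map_true, u=1.0, dt=10.0,
                                  beta=t.beta, b=t.b)
        assert abs(z1 - plant.map_true) < 1.0


class TestControlLaw:
    def test_null_error_gives_zero(self):
        c = AdrcController(tuning(), dt=10.0)
        c.z1, c.z2, c.z3 = 65.0, 0.0, 0.0
        assert c.control(65.0) == 0.0

    def test_direct_evaluation(self):
        c = AdrcController(tuning(kp=1.0, kd=0.0, b=1.0, adapt_gain=0.0),
                           dt=10.0)
        c.z1, c.z2, c.z3 = 60.0, 0.0, 0.0
        assert c.control(65.0) == pytest.approx(5.0)

    def test_adaptive_gain_scales_with_error(self):
        c = AdrcController(tuning(kp=1.0, kd=0.0, b=1.0, adapt_gain=1.0,
                                  adapt_ref=20.0), dt=10.0)
        c.z1, c.z2, c.z3 = 45.0, 0.0, 0.0
        # error 20 mmHg saturates the adaptation: kp doubled
        assert c.control(65.0) == pytest.approx(40.0)

    def test_rapid_rise_blocks_increases(self):
        c = AdrcController(tuning(), dt=10.0)
        c.tick(measured=50.0, target=65.0)
        c.z2 = 0.2  # estimated slope +12 mmHg/min
        before = c.current_rate
        after = c.tick(measured=50.0, target=65.0)
        assert after <= before + 1e-12

    def test_zero_b_rejected(self):
        with pytest.raises(ValueError):
            tuning(b=0.0)

    def test_rate_limits_respected_in_closed_loop(self):
        plant = Plant(params=PlantParams(baseline_map=35.0))
        t = tuning()
        c = AdrcController(t, dt=10.0)
        prev = c.current_rate
        for _ in range(120):
            rate = c.tick(plant.sample(10.0), 65.0)
            plant.apply_dose(rate)
            for _ in range(40):
                plant.step(0.25)
            assert rate >= 0.0
            assert abs(rate - prev) <= t.max_rate_step + 1e-12
            prev = rate
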