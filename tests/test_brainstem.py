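"""Burst generator, displacement integrator and hold switch."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omvsim.brainstem import (BrainstemState, burst_output, hold_switch,
                              integrator_step, sc_command)


class TestScCommand:
    @pytest.mark.parametrize("target", [0.0, 15.0, 20.0])
    def test_identity_mapping_one_hz_per_degree(self, target):
        assert sc_command(target) == target

    def test_leftward_targets_rejected(self):
        with pytest.raises(ValueError):
            sc_command(-5.0)


class TestBurstOutput:
    def test_zero_drive_gives_zero_burst(self):
        u = burst_output(0.0, 0.0, BrainstemState(), A=1100.0, sigma=16.0)
        assert u == 0.0

    def test_scalar_formula_against_independent_evaluation(self):
        # independent scalar oracle: A * (1 - e^{-(yc+yd-D)/sigma})
        expected = 1100.0 * (1.0 - math.exp(-20.0 / 16.0))
        u = burst_output(20.0, 0.0, BrainstemState(D=0.0), 1100.0, 16.0)
        assert u == pytest.approx(expected, rel=1e-12)
        assert u == pytest.approx(784.84, abs=0.01)

    def test_overshot_integrator_is_rectified_to_zero(self):
        # D beyond the command makes the exponent argument negative
        u = burst_output(10.0, 0.0, BrainstemState(D=12.0), 1100.0, 16.0)
        assert u == 0.0

    def test_motivation_scales_amplitude(self):
        full = burst_output(20.0, 0.0, BrainstemState(), 1100.0, 16.0)
        reduced = burst_output(20.0, 0.0, BrainstemState(), 1100.0, 16.0,
                               motivation_scale=0.84)
        assert reduced == pytest.approx(0.84 * full, rel=1e-12)

    def test_hold_silences_burst(self):
        state = BrainstemState(hold_active=True)
        assert burst_output(20.0, 0.0, state, 1100.0, 16.0) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(y_d=st.floats(0, 30), y_c=st.floats(-50, 50),
           D=st.floats(-10, 50), scale=st.floats(0.01, 1.0))
    def test_bounded_below_amplitude_and_nonnegative(self, y_d, y_c, D,
                                                     scale):
        u = burst_output(y_d, y_c, BrainstemState(D=D), 1100.0, 16.0, scale)
        assert 0.0 <= u < 1100.0 * scale

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(drive_lo=st.floats(-30, 60), extra=st.floats(0, 30),
           D=st.floats(0, 40))
    def test_monotone_in_total_drive(self, drive_lo, extra, D):
        state = BrainstemState(D=D)
        lo = burst_output(0.0, drive_lo, state, 1100.0, 16.0)
        hi = burst_output(0.0, drive_lo + extra, state, 1100.0, 16.0)
        assert hi >= lo


class TestIntegrator:
    def test_analytic_integral_of_constant_burst(self):
        # u = 100 Hz held 0.1 s with k = 0.72 accumulates k*u*t = 7.2
        state = BrainstemState()
        for _ in range(100):
            state = integrator_step(state, 100.0, k=0.72, dt=0.001)
        assert state.D == pytest.approx(7.2, rel=1e-9)
        assert state.n_int == pytest.approx(10.0, rel=1e-9)

    def test_zero_burst_leaves_state(self):
        state = BrainstemState(D=3.0, n_int=4.0)
        out = integrator_step(state, 0.0, k=0.72, dt=0.001)
        assert out.D == 3.0 and out.n_int == 4.0

    def test_zero_gain_never_accumulates(self):
        state = BrainstemState()
        for _ in range(50):
            state = integrator_step(state, 500.0, k=0.0, dt=0.001)
        assert state.D == 0.0  # the internal loop never closes


class TestHoldSwitch:
    def test_before_threshold(self):
        assert not hold_switch(0.05, 0.19, 0.15)

    def test_at_threshold(self):
        assert hold_switch(0.05, 0.20, 0.15)

    def test_no_onset_never_fires(self):
        assert not hold_switch(None, 0.39, 0.15)
        assert not hold_switch(np.inf, 0.39, 0.15)

    def test_monotone_once_fired(self):
        fired_at = [t for t in np.arange(0, 0.4, 0.001)
                    if hold_switch(0.05, t, 0.15)]
        assert fired_at and fired_at == sorted(fired_at)
        assert min(fired_at) == pytest.approx(0.2)
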