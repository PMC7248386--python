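import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siglognorm.model import (
    InvalidParameterError,
    LognormalComponent,
    UndefinedReactionTimeError,
    angular_profile,
    conduction_time,
    derived_parameters,
    lognormal_peak_time,
    lognormal_peak_value,
    lognormal_speed,
    reaction_time,
    superpose,
    wrap_angle,
)

GRID_1KHZ = np.arange(0.0, 12.0, 0.001)


def params(t0=0.2, D=200.0, mu=-1.4, sigma=0.3, theta_s=0.0, theta_e=0.0):
    return LognormalComponent(t0=t0, D=D, mu=mu, sigma=sigma,
                              theta_s=theta_s, theta_e=theta_e)


class TestLognormalSpeed:
    def test_zero_before_onset(self, component):
        v = lognormal_speed(component, np.array([component.t0 - 0.1, component.t0]))
        assert np.all(v == 0.0)

    def test_nonnegative(self, component):
        assert np.all(lognormal_speed(component, GRID_1KHZ) >= 0.0)

    def test_argmax_matches_closed_form(self):
        comp = params(t0=0.2, mu=-1.4, sigma=0.3, D=200.0)
        v = lognormal_speed(comp, GRID_1KHZ)
        t_peak_grid = GRID_1KHZ[np.argmax(v)]
        assert abs(t_peak_grid - lognormal_peak_time(comp)) <= 0.001

    def test_peak_value_closed_form(self):
        comp = params(t0=0.2, mu=-1.4, sigma=0.3, D=200.0)
        at_peak = lognormal_speed(comp, np.array([lognormal_peak_time(comp)]))
        assert at_peak[0] == pytest.approx(lognormal_peak_value(comp), rel=1e-12)
        v = lognormal_speed(comp, GRID_1KHZ)
        assert v.max() == pytest.approx(lognormal_peak_value(comp), rel=1e-4)
        assert v.max() <= lognormal_peak_value(comp) + 1e-9

    def test_integral_equals_amplitude(self, component):
        t = np.linspace(component.t0, component.t0 + 10.0, 200_001)
        area = np.trapezoid(lognormal_speed(component, t), t)
        assert area == pytest.approx(component.D, rel=1e-3)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            LognormalComponent(t0=0.1, D=100.0, mu=-1.0, sigma=0.0)
        with pytest.raises(InvalidParameterError):
            LognormalComponent(t0=0.1, D=-5.0, mu=-1.0, sigma=0.3)

    def test_nonascending_times_rejected(self, component):
        with pytest.raises(ValueError):
            lognormal_speed(component, np.array([0.2, 0.1, 0.3]))


class TestAngularProfile:
    def test_degenerate_arc_constant(self):
        comp = params(theta_s=0.5, theta_e=0.5)
        theta = angular_profile(comp, np.linspace(0.0, 2.0, 500))
        assert np.allclose(theta, 0.5)

    def test_median_angle_is_midpoint(self):
        comp = params(theta_s=0.2, theta_e=0.8)
        t_mid = comp.t0 + math.exp(comp.mu)
        theta = angular_profile(comp, np.array([t_mid - 1e-12, t_mid + 1e-12]))
        assert theta[-1] == pytest.approx(0.5, abs=1e-9)

    def test_late_times_reach_end_angle(self):
        comp = params(theta_s=0.2, theta_e=0.8)
        t_late = comp.t0 + 100.0 * math.exp(comp.mu)
        theta = angular_profile(comp, np.array([t_late]))
        assert abs(theta[0] - comp.theta_e) < 1e-6

    def test_before_onset_returns_start_angle(self):
        comp = params(theta_s=-0.4, theta_e=0.9)
        theta = angular_profile(comp, np.array([comp.t0 - 0.5]))
        assert theta[0] == pytest.approx(comp.theta_s)


class TestSuperpose:
    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            superpose([], GRID_1KHZ)

    def test_opposed_pair_cancels_displacement(self):
        fwd = params(theta_s=0.0, theta_e=0.0)
        bwd = params(theta_s=math.pi, theta_e=math.pi)
        t = np.linspace(0.0, 10.0, 20001)
        vx, vy, _ = superpose([fwd, bwd], t)
        assert np.trapezoid(vx, t) == pytest.approx(0.0, abs=1e-6)
        assert np.trapezoid(vy, t) == pytest.approx(0.0, abs=1e-6)

    def test_horizontal_component_has_zero_vy(self):
        comp = params(theta_s=0.0, theta_e=0.0)
        _, vy, _ = superpose([comp], GRID_1KHZ)
        assert np.allclose(vy, 0.0)

    def test_collinear_pair_speed_is_absolute_difference(self):
        a = params(t0=0.2, D=200.0, mu=-1.4, sigma=0.3, theta_s=0.0, theta_e=0.0)
        b = params(t0=0.4, D=40.0, mu=-1.8, sigma=0.25,
                   theta_s=math.pi, theta_e=math.pi)
        t = np.linspace(0.0, 3.0, 3000)
        _, _, speed = superpose([a, b], t)
        oracle = np.abs(lognormal_speed(a, t) - lognormal_speed(b, t))
        assert np.allclose(speed, oracle, atol=1e-9)

    def test_linearity(self, rng):
        comps = [params(t0=0.1 * k + 0.1, D=50.0 + 10 * k, mu=-1.5 + 0.1 * k,
                        sigma=0.2 + 0.02 * k, theta_s=0.3 * k, theta_e=0.2 * k)
                 for k in range(4)]
        t = np.linspace(0.0, 2.0, 800)
        vx_all, vy_all, _ = superpose(comps, t)
        vx_sum = sum(superpose([c], t)[0] for c in comps)
        vy_sum = sum(superpose([c], t)[1] for c in comps)
        assert np.allclose(vx_all, vx_sum, atol=1e-9)
        assert np.allclose(vy_all, vy_sum, atol=1e-9)


class TestDerivedParameters:
    def test_printed_response_time(self):
        d = derived_parameters(params(t0=0.23, mu=-1.42, sigma=0.27))
        assert round(d.response_time, 2) == 0.07

    def test_degenerate_sigma_collapses_timing(self):
        d = derived_parameters(params(t0=0.2, mu=-1.4, sigma=1e-9))
        expected = 0.2 + math.exp(-1.4)
        assert d.mode == pytest.approx(expected, abs=1e-6)
        assert d.median == pytest.approx(expected, abs=1e-6)
        assert d.time_delay == pytest.approx(expected, abs=1e-6)

    def test_asymmetry_matches_moment_integral(self, component):
        # third standardized moment of the impulse response by quadrature
        t = np.linspace(component.t0 + 1e-9, component.t0 + 60.0, 4_000_001)
        lam = lognormal_speed(component, t) / component.D
        m1 = np.trapezoid(t * lam, t)
        m2 = np.trapezoid((t - m1) ** 2 * lam, t)
        m3 = np.trapezoid((t - m1) ** 3 * lam, t)
        skew = m3 / m2**1.5
        assert derived_parameters(component).asymmetry == pytest.approx(skew, abs=1e-4)

    @given(sigma=st.floats(0.01, 1.2), mu=st.floats(-3.0, 0.5),
           t0=st.floats(0.0, 2.0))
    @settings(max_examples=80, deadline=None)
    def test_timing_order_invariant(self, sigma, mu, t0):
        d = derived_parameters(params(t0=t0, mu=mu, sigma=sigma))
        assert d.mode < d.median < d.time_delay
        assert d.response_time > 0
        assert d.asymmetry > 0
        assert all(np.isfinite([d.mode, d.median, d.time_delay,
                                d.response_time, d.asymmetry]))

    @given(sigma=st.floats(0.05, 0.6))
    @settings(max_examples=20, deadline=None)
    def test_distance_conservation(self, sigma):
        comp = params(t0=0.1, D=120.0, mu=-1.2, sigma=sigma)
        t = np.linspace(comp.t0, comp.t0 + 30.0, 300_001)
        area = np.trapezoid(lognormal_speed(comp, t), t)
        assert area == pytest.approx(comp.D, rel=1e-3)


class TestReactionTime:
    def test_linear_ramp(self):
        t = np.linspace(0.0, 1.0, 1001)
        assert reaction_time(100.0 * t, t) == pytest.approx(0.1)

    def test_single_lognormal_grid_scan(self, component):
        t = GRID_1KHZ
        v = lognormal_speed(component, t)
        oracle = t[np.nonzero(v >= 0.1 * v.max())[0][0]]
        assert reaction_time(v, t) == oracle

    def test_zero_speed_rejected(self):
        t = np.linspace(0.0, 1.0, 100)
        with pytest.raises(UndefinedReactionTimeError):
            reaction_time(np.zeros_like(t), t)

    def test_conduction(self):
        assert conduction_time(0.23, 0.31) == pytest.approx(0.08)


@given(st.floats(-50.0, 50.0))
@settings(max_examples=100, deadline=None)
def test_wrap_angle_range(theta):
    w = wrap_angle(theta)
    assert -math.pi < w <= math.pi
    assert math.cos(w) == pytest.approx(math.cos(theta), abs=1e-9)
    assert math.sin(w) == pytest.approx(math.sin(theta), abs=1e-9)
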