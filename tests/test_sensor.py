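"""Two-state sensor kinetics: closed form vs ODE oracle, limits, inversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from redoxkin.sensor import (
    ExposureCondition,
    SensorSpecies,
    activation_rate,
    kinetics_summary,
    oxidized_fraction,
    reduced_fraction,
    required_h2o2,
    required_rate_constant,
    response_time,
    steady_state_oxidized,
)

LN2 = math.log(2.0)


def ode_reduced_fraction(k_act: float, k_off: float, f0: float, t: float) -> float:
    """Independent oracle: integrate df/dt = k_off(1-f) - k_act f numerically."""
    if t == 0:
        return f0
    sol = solve_ivp(
        lambda _t, y: [k_off * (1.0 - y[0]) - k_act * y[0]],
        (0.0, t),
        [f0],
        method="LSODA",
        rtol=1e-11,
        atol=1e-14,
    )
    assert sol.success
    return float(sol.y[0, -1])


class TestActivationRate:
    def test_product_of_rate_constant_and_concentration(self):
        s = SensorSpecies("PTP1B", rate_constant=20.0)
        e = ExposureCondition(h2o2=1e-4)
        assert activation_rate(s, e) == pytest.approx(2e-3, rel=1e-12)

    @pytest.mark.parametrize("k,h", [(0.0, 1e-3), (50.0, 0.0), (0.0, 0.0)])
    def test_zero_iff_either_factor_zero(self, k, h):
        assert activation_rate(SensorSpecies("s", k), ExposureCondition(h)) == 0.0

    def test_direct_product_matches_hand_value(self):
        # k=140 at 1.4 µM: the combination that gives a ~1 h response time
        s = SensorSpecies("KEAP1", 140.0)
        e = ExposureCondition(1.4e-6)
        assert activation_rate(s, e) == pytest.approx(1.96e-4, rel=1e-12)
        assert response_time(s, e) == pytest.approx(LN2 / 1.96e-4, rel=1e-12)

    def test_extracellular_dose_divided_by_gradient(self):
        s = SensorSpecies("s", 10.0)
        intra = ExposureCondition(h2o2=1e-4)
        extra = ExposureCondition(h2o2=6.8e-4, gradient_factor=6.8, extracellular=True)
        assert activation_rate(s, extra) == pytest.approx(activation_rate(s, intra))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            SensorSpecies("s", -1.0)
        with pytest.raises(ValueError):
            ExposureCondition(-1e-6)
        with pytest.raises(ValueError):
            ExposureCondition(1e-6, gradient_factor=0.5)


class TestReducedFraction:
    def test_identity_at_t_zero(self):
        s = SensorSpecies("s", 123.0, switchoff_rate=0.5, reduced_fraction0=0.73)
        assert reduced_fraction(s, ExposureCondition(1e-5, duration=0.0)) == 0.73

    def test_pure_exponential_half_oxidation(self):
        # GSH-like sensor: k=0.87, 2.7e-2 M for 30 s puts it near 50% oxidized
        s = SensorSpecies("GSH", 0.87)
        f = reduced_fraction(s, ExposureCondition(2.7e-2, duration=30.0))
        assert f == pytest.approx(math.exp(-0.87 * 2.7e-2 * 30.0), rel=1e-14)
        assert f == pytest.approx(0.494, abs=5e-3)

    def test_long_time_limit_is_switchoff_ratio(self):
        s = SensorSpecies("s", 100.0, switchoff_rate=3e-3)
        e = ExposureCondition(1e-4, duration=1e6)
        k_act = 100.0 * 1e-4
        assert reduced_fraction(s, e) == pytest.approx(3e-3 / (3e-3 + k_act), rel=1e-9)

    @pytest.mark.parametrize(
        "k_act,k_off,f0,t",
        [
            (1e-3, 0.0, 1.0, 500.0),
            (1e-3, 1e-3, 1.0, 800.0),
            (5.0, 1e-4, 0.4, 2.0),
            (1e-6, 1e-2, 0.0, 300.0),
            (0.2, 7.0, 0.9, 1.5),
        ],
    )
    def test_matches_ode_oracle(self, k_act, k_off, f0, t):
        s = SensorSpecies("s", k_act, switchoff_rate=k_off, reduced_fraction0=f0)
        e = ExposureCondition(h2o2=1.0, duration=t)  # k_act via k*1.0
        expected = ode_reduced_fraction(k_act, k_off, f0, t)
        assert reduced_fraction(s, e) == pytest.approx(expected, rel=1e-8)

    def test_ode_oracle_grid_six_decades(self):
        """Closed form matches numerical integration over 6 decades in both rates."""
        rates = np.logspace(-4, 2, 4)  # 1e-4 .. 1e2 s^-1
        for k_act in rates:
            for k_off in rates:
                t = 2.0 / (k_act + k_off)  # a couple of relaxation times
                s = SensorSpecies("s", k_act, switchoff_rate=k_off)
                e = ExposureCondition(1.0, duration=t)
                expected = ode_reduced_fraction(k_act, k_off, 1.0, t)
                assert reduced_fraction(s, e) == pytest.approx(expected, rel=1e-8)

    @given(
        k_act=st.floats(1e-6, 1e3),
        k_off=st.floats(0.0, 1e3),
        f0=st.floats(0.0, 1.0),
        t=st.floats(0.0, 1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_conservation_reduced_plus_oxidized(self, k_act, k_off, f0, t):
        s = SensorSpecies("s", k_act, switchoff_rate=k_off, reduced_fraction0=f0)
        e = ExposureCondition(1.0, duration=t)
        assert reduced_fraction(s, e) + oxidized_fraction(s, e) == 1.0

    @given(
        k=st.floats(1e-3, 1e6),
        h=st.floats(1e-9, 1e-2),
        scale=st.floats(1e-3, 1e3),
        t=st.floats(0.0, 1e5),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_invariance_k_times_h2o2(self, k, h, scale, t):
        """Outputs depend on the product k*[H2O2] only."""
        a = reduced_fraction(SensorSpecies("a", k), ExposureCondition(h, duration=t))
        b = reduced_fraction(
            SensorSpecies("b", k * scale), ExposureCondition(h / scale, duration=t)
        )
        assert b == pytest.approx(a, rel=1e-9)

    def test_strictly_decreasing_when_starting_above_steady_state(self):
        s = SensorSpecies("s", 1.0, switchoff_rate=0.5, reduced_fraction0=0.9)
        # steady-state reduced fraction = 0.5/1.5 = 1/3 < 0.9
        ts = np.linspace(0.0, 10.0, 50)
        vals = [reduced_fraction(s, ExposureCondition(1.0, duration=t)) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestResponseTime:
    def test_low_reactivity_sensor_at_signaling_h2o2(self):
        # PTP1B at the 1e-4 M bottleneck steady state: half-life ~5.8 min
        tau = response_time(SensorSpecies("PTP1B", 20.0), ExposureCondition(1e-4))
        assert tau == pytest.approx(346.57, rel=1e-3)
        assert tau / 60.0 == pytest.approx(5.7, rel=0.02)

    def test_doubling_h2o2_halves_response_time(self):
        s = SensorSpecies("s", 33.0)
        t1 = response_time(s, ExposureCondition(1e-5))
        t2 = response_time(s, ExposureCondition(2e-5))
        assert t2 == pytest.approx(t1 / 2.0, rel=1e-12)

    def test_with_switchoff_halves_gap_to_steady_state(self):
        """tau_1/2 is where the closed form covers half the distance to its asymptote."""
        s = SensorSpecies("s", 2.0, switchoff_rate=0.7)
        e0 = ExposureCondition(1.0)
        tau = response_time(s, e0)
        f_ss = 0.7 / 2.7
        f0 = 1.0

        def gap(t):
            f = reduced_fraction(s, ExposureCondition(1.0, duration=t))
            return (f - f_ss) / (f0 - f_ss) - 0.5

        root = brentq(gap, 1e-6, 100.0, xtol=1e-12)
        assert tau == pytest.approx(root, rel=1e-9)

    def test_switchoff_limit_consistency(self):
        """With k_off = 0 the two response-time expressions coincide."""
        e = ExposureCondition(1e-4)
        assert response_time(SensorSpecies("s", 20.0), e) == response_time(
            SensorSpecies("s", 20.0, switchoff_rate=0.0), e
        )

    def test_no_dynamics_raises(self):
        with pytest.raises(ValueError, match="no dynamics"):
            response_time(SensorSpecies("s", 0.0), ExposureCondition(0.0))


class TestInversions:
    def test_required_h2o2_glutathione_fast_response(self):
        # GSH (0.87 M^-1 s^-1) needs ~27 mM for a 30-s response
        c = required_h2o2(0.87, 30.0)
        assert c * 1e6 == pytest.approx(2.7e4, rel=0.02)

    def test_required_h2o2_slow_sensor_slow_signal(self):
        # Cdc25B-class constant over 1 h: ~1.2 µM suffices
        assert required_h2o2(160.0, 3600.0) * 1e6 == pytest.approx(1.2, rel=0.02)

    @given(k=st.floats(1e-3, 1e8), c=st.floats(1e-12, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_concentration(self, k, c):
        tau = response_time(SensorSpecies("s", k), ExposureCondition(c))
        assert required_h2o2(k, tau) == pytest.approx(c, rel=1e-12)

    @given(k=st.floats(1e-3, 1e8), c=st.floats(1e-12, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_rate_constant(self, k, c):
        tau = response_time(SensorSpecies("s", k), ExposureCondition(c))
        assert required_rate_constant(c, tau) == pytest.approx(k, rel=1e-12)

    def test_rate_constant_from_half_maximal_response(self):
        # 50% response in 5 min at 12.5 µM steady state
        k = required_rate_constant(12.5e-6, 300.0)
        assert k == pytest.approx(1.8e2, rel=0.03)
        k_intra = required_rate_constant(12.5e-6, 300.0, gradient_factor=6.8)
        assert k_intra == pytest.approx(1.3e3, rel=0.04)

    @pytest.mark.parametrize("func", [required_h2o2, required_rate_constant])
    def test_invalid_inputs(self, func):
        with pytest.raises(ValueError):
            func(0.0, 10.0)
        with pytest.raises(ValueError):
            func(10.0, -1.0)


class TestSteadyState:
    def test_no_activation_means_fully_reduced(self):
        s = SensorSpecies("s", 5.0, switchoff_rate=0.1)
        assert steady_state_oxidized(s, ExposureCondition(0.0)) == 0.0

    def test_no_switchoff_means_fully_oxidized(self):
        s = SensorSpecies("s", 5.0)
        assert steady_state_oxidized(s, ExposureCondition(1e-6)) == 1.0

    def test_equals_long_time_limit_of_time_course(self):
        s = SensorSpecies("s", 40.0, switchoff_rate=2e-3)
        e = ExposureCondition(1e-4)
        tau = response_time(s, e)
        f_long = oxidized_fraction(s, ExposureCondition(1e-4, duration=50.0 * tau))
        assert steady_state_oxidized(s, e) == pytest.approx(f_long, abs=1e-8)

    def test_both_rates_zero_raises(self):
        with pytest.raises(ValueError, match="no dynamics"):
            steady_state_oxidized(SensorSpecies("s", 0.0), ExposureCondition(0.0))


def test_kinetics_summary_is_self_consistent():
    s = SensorSpecies("s", 50.0, switchoff_rate=1e-3)
    e = ExposureCondition(2e-5, duration=120.0)
    r = kinetics_summary(s, e)
    assert r.activation_rate == pytest.approx(1e-3, rel=1e-12)
    assert r.reduced_fraction_t + r.oxidized_fraction_t == 1.0
    assert r.response_time == pytest.approx(LN2 / 2e-3, rel=1e-12)
    assert 0.0 <= r.steady_state_oxidized <= 1.0
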