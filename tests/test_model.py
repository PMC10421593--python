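"""Unit and property tests for the four-sensor Cav gating model."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from cavprime import (CavParams, ConfigurationError, UndefinedRatioError,
                      VoltageTrace, augmentation_ratio, convergence_error,
                      sensor_velocity, simulate_current, state_occupancies,
                      steady_iv_curve, steady_open_probability,
                      steady_sensor_activation, step_sensor)
from conftest import make_step


class TestSteadyCurves:
    def test_half_activation_at_v50(self, params):
        assert steady_open_probability(-17.0, params) == pytest.approx(0.5)

    def test_boltzmann_value(self, params):
        # direct evaluation at V = V_Cav50 - 20 mV: 1/(1+e^4)
        assert steady_open_probability(-37.0, params) == pytest.approx(
            1.0 / (1.0 + np.exp(4.0)), rel=1e-12)

    def test_sigmoid_limits(self, params):
        assert steady_open_probability(1e4, params) == pytest.approx(1.0)
        assert steady_open_probability(-1e4, params) == pytest.approx(0.0, abs=1e-12)

    def test_sensor_activation_fourth_root(self, params):
        assert steady_sensor_activation(-17.0, params) == pytest.approx(0.5**0.25)

    @given(V=st.floats(-120, 80))
    @settings(max_examples=50, deadline=None)
    def test_sensor_fourth_power_identity(self, V):
        p = CavParams()
        assert steady_sensor_activation(V, p) ** 4 == pytest.approx(
            steady_open_probability(V, p), rel=1e-10)

    def test_monotone_in_voltage(self, params):
        V = np.linspace(-100, 60, 200)
        assert np.all(np.diff(steady_open_probability(V, params)) > 0)

    def test_nonfinite_rejected(self, params):
        with pytest.raises(ValueError):
            steady_open_probability(np.nan, params)


class TestSensorKinetics:
    def test_activation_branch(self, params):
        assert sensor_velocity(0.07, 0.992, params) == pytest.approx(0.55 * 0.992)

    def test_deactivation_branch(self, params):
        assert sensor_velocity(0.9, 0.1, params) == pytest.approx(0.65 * 0.9)

    def test_tie_has_zero_drive(self, params):
        # exact tie: steady == current activation leaves P unchanged
        ps = 0.5**0.25
        assert step_sensor(ps, -17.0, params) == pytest.approx(ps, abs=1e-15)

    def test_out_of_range_probability(self, params):
        with pytest.raises(ValueError):
            sensor_velocity(1.2, 0.5, params)
        with pytest.raises(ValueError):
            sensor_velocity(0.5, -0.1, params)

    def test_single_euler_step_hand_value(self, params):
        # from rest P=0 at 0 mV: dP = dt * k_on * ps * ps with ps ~ 0.99183
        assert step_sensor(0.0, 0.0, params) == pytest.approx(0.005411, abs=2e-6)

    @given(p=st.floats(0, 1), V=st.floats(-100, 60))
    @settings(max_examples=100, deadline=None)
    def test_step_bounded(self, p, V):
        prm = CavParams()
        out = step_sensor(p, V, prm)
        assert 0.0 <= out <= 1.0
        assert abs(out - p) <= prm.dt * max(prm.k_on, prm.k_off) + 1e-15


class TestOccupancies:
    def test_all_resting(self):
        assert np.allclose(state_occupancies(0.0), [1, 0, 0, 0, 0])

    def test_half_activated_binomial(self):
        assert state_occupancies(0.5) == pytest.approx(
            [0.0625, 0.25, 0.375, 0.25, 0.0625])

    # scipy's binom.pmf overflows for p below ~1e-300; endpoints covered above
    @given(p=st.floats(1e-6, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_matches_binomial_pmf_and_sums_to_one(self, p):
        occ = state_occupancies(p)
        assert occ.sum() == pytest.approx(1.0, abs=1e-12)
        assert occ == pytest.approx(binom.pmf(np.arange(5), 4, p), abs=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            state_occupancies(1.5)


class TestSimulateCurrent:
    def test_zero_current_at_reversal(self, params):
        stim = VoltageTrace(0.0, params.dt, np.full(500, params.E_Ca))
        I, _ = simulate_current(stim, params)
        assert np.all(I.I == 0.0)

    def test_constant_voltage_fixed_point(self, params):
        stim = VoltageTrace(0.0, params.dt, np.full(2000, -55.0))
        _, occ = simulate_current(stim, params, P_init="steady")
        p_open = occ[:, 4]
        assert np.ptp(p_open) <= params.dt * 1e-12

    def test_terminal_steady_state(self, params):
        # long hold relaxes the current to its steady value
        stim = VoltageTrace(0.0, params.dt, np.full(6000, -20.0))
        I, _ = simulate_current(stim, params, P_init=0.2)
        expected = steady_open_probability(-20.0, params) * (-20.0 - params.E_Ca)
        assert I.I[-1] == pytest.approx(expected, abs=1e-6)

    def test_occupancy_conservation(self, step_response):
        _, _, occ = step_response
        assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-10

    def test_dt_mismatch_rejected(self, params):
        stim = VoltageTrace(0.0, 0.02, np.full(100, -70.0))
        with pytest.raises(ConfigurationError):
            simulate_current(stim, params)

    def test_deterministic(self, params):
        stim = make_step(params, step_V=-10.0, dur_ms=5.0)
        I1, _ = simulate_current(stim, params)
        I2, _ = simulate_current(stim, params)
        assert np.array_equal(I1.I, I2.I)

    def test_euler_convergence_order(self, params):
        # halving dt changes the trajectory by O(dt): error vs a fine
        # reference shrinks roughly linearly
        stim = make_step(params)
        err_coarse = convergence_error(stim, params, refine=4)
        fine = CavParams(dt=params.dt / 2)
        stim_f = make_step(fine)
        err_fine = convergence_error(stim_f, fine, refine=4)
        assert err_fine < err_coarse
        assert err_coarse < 0.01


class TestIVCurve:
    def test_zero_at_reversal(self, params):
        iv = steady_iv_curve([params.E_Ca], params)
        assert iv[0, 1] == pytest.approx(0.0)

    def test_value_at_half_activation(self, params):
        iv = steady_iv_curve([-17.0], params)
        assert iv[0, 1] == pytest.approx(0.5 * (-17.0 - 60.0))  # -38.5

    def test_minimum_location(self, params):
        V = np.linspace(-80, 60, 1401)
        iv = steady_iv_curve(V, params)
        v_min = iv[np.argmin(iv[:, 1]), 0]
        assert params.V_Cav50 < v_min < params.E_Ca

    def test_empty_grid(self, params):
        with pytest.raises(ValueError):
            steady_iv_curve([], params)


class TestAugmentationRatio:
    def test_identical_traces(self, step_response):
        _, current, _ = step_response
        assert augmentation_ratio(current, current, (10.0, 25.0)) == 1.0

    def test_zero_control(self, params):
        from cavprime import CurrentTrace
        flat = CurrentTrace(0.0, params.dt, np.zeros(3000))
        with pytest.raises(UndefinedRatioError):
            augmentation_ratio(flat, flat, (10.0, 25.0))


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": -0.1}, {"k_on": 0.0}, {"dt": 0.001}, {"dt": 0.1},
        {"E_Ca": -30.0, "V_Cav50": -17.0},
    ])
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            CavParams(**kwargs)
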