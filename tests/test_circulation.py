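"""Unit and property tests of the closed-loop 0D circulation model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import cardioinverse as ci
from cardioinverse import _kernel as K
from cardioinverse import circulation_model as cm


# ---------------------------------------------------------------------------
# ventricular activation
# ---------------------------------------------------------------------------

class TestActivation:
    def test_zero_throughout_diastole(self, base_params):
        timing = base_params.timing
        T = 0.8
        tsys = timing.tsys0 - timing.ksys / T
        for phase in np.linspace(tsys / T + 1e-9, 1 - 1e-9, 7):
            assert cm.ventricular_activation(phase, timing, T) == 0.0

    def test_unit_peak_at_mid_systole(self, base_params):
        timing = base_params.timing
        T = 0.8
        tsys = timing.tsys0 - timing.ksys / T
        peak_phase = tsys / (2 * T)
        assert cm.ventricular_activation(peak_phase, timing, T) == pytest.approx(1.0)

    def test_bounded_with_single_contiguous_peak(self, base_params):
        timing = base_params.timing
        T = 0.9
        phases = np.linspace(0, 1, 5000, endpoint=False)
        phi = np.array([cm.ventricular_activation(p, timing, T) for p in phases])
        assert np.all((phi >= 0) & (phi <= 1))
        assert phi.max() == pytest.approx(1.0, abs=1e-5)
        near_peak = np.nonzero(phi > 0.999)[0]
        assert np.all(np.diff(near_peak) == 1)  # one contiguous summit

    def test_cycle_integral_matches_quadrature_oracle(self, base_params):
        # closed form: integral of sin^2(pi u / tsys) over [0, tsys] = tsys/2
        timing = base_params.timing
        T = 0.85
        tsys = timing.tsys0 - timing.ksys / T
        u = np.linspace(0, T, 100001)  # ~dt/10 of the solver step
        phi = np.array([K.activation(x, T, timing.tsys0, timing.ksys) for x in u])
        quad = np.trapezoid(phi, u)
        assert quad == pytest.approx(tsys / 2, rel=1e-6)

    def test_rejects_phase_outside_cycle(self, base_params):
        with pytest.raises(ValueError):
            cm.ventricular_activation(1.0, base_params.timing)


# ---------------------------------------------------------------------------
# ventricle pressure and valves
# ---------------------------------------------------------------------------

class TestVentriclePressure:
    def test_end_systolic_line_through_unstressed_volume(self, base_params):
        lv = base_params.left_ventricle
        assert cm.ventricle_pressure(lv.vu, 1.0, lv, emax=2.0) == pytest.approx(0.0)

    def test_diastolic_curve_through_origin(self, base_params):
        assert cm.ventricle_pressure(0.0, 0.0, base_params.left_ventricle) == 0.0

    def test_linear_elastance_arithmetic(self, base_params):
        lv = base_params.left_ventricle
        p = cm.ventricle_pressure(lv.vu + 50.0, 1.0, lv, emax=2.0)
        assert p == pytest.approx(100.0)

    @given(st.floats(0.0, 1.0), st.floats(10.0, 250.0), st.floats(10.0, 250.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_volume(self, phi, v1, v2):
        lv = cm.VentricleParameters(emax0=2.392, p0=1.5, ke=0.014,
                                    vu=16.77, kr=0.000375)
        p1 = cm.ventricle_pressure(v1, phi, lv, emax=2.5)
        p2 = cm.ventricle_pressure(v2, phi, lv, emax=2.5)
        if v1 < v2:
            assert p1 < p2
        elif v1 > v2:
            assert p1 > p2

    def test_overflow_guard(self, base_params):
        with pytest.raises(OverflowError):
            cm.ventricle_pressure(1e5, 0.0, base_params.left_ventricle)


class TestValveFlow:
    @pytest.mark.parametrize("pu,pd,r,expected", [
        (10.0, 5.0, 1.0, 5.0),   # Ohmic open valve
        (5.0, 10.0, 1.0, 0.0),   # closed: no backflow
        (7.0, 7.0, 2.0, 0.0),    # zero-gradient boundary
    ])
    def test_ideal_diode(self, pu, pd, r, expected):
        assert cm.valve_flow(pu, pd, r) == expected

    @given(st.floats(-50, 250), st.floats(-50, 250), st.floats(1e-4, 10))
    @settings(max_examples=100, deadline=None)
    def test_never_negative(self, pu, pd, r):
        assert cm.valve_flow(pu, pd, r) >= 0.0

    def test_rejects_nonpositive_resistance(self):
        with pytest.raises(ValueError):
            cm.valve_flow(10, 5, 0.0)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

class TestCompartmentRhs:
    def test_closed_loop_volume_derivatives_sum_to_zero(self, base_params):
        y0, _, _ = cm.initial_state(base_params)
        rng = np.random.default_rng(3)
        for _ in range(5):
            y = y0.copy()
            y[:11] *= 1.0 + 0.05 * rng.standard_normal(11)
            dy = cm.compartment_rhs(y, base_params, cycle_time=0.1, t_heart=0.8)
            assert abs(np.sum(dy[:11])) < 1e-9 * base_params.total_blood_volume

    def test_nonfinite_state_signalled(self, base_params):
        y0, _, _ = cm.initial_state(base_params)
        y0[0] = np.nan
        with pytest.raises(FloatingPointError):
            cm.compartment_rhs(y0, base_params)

    def test_against_adaptive_solver_oracle(self, base_params):
        """Fixed-step RK4 vs scipy's adaptive RK45 on the same vector field.

        With every reflex gain zeroed the delayed inputs are inert and the
        heart period is constant, so the kernel integrates exactly the ODE
        seen by the oracle; they must agree to valve-switching accuracy.
        """
        p = base_params.copy()
        for e in p.baroreflex.effectors.values():
            e.gain = 0.0
        T = p.timing.t0
        y0, fes0, fev0 = cm.initial_state(p)
        pk = cm.pack_parameters(p)

        t_final = 4.0
        trace, *_ = K.integrate(pk, y0, t_final, 0.002, fes0, fev0)

        fes_del = np.full(7, fes0)

        def rhs(t, y):
            dy = np.empty(K.N_STATES)
            K.rhs(y, pk, t % T, T, fes_del, fev0, dy)
            return dy

        sol = solve_ivp(rhs, (0.0, t_final), y0, method="RK45",
                        rtol=1e-8, atol=1e-8, dense_output=True)
        sap_oracle = (sol.sol(trace[:, K.O_T])[K.S_V_SA]
                      - pk[K.VU_SA]) / pk[K.C_SA]
        assert np.max(np.abs(trace[:, K.O_SAP] - sap_oracle)) < 0.5  # mmHg


# ---------------------------------------------------------------------------
# baroreflex statics
# ---------------------------------------------------------------------------

class TestBaroreflex:
    def test_zero_gain_effector_is_inert(self, base_params):
        b = base_params.baroreflex
        p = base_params.copy()
        p.baroreflex.effectors["emax_lv"].gain = 0.0
        out = cm.baroreflex_update(70.0, p.baroreflex)
        assert out["emax_lv"] == 0.0  # no offset: Emax stays at its basal value

    def test_sympathetic_offsets_fall_with_pressure(self, base_params):
        b = base_params.baroreflex
        offsets = [cm.baroreflex_update(pc, b)["emax_lv"] for pc in (60, 92, 120)]
        assert offsets[0] > offsets[1] > offsets[2] > 0

    def test_afferent_firing_saturates(self, base_params):
        b = base_params.baroreflex
        low = cm.baroreflex_update(0.0, b)
        high = cm.baroreflex_update(300.0, b)
        assert low["f_ab"] == pytest.approx(b.f_min, rel=0.02)
        assert high["f_ab"] == pytest.approx(b.f_max, rel=0.02)

    def test_effector_state_relaxes_monotonically_to_step(self, base_params):
        # first-order effector: sustained hypotension drives Emax up monotonely
        b = base_params.baroreflex
        sigma = b.effectors["emax_lv"].gain * np.log(
            cm.baroreflex_update(60.0, b)["f_es"] - b.f_es_min + 1)
        tau = b.effectors["emax_lv"].tau
        x = cm.baroreflex_update(92.0, b)["emax_lv"]  # basal offset
        xs = [x]
        dt = 0.01
        for _ in range(6000):  # ~7.5 effector time constants
            x += dt * (sigma - x) / tau
            xs.append(x)
        diffs = np.diff(xs)
        assert np.all(diffs >= -1e-12)
        assert xs[-1] == pytest.approx(sigma, rel=0.01)


# ---------------------------------------------------------------------------
# full simulation
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_blood_volume_conserved(self, base_params, baseline_sim):
        drift = np.abs(baseline_sim.total_volume - base_params.total_blood_volume)
        assert drift.max() < 1e-6 * base_params.total_blood_volume

    def test_valve_flows_unidirectional(self, baseline_sim):
        assert (baseline_sim.valve_flows.to_numpy() >= 0.0).all()

    def test_deterministic(self, base_params, baseline_sim):
        again = ci.simulate(base_params)
        assert np.array_equal(again.sap, baseline_sim.sap)

    def test_time_grid_uniform(self, baseline_sim):
        steps = np.diff(baseline_sim.time)
        assert np.allclose(steps, steps[0])
        assert np.all(np.isfinite(baseline_sim.sap))
        assert np.all(np.isfinite(baseline_sim.pap))

    def test_steady_state_flag_at_baseline(self, baseline_sim):
        assert baseline_sim.steady_state_reached

    def test_dt_refinement_converges(self, base_params, baseline_sim):
        s = baseline_sim.analysis_slice
        msap_coarse = baseline_sim.sap[s].mean()
        fine = ci.simulate(base_params, dt=0.001)
        msap_fine = fine.sap[fine.analysis_slice].mean()
        assert abs(msap_coarse - msap_fine) < 0.1  # mmHg

    def test_lvef_monotone_in_contractility_without_reflex(self, base_params):
        p0 = base_params.copy()
        for e in p0.baroreflex.effectors.values():
            e.gain = 0.0
        efs = []
        for emax in (1.5, 2.2, 2.95):
            p = p0.copy()
            p.left_ventricle.emax = emax
            h = ci.extract_hemodynamics(ci.simulate(p))
            efs.append(h.lvef)
        assert efs[0] < efs[1] < efs[2]

    def test_severe_failure_dilates_and_depresses_pv_loop(self, base_params, ranges):
        low = ci.LVSystolicParameters.from_array(ranges.lower)
        high = ci.LVSystolicParameters.from_array(ranges.upper)
        h_low = ci.extract_hemodynamics(ci.simulate(ci.apply_parameters(base_params, low)))
        h_high = ci.extract_hemodynamics(ci.simulate(ci.apply_parameters(base_params, high)))
        assert h_low.lvedv > h_high.lvedv
        assert h_low.lvef < h_high.lvef

    def test_nonphysiological_parameters_abort_with_diagnostic(self, base_params):
        p = base_params.copy()
        p.left_ventricle.ke = 0.5  # absurd EDPVR steepness -> blow-up
        with pytest.raises(FloatingPointError, match="non-finite state"):
            ci.simulate(p, duration=12.0)

    def test_invalid_arguments_rejected(self, base_params):
        with pytest.raises(ValueError):
            ci.simulate(base_params, dt=-1.0)
        with pytest.raises(ValueError):
            ci.simulate(base_params, duration=5.0, transient=10.0)


class TestConfigRoundTrip:
    def test_dict_round_trip_preserves_packed_parameters(self, base_params):
        d = base_params.to_dict()
        rebuilt = cm.CirculationParameters.from_dict(d)
        assert np.array_equal(cm.pack_parameters(rebuilt),
                              cm.pack_parameters(base_params))

    def test_missing_compartment_rejected(self, base_params):
        d = base_params.to_dict()
        d["compartments"].pop("left_atrium")
        with pytest.raises(ValueError, match="missing compartments"):
            cm.CirculationParameters.from_dict(d)

    def test_output_table_has_unit_columns(self, baseline_sim):
        df = baseline_sim.to_frame()
        assert "sap_mmHg" in df.columns and "time_s" in df.columns
        assert len(df) == len(baseline_sim.time)
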