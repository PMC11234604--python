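"""Circulation-model mechanics: elastance, derivatives, steady-state simulation."""

import numpy as np
import pytest

from cardiofit.cv_models import (
    CVParameters,
    SolverConfig,
    WaveformRecord,
    closed_loop_derivatives,
    derive_outputs,
    open_loop_derivatives,
    simulate,
    ventricular_elastance,
)
from cardiofit.personalization import typical_parameters


class TestVentricularElastance:
    def test_cycle_endpoints_and_peak(self, closed_params):
        p = closed_params
        assert ventricular_elastance(0.0, p) == pytest.approx(p.E_min)
        assert ventricular_elastance(p.t_peak, p) == pytest.approx(p.E_max)
        assert ventricular_elastance(p.T, p) == pytest.approx(p.E_min)

    def test_half_activation_value(self):
        # sin²(π/4) = 1/2 halfway up the rise: E = E_min + (E_max − E_min)/2
        p = CVParameters(C_ao=1.0, E_max=2.0, E_min=0.06, R_mv=0.01, R_sys=1.0,
                         T=1.0, t_peak=0.4, Z_ao=0.03)
        assert ventricular_elastance(0.2, p) == pytest.approx(0.06 + 1.94 * 0.5)

    def test_fully_relaxed_after_t_rel(self, closed_params):
        p = closed_params
        t_rel = min(1.5 * p.t_peak, p.T)
        t = np.linspace(t_rel + 1e-9, p.T, 20)
        assert np.allclose(ventricular_elastance(t, p), p.E_min)

    def test_activation_bounded_and_continuous(self, closed_params):
        p = closed_params
        t = np.linspace(0, p.T, 5000)
        e = ventricular_elastance(t, p)
        assert np.all(e >= p.E_min - 1e-12) and np.all(e <= p.E_max + 1e-12)
        assert np.max(np.abs(np.diff(e))) < 0.02 * (p.E_max - p.E_min)

    def test_domain_error_outside_cycle(self, closed_params):
        with pytest.raises(ValueError):
            ventricular_elastance(-0.01, closed_params)
        with pytest.raises(ValueError):
            ventricular_elastance(closed_params.T + 0.01, closed_params)


class TestDerivatives:
    def test_closed_loop_conserves_volume(self, closed_params):
        d = closed_loop_derivatives([120.0, 150.0, 130.0], 0.1, closed_params)
        assert d.sum() == pytest.approx(0.0, abs=1e-12)

    def test_closed_loop_hand_arithmetic(self):
        # P_ao = 150/1.5 = 100, P_sv = 1000/100 = 10 → Q_sys = 90 mL/s
        p = CVParameters(C_ao=1.5, C_sv=100.0, E_max=2.0, E_min=0.06, R_mv=0.01,
                         R_sys=1.0, T=1.0, t_peak=0.3, V_tot=1300.0, Z_ao=0.03)
        d = closed_loop_derivatives([150.0, 150.0, 1000.0], 0.0, p)
        # at t=0 the elastance is E_min: P_lv = 9 < P_ao, P_sv > P_lv → mitral open
        q_sys = 90.0
        assert d[1] == pytest.approx(-q_sys)  # dV_ao = Q_lvao − Q_sys = −90

    def test_both_diodes_reverse_biased(self, closed_params):
        # P_sv < P_lv < P_ao: only the peripheral flow is nonzero
        p = closed_params
        t = p.t_peak  # peak elastance
        v_lv = 50.0
        p_lv = p.E_max * v_lv
        v_ao = p.C_ao * (p_lv + 50.0)
        v_sv = p.C_sv * (p_lv - 50.0)
        d = closed_loop_derivatives([v_lv, v_ao, v_sv], t, p)
        assert d[0] == 0.0  # no ventricular in/outflow
        assert d[1] < 0 and d[2] > 0  # peripheral run-off only

    def test_open_loop_rc_decay(self, open_params):
        # valves closed → dP_ao/dt = −P_ao/(R_sys·C_ao) = −80/1.6 = −50
        p = open_params.replace(C_ao=1.6, R_sys=1.0)
        v_lv = 10.0  # P_lv well below both P_fill-threshold? no: keep P_lv > P_fill
        d = open_loop_derivatives([v_lv, 80.0], p.t_peak, p, P_fill=0.1)
        assert d[1] == pytest.approx(-50.0)

    def test_open_loop_diode_thresholds(self, open_params):
        p = open_params
        p_fill = 7.5
        v_lv = p_fill / p.E_min  # P_lv = P_fill at diastole
        d = open_loop_derivatives([v_lv, p_fill], 0.0, p, P_fill=p_fill)
        assert d[0] == 0.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CVParameters(C_ao=-1.0, E_max=2.0, E_min=0.06, R_mv=0.01, R_sys=1.0,
                         T=1.0, t_peak=0.3, Z_ao=0.03)
        with pytest.raises(ValueError):
            CVParameters(C_ao=1.0, E_max=0.05, E_min=0.06, R_mv=0.01, R_sys=1.0,
                         T=1.0, t_peak=0.3, Z_ao=0.03)
        with pytest.raises(ValueError):  # C_sv without V_tot
            CVParameters(C_ao=1.0, E_max=2.0, E_min=0.06, R_mv=0.01, R_sys=1.0,
                         T=1.0, t_peak=0.3, Z_ao=0.03, C_sv=20.0)


class TestSimulate:
    def test_closed_loop_volume_conservation(self, closed_sim, closed_params):
        total = closed_sim.states.sum(axis=1)
        assert np.max(np.abs(total - closed_params.V_tot)) / closed_params.V_tot < 1e-6

    def test_steady_state_is_periodic(self, closed_sim):
        assert closed_sim.converged
        w = closed_sim.waveform
        assert abs(w.P_ao[0] - w.P_ao[-1]) / w.P_ao[0] < 1e-3

    def test_physiological_output_ranges(self, closed_sim, open_sim):
        for sim in (closed_sim, open_sim):
            s = sim.summary
            assert 50 <= s.SV <= 120
            assert 90 <= s.P_sys <= 180
            assert s.P_dia <= s.MAP <= s.P_sys

    def test_frozen_regression_values(self, closed_sim):
        # regression guard: the documented typical closed-loop hemodynamics
        s = closed_sim.summary
        assert s.P_sys == pytest.approx(141.06, abs=0.1)
        assert s.P_dia == pytest.approx(89.00, abs=0.1)
        assert s.SV == pytest.approx(87.20, abs=0.1)
        assert s.MVP == pytest.approx(6.01, abs=0.05)

    def test_no_pump_function_gives_zero_stroke_volume(self, closed_params):
        p = closed_params.replace(E_max=closed_params.E_min * (1 + 1e-9))
        sim = simulate(p)
        assert sim.summary.SV == pytest.approx(0.0, abs=1e-3)

    def test_open_loop_diastolic_decay_matches_closed_form(self, open_params):
        # both valves shut: P_ao decays as exp(−t/(R_sys·C_ao))
        p = open_params.replace(E_max=0.07, E_min=0.06, R_sys=1.0, C_ao=1.6)
        solver = SolverConfig(p_fill=1.0, max_cycles=1)
        sim = simulate(p, solver=solver, store_trajectory=True)
        n = int(0.4 / solver.dt)
        t = np.arange(n + 1) * solver.dt
        p_ao = sim.trajectory[: n + 1, 1]
        expected = p_ao[0] * np.exp(-t / (p.R_sys * p.C_ao))
        assert np.max(np.abs(p_ao - expected) / expected) < 0.01

    def test_open_loop_mean_flow_identity(self, open_sim, open_params):
        # at steady state mean outflow equals CO, so MAP ≈ CO·R_sys
        s = open_sim.summary
        assert s.MAP == pytest.approx(s.CO * open_params.R_sys, rel=0.01)

    def test_step_halving_changes_outputs_below_0p1_percent(self, open_params):
        a = simulate(open_params, solver=SolverConfig(dt=1e-3, tol=1e-6)).summary
        b = simulate(open_params, solver=SolverConfig(dt=5e-4, tol=1e-6)).summary
        assert abs(a.SV - b.SV) / b.SV < 1e-3
        assert abs(a.P_sys - b.P_sys) / b.P_sys < 1e-3

    def test_non_convergence_is_flagged_not_raised(self, closed_params):
        sim = simulate(closed_params, solver=SolverConfig(max_cycles=1))
        assert not sim.converged

    def test_closed_simulation_requires_closed_parameters(self, open_params):
        with pytest.raises(ValueError):
            simulate(open_params, model_kind="closed")


class TestDeriveOutputs:
    def test_constant_pressure(self):
        t = np.linspace(0, 1, 50)
        w = WaveformRecord(t=t, P_ao=np.full(50, 100.0), Q_lvao=np.zeros(50), T=1.0)
        s = derive_outputs(w)
        assert s.P_sys == s.P_dia == s.MAP == 100.0

    def test_half_sine_stroke_volume(self):
        # ∫ 300·sin(πt/0.3) dt over [0, 0.3] = 300·(2/π)·0.3 ≈ 57.2958 mL
        t = np.linspace(0, 0.9, 2001)
        q = np.where(t <= 0.3, 300.0 * np.sin(np.pi * t / 0.3), 0.0)
        w = WaveformRecord(t=t, P_ao=np.full_like(t, 100.0), Q_lvao=q, T=0.9)
        s = derive_outputs(w)
        assert s.SV == pytest.approx(300.0 * (2 / np.pi) * 0.3, rel=1e-4)
        assert s.CO == pytest.approx(s.SV / 0.9)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            WaveformRecord(t=[0.0], P_ao=[100.0], Q_lvao=[0.0], T=1.0)
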