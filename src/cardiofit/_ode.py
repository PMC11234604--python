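"""Numba kernels for the fixed-step RK4 integration of both circulation models.

Parameter vectors passed to the kernels use the fixed layout

    [C_ao, C_sv, E_max, E_min, R_mv, R_sys, T, t_peak, V_tot, Z_ao, P_fill]

with C_sv / V_tot ignored by the open-loop kernel and P_fill ignored by the
closed-loop kernel.  State layout: closed loop [V_lv, V_ao, V_sv] (stressed
volumes, mL); open loop [V_lv, P_ao].  The integration loops are written in
scalar form so numba compiles them to tight machine code: a cost-function
evaluation triggers thousands of cycle integrations during ensemble fitting.
"""

import numpy as np
from numba import njit

# parameter indices
C_AO, C_SV, E_MAX, E_MIN, R_MV, R_SYS, T, T_PEAK, V_TOT, Z_AO, P_FILL = range(11)


@njit(cache=True, fastmath=True)
def _phi(t, t_peak, t_rel):
    """Normalized elastance activation: 0 at cycle start, 1 at t_peak, 0 after t_rel."""
    if t <= t_peak:
        s = np.sin(0.5 * np.pi * t / t_peak)
        return s * s
    if t <= t_rel:
        c = np.cos(0.5 * np.pi * (t - t_peak) / (t_rel - t_peak))
        return c * c
    return 0.0


@njit(cache=True, fastmath=True)
def _integrate_closed(p, y0, dt, max_cycles, tol):
    """RK4 of the closed loop to periodic steady state.

    Returns (t_cycle, states, n_cycles, converged) with `states` holding the
    last integrated cycle inclusive of both endpoints."""
    period = p[T]
    n_steps = max(2, int(round(period / dt)))
    h = period / n_steps
    c_ao, c_sv = p[C_AO], p[C_SV]
    e_max, e_min = p[E_MAX], p[E_MIN]
    r_mv, r_sys, z_ao = p[R_MV], p[R_SYS], p[Z_AO]
    t_peak = p[T_PEAK]
    t_rel = min(1.5 * t_peak, period)

    prev = np.empty((n_steps + 1, 3))
    cur = np.empty((n_steps + 1, 3))
    v_lv, v_ao, v_sv = y0[0], y0[1], y0[2]
    converged = False
    n_cycles = 0
    for cyc in range(max_cycles):
        cur[0, 0] = v_lv
        cur[0, 1] = v_ao
        cur[0, 2] = v_sv
        for i in range(n_steps):
            t = i * h
            # four RK stages, scalar form
            e = e_min + (e_max - e_min) * _phi(t, t_peak, t_rel)
            q1 = max(0.0, (e * v_lv - v_ao / c_ao) / z_ao)
            qs = (v_ao / c_ao - v_sv / c_sv) / r_sys
            qm = max(0.0, (v_sv / c_sv - e * v_lv) / r_mv)
            k1a, k1b, k1c = qm - q1, q1 - qs, qs - qm

            th = t + 0.5 * h
            e = e_min + (e_max - e_min) * _phi(th, t_peak, t_rel)
            a = v_lv + 0.5 * h * k1a
            b = v_ao + 0.5 * h * k1b
            c = v_sv + 0.5 * h * k1c
            q1 = max(0.0, (e * a - b / c_ao) / z_ao)
            qs = (b / c_ao - c / c_sv) / r_sys
            qm = max(0.0, (c / c_sv - e * a) / r_mv)
            k2a, k2b, k2c = qm - q1, q1 - qs, qs - qm

            a = v_lv + 0.5 * h * k2a
            b = v_ao + 0.5 * h * k2b
            c = v_sv + 0.5 * h * k2c
            q1 = max(0.0, (e * a - b / c_ao) / z_ao)
            qs = (b / c_ao - c / c_sv) / r_sys
            qm = max(0.0, (c / c_sv - e * a) / r_mv)
            k3a, k3b, k3c = qm - q1, q1 - qs, qs - qm

            te = t + h
            e = e_min + (e_max - e_min) * _phi(te if te <= period else te - period, t_peak, t_rel)
            a = v_lv + h * k3a
            b = v_ao + h * k3b
            c = v_sv + h * k3c
            q1 = max(0.0, (e * a - b / c_ao) / z_ao)
            qs = (b / c_ao - c / c_sv) / r_sys
            qm = max(0.0, (c / c_sv - e * a) / r_mv)
            k4a, k4b, k4c = qm - q1, q1 - qs, qs - qm

            v_lv += (h / 6.0) * (k1a + 2.0 * (k2a + k3a) + k4a)
            v_ao += (h / 6.0) * (k1b + 2.0 * (k2b + k3b) + k4b)
            v_sv += (h / 6.0) * (k1c + 2.0 * (k2c + k3c) + k4c)
            cur[i + 1, 0] = v_lv
            cur[i + 1, 1] = v_ao
            cur[i + 1, 2] = v_sv
        n_cycles = cyc + 1

        if cyc > 0:
            worst = 0.0
            for i in range(n_steps + 1):
                for j in range(3):
                    scale = abs(prev[i, j])
                    if scale < 1e-9:
                        scale = 1e-9
                    d = abs(cur[i, j] - prev[i, j]) / scale
                    if d > worst:
                        worst = d
            if worst < tol:
                converged = True
        tmp = prev
        prev = cur
        cur = tmp
        if converged:
            break

    t_cycle = np.empty(n_steps + 1)
    for i in range(n_steps + 1):
        t_cycle[i] = i * h
    return t_cycle, prev.copy(), n_cycles, converged


@njit(cache=True, fastmath=True)
def _integrate_open(p, y0, dt, max_cycles, tol):
    """RK4 of the open loop (Windkessel + elastance ventricle) to steady state."""
    period = p[T]
    n_steps = max(2, int(round(period / dt)))
    h = period / n_steps
    c_ao = p[C_AO]
    e_max, e_min = p[E_MAX], p[E_MIN]
    r_mv, r_sys, z_ao = p[R_MV], p[R_SYS], p[Z_AO]
    p_fill = p[P_FILL]
    t_peak = p[T_PEAK]
    t_rel = min(1.5 * t_peak, period)

    prev = np.empty((n_steps + 1, 2))
    cur = np.empty((n_steps + 1, 2))
    v_lv, p_ao = y0[0], y0[1]
    converged = False
    n_cycles = 0
    for cyc in range(max_cycles):
        cur[0, 0] = v_lv
        cur[0, 1] = p_ao
        for i in range(n_steps):
            t = i * h
            e = e_min + (e_max - e_min) * _phi(t, t_peak, t_rel)
            q1 = max(0.0, (e * v_lv - p_ao) / z_ao)
            qm = max(0.0, (p_fill - e * v_lv) / r_mv)
            k1a = qm - q1
            k1b = (q1 - p_ao / r_sys) / c_ao

            th = t + 0.5 * h
            e = e_min + (e_max - e_min) * _phi(th, t_peak, t_rel)
            a = v_lv + 0.5 * h * k1a
            b = p_ao + 0.5 * h * k1b
            q1 = max(0.0, (e * a - b) / z_ao)
            qm = max(0.0, (p_fill - e * a) / r_mv)
            k2a = qm - q1
            k2b = (q1 - b / r_sys) / c_ao

            a = v_lv + 0.5 * h * k2a
            b = p_ao + 0.5 * h * k2b
            q1 = max(0.0, (e * a - b) / z_ao)
            qm = max(0.0, (p_fill - e * a) / r_mv)
            k3a = qm - q1
            k3b = (q1 - b / r_sys) / c_ao

            te = t + h
            e = e_min + (e_max - e_min) * _phi(te if te <= period else te - period, t_peak, t_rel)
            a = v_lv + h * k3a
            b = p_ao + h * k3b
            q1 = max(0.0, (e * a - b) / z_ao)
            qm = max(0.0, (p_fill - e * a) / r_mv)
            k4a = qm - q1
            k4b = (q1 - b / r_sys) / c_ao

            v_lv += (h / 6.0) * (k1a + 2.0 * (k2a + k3a) + k4a)
            p_ao += (h / 6.0) * (k1b + 2.0 * (k2b + k3b) + k4b)
            cur[i + 1, 0] = v_lv
            cur[i + 1, 1] = p_ao
        n_cycles = cyc + 1

        if cyc > 0:
            worst = 0.0
            for i in range(n_steps + 1):
                for j in range(2):
                    scale = abs(prev[i, j])
                    if scale < 1e-9:
                        scale = 1e-9
                    d = abs(cur[i, j] - prev[i, j]) / scale
                    if d > worst:
                        worst = d
            if worst < tol:
                converged = True
        tmp = prev
        prev = cur
        cur = tmp
        if converged:
            break

    t_cycle = np.empty(n_steps + 1)
    for i in range(n_steps + 1):
        t_cycle[i] = i * h
    return t_cycle, prev.copy(), n_cycles, converged


def _integrate(p, y0, closed, dt, max_cycles, tol, store_all):
    """Dispatch to the specialized kernels; optionally record the full
    multi-cycle trajectory by chaining single-cycle integrations."""
    if not store_all:
        if closed:
            t, states, n, conv = _integrate_closed(p, y0, dt, max_cycles, tol)
        else:
            t, states, n, conv = _integrate_open(p, y0, dt, max_cycles, tol)
        return t, states, n, conv, None

    kernel = _integrate_closed if closed else _integrate_open
    pieces = [y0[None, :].copy()]
    y = y0.copy()
    prev_cycle = None
    n_cycles = 0
    converged = False
    t = None
    for _ in range(max_cycles):
        t, states, _, _ = kernel(p, y, dt, 1, tol)
        pieces.append(states[1:])
        y = states[-1].copy()
        n_cycles += 1
        if prev_cycle is not None:
            scale = np.maximum(np.abs(prev_cycle), 1e-9)
            if np.max(np.abs(states - prev_cycle) / scale) < tol:
                converged = True
        prev_cycle = states
        if converged:
            break
    traj = np.concatenate(pieces, axis=0)
    return t, prev_cycle, n_cycles, converged, traj


@njit(cache=True, fastmath=True)
def _cost_kernel(p, y0, closed, dt, max_cycles, tol,
                 t_meas, p_meas, q_meas, sv_m, psys_m, pdia_m, w):
    """Full cost evaluation in compiled code.

    ``w`` layout: [K_p, K_q, K_p_sys, K_p_dia, K_SV, K_MVP, mvp_target,
    waveform_weight_ref, penalty].  Returns (J, y_end, converged)."""
    penalty = w[8]
    if closed:
        t_cycle, states, n_cycles, conv = _integrate_closed(p, y0, dt, max_cycles, tol)
    else:
        t_cycle, states, n_cycles, conv = _integrate_open(p, y0, dt, max_cycles, tol)
    y_end = states[-1].copy()
    if not conv:
        return penalty, y_end, False

    n_raw = t_cycle.shape[0]
    period = p[T]
    t_rel = min(1.5 * p[T_PEAK], period)
    p_ao_raw = np.empty(n_raw)
    q_raw = np.empty(n_raw)
    for i in range(n_raw):
        tt = t_cycle[i]
        if tt > period:
            tt = period
        e = p[E_MIN] + (p[E_MAX] - p[E_MIN]) * _phi(tt, p[T_PEAK], t_rel)
        p_lv = e * states[i, 0]
        if closed:
            pa = states[i, 1] / p[C_AO]
        else:
            pa = states[i, 1]
        p_ao_raw[i] = pa
        q_raw[i] = max(0.0, (p_lv - pa) / p[Z_AO])

    p_mod = np.interp(t_meas, t_cycle, p_ao_raw)
    q_mod = np.interp(t_meas, t_cycle, q_raw)

    n = t_meas.shape[0]
    p_sys = p_mod[0]
    p_dia = p_mod[0]
    sv = 0.0
    for i in range(n):
        if p_mod[i] > p_sys:
            p_sys = p_mod[i]
        if p_mod[i] < p_dia:
            p_dia = p_mod[i]
        if i > 0:
            sv += 0.5 * (q_mod[i] + q_mod[i - 1]) * (t_meas[i] - t_meas[i - 1])
    if not np.isfinite(sv) or sv <= 0.0:
        return penalty, y_end, True

    j = 0.0
    for i in range(n):
        dp = (p_meas[i] - p_mod[i]) / w[0]
        dq = (q_meas[i] - q_mod[i]) / w[1]
        j += dp * dp + dq * dq
    fac = (7.5 * n / w[7]) ** 2
    j += fac * (((psys_m - p_sys) / w[2]) ** 2 + ((pdia_m - p_dia) / w[3]) ** 2)
    j += fac * ((sv_m - sv) / w[4]) ** 2
    if closed:
        p_sv_raw = states[:, 2] / p[C_SV]
        p_sv = np.interp(t_meas, t_cycle, p_sv_raw)
        mvp = 0.0
        for i in range(1, n):
            mvp += 0.5 * (p_sv[i] + p_sv[i - 1]) * (t_meas[i] - t_meas[i - 1])
        mvp /= t_meas[n - 1] - t_meas[0]
        j += fac * ((w[6] - mvp) / w[5]) ** 2 / 9.0
    if not np.isfinite(j):
        return penalty, y_end, True
    return j, y_end, True
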