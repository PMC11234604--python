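"""Lumped-parameter (0D) models of the left ventricle and systemic circulation.

Two model variants are supported:

* ``"closed"`` — a closed-loop circuit of three compliant compartments
  (left ventricle with time-varying elastance, systemic arteries, systemic
  veins) exchanging a fixed total stressed blood volume ``V_tot`` through the
  aortic characteristic impedance ``Z_ao``, the peripheral resistance
  ``R_sys`` and the mitral valve resistance ``R_mv``.  Both valves are perfect
  unidirectional diodes (no backflow, no inertance).
* ``"open"`` — an open-loop three-element Windkessel (``Z_ao``, ``C_ao``,
  ``R_sys`` referenced to zero pressure) driven by the same elastance-based
  ventricle, filled from a constant venous source pressure ``P_fill``.

The ventricular pressure is ``P_lv = E(t) * V_lv`` where the elastance E(t)
cycles between ``E_min`` (diastole) and ``E_max`` (end systole), peaking at
``t_peak`` after the onset of activation (cycle time zero).

Simulation uses a fixed-step 4th-order Runge-Kutta scheme, integrating cycle
by cycle until the solution is periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import _ode

ModelKind = Literal["closed", "open"]

#: parameter names in kernel order (without the open-loop filling pressure)
PARAM_NAMES = ("C_ao", "C_sv", "E_max", "E_min", "R_mv", "R_sys", "T", "t_peak", "V_tot", "Z_ao")

#: parameters that carry mechanical units and are scaled when indexing by BSA
MECHANICAL_PARAMS = ("C_ao", "C_sv", "E_max", "E_min", "R_mv", "R_sys", "V_tot", "Z_ao")


@dataclass
class CVParameters:
    """Mechanical parameter vector of the circulation models.

    Units: compliances mL/mmHg, elastances mmHg/mL, resistances and
    impedances mmHg·s/mL, volumes mL, times s.  ``C_sv`` and ``V_tot`` exist
    only in the closed-loop model and are ``None`` for open-loop parameter
    sets.  ``bsa_indexed`` flags values divided by body surface area (per-m²
    units).
    """

    C_ao: float
    E_max: float
    E_min: float
    R_mv: float
    R_sys: float
    T: float
    t_peak: float
    Z_ao: float
    C_sv: float | None = None
    V_tot: float | None = None
    bsa_indexed: bool = False

    def __post_init__(self) -> None:
        for name in ("C_ao", "E_max", "E_min", "R_mv", "R_sys", "T", "t_peak", "Z_ao"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("C_sv", "V_tot"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be strictly positive when present, got {v!r}")
        if self.E_max <= self.E_min:
            raise ValueError(f"E_max ({self.E_max}) must exceed E_min ({self.E_min})")
        if not (0 < self.t_peak < self.T):
            raise ValueError(f"t_peak must lie in (0, T), got {self.t_peak} with T={self.T}")
        if (self.C_sv is None) != (self.V_tot is None):
            raise ValueError("C_sv and V_tot must be given together (closed loop) or both omitted")

    @property
    def kind(self) -> ModelKind:
        return "closed" if self.C_sv is not None else "open"

    def replace(self, **kw) -> "CVParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = {n: getattr(self, n) for n in PARAM_NAMES}
        d["bsa_indexed"] = self.bsa_indexed
        return d

    def to_array(self, p_fill: float = 7.5) -> np.ndarray:
        """Kernel-layout array; absent closed-loop fields become NaN."""
        vals = [getattr(self, n) for n in PARAM_NAMES]
        vals = [np.nan if v is None else float(v) for v in vals]
        return np.array(vals + [p_fill], dtype=float)

    @classmethod
    def from_dict(cls, d: dict) -> "CVParameters":
        known = {k: d.get(k) for k in PARAM_NAMES}
        return cls(bsa_indexed=bool(d.get("bsa_indexed", False)), **known)


@dataclass
class WaveformRecord:
    """One cardiac cycle of synchronized aortic pressure and flow samples."""

    t: np.ndarray  # s, uniform, spans exactly one period
    P_ao: np.ndarray  # mmHg
    Q_lvao: np.ndarray  # mL/s
    T: float  # heart period, s

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.P_ao = np.asarray(self.P_ao, dtype=float)
        self.Q_lvao = np.asarray(self.Q_lvao, dtype=float)
        n = len(self.t)
        if n < 2 or len(self.P_ao) != n or len(self.Q_lvao) != n:
            raise ValueError("t, P_ao and Q_lvao must share a common length N >= 2")
        if self.T <= 0:
            raise ValueError("heart period T must be positive")

    @property
    def N(self) -> int:
        return len(self.t)


@dataclass
class SummaryHemodynamics:
    """Cycle-level summaries derived from simulated or measured waveforms."""

    P_sys: float  # mmHg
    P_dia: float  # mmHg
    MAP: float  # mmHg, time average over the cycle
    SV: float  # mL
    CO: float  # mL/s
    ESV_model: float | None = None  # mL, minimum LV volume over the cycle
    MVP: float | None = None  # mmHg, mean venous pressure (closed loop only)


@dataclass
class SolverConfig:
    """Fixed-step RK4 settings for cycle-to-cycle steady-state simulation."""

    dt: float = 1e-3  # s
    max_cycles: int = 50
    tol: float = 1e-4  # per-sample relative periodicity criterion
    n_samples: int = 100  # output resampling
    p_fill: float = 7.5  # mmHg, open-loop venous source pressure

    def to_dict(self) -> dict:
        return {"dt": self.dt, "max_cycles": self.max_cycles, "tol": self.tol,
                "n_samples": self.n_samples, "p_fill": self.p_fill}


@dataclass
class SimulationResult:
    """Periodic steady-state output of one model simulation."""

    waveform: WaveformRecord
    summary: SummaryHemodynamics
    v_lv: np.ndarray  # mL, resampled LV volume over the output cycle
    states: np.ndarray  # raw final-cycle state samples (n_steps+1, n_state)
    t_cycle: np.ndarray  # s, raw final-cycle sample times
    trajectory: np.ndarray | None  # full multi-cycle state history if stored
    n_cycles: int
    converged: bool
    kind: ModelKind
    params: CVParameters = field(repr=False, default=None)


def ventricular_elastance(t, params: CVParameters):
    """Time-varying ventricular elastance E(t) in mmHg/mL.

    The activation rises as sin² to its peak at ``t_peak`` and relaxes as cos²
    until ``T_rel = min(1.5 t_peak, T)``, after which the ventricle is fully
    relaxed (E = E_min).  Accepts scalars or arrays; t must lie in [0, T].
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > params.T):
        raise ValueError(f"t must lie within [0, T={params.T}]")
    t_rel = min(1.5 * params.t_peak, params.T)
    phi = np.zeros_like(t_arr)
    up = t_arr <= params.t_peak
    phi[up] = np.sin(0.5 * np.pi * t_arr[up] / params.t_peak) ** 2
    down = (~up) & (t_arr <= t_rel)
    phi[down] = np.cos(0.5 * np.pi * (t_arr[down] - params.t_peak) / (t_rel - params.t_peak)) ** 2
    e = params.E_min + (params.E_max - params.E_min) * phi
    return float(e) if np.isscalar(t) else e


def closed_loop_derivatives(state, t: float, params: CVParameters):
    """d/dt of the closed-loop stressed volumes (V_lv, V_ao, V_sv) in mL/s."""
    if params.kind != "closed":
        raise ValueError("closed_loop_derivatives requires closed-loop parameters")
    v_lv, v_ao, v_sv = state
    p_lv = ventricular_elastance(t % params.T, params) * v_lv
    p_ao = v_ao / params.C_ao
    p_sv = v_sv / params.C_sv
    q_lvao = max(0.0, (p_lv - p_ao) / params.Z_ao)
    q_sys = (p_ao - p_sv) / params.R_sys
    q_mv = max(0.0, (p_sv - p_lv) / params.R_mv)
    return np.array([q_mv - q_lvao, q_lvao - q_sys, q_sys - q_mv])


def open_loop_derivatives(state, t: float, params: CVParameters, P_fill: float = 7.5):
    """d/dt of the open-loop state (V_lv in mL/s, P_ao in mmHg/s)."""
    if P_fill <= 0:
        raise ValueError("P_fill must be positive")
    v_lv, p_ao = state
    p_lv = ventricular_elastance(t % params.T, params) * v_lv
    q_mv = max(0.0, (P_fill - p_lv) / params.R_mv)
    q_lvao = max(0.0, (p_lv - p_ao) / params.Z_ao)
    return np.array([q_mv - q_lvao, (q_lvao - p_ao / params.R_sys) / params.C_ao])


def _initial_state(params: CVParameters, kind: ModelKind, p_fill: float) -> np.ndarray:
    if kind == "closed":
        # rough diastolic split of the stressed volume; steady state forgets it
        v_ao = min(0.45 * params.V_tot, params.C_ao * 85.0)
        v_lv = min(0.35 * params.V_tot, 6.0 / params.E_min)
        v_sv = params.V_tot - v_ao - v_lv
        if v_sv <= 0:
            v_lv = 0.3 * params.V_tot
            v_ao = 0.4 * params.V_tot
            v_sv = params.V_tot - v_lv - v_ao
        return np.array([v_lv, v_ao, v_sv])
    return np.array([p_fill / params.E_min, 90.0])


def simulate(
    params: CVParameters,
    model_kind: ModelKind | None = None,
    solver: SolverConfig | None = None,
    store_trajectory: bool = False,
    initial_state: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate a model to periodic steady state and derive its outputs.

    Non-convergence within ``solver.max_cycles`` is reported on the result
    (``converged=False``), not raised, so callers can decide how to handle it.
    ``initial_state`` allows warm-starting from a previous steady state; for
    the closed loop it is rescaled so the volumes sum to ``V_tot``.
    """
    solver = solver or SolverConfig()
    kind = model_kind or params.kind
    if kind == "closed" and params.kind != "closed":
        raise ValueError("closed-loop simulation requires C_sv and V_tot")
    p = params.to_array(p_fill=solver.p_fill)
    if initial_state is not None:
        y0 = np.asarray(initial_state, dtype=float).copy()
        n_expected = 3 if kind == "closed" else 2
        if y0.shape != (n_expected,) or not np.all(np.isfinite(y0)):
            y0 = _initial_state(params, kind, solver.p_fill)
        elif kind == "closed":
            total = y0.sum()
            y0 = y0 * (params.V_tot / total) if total > 0 else _initial_state(params, kind, solver.p_fill)
    else:
        y0 = _initial_state(params, kind, solver.p_fill)
    t_cycle, states, n_cycles, converged, traj = _ode._integrate(
        p, y0, kind == "closed", solver.dt, solver.max_cycles, solver.tol, store_trajectory
    )

    # reconstruct pressures/flows on the raw cycle grid
    e = ventricular_elastance(np.clip(t_cycle, 0, params.T), params)
    v_lv_raw = states[:, 0]
    p_lv = e * v_lv_raw
    if kind == "closed":
        p_ao_raw = states[:, 1] / params.C_ao
        p_sv_raw = states[:, 2] / params.C_sv
    else:
        p_ao_raw = states[:, 1]
        p_sv_raw = None
    q_raw = np.maximum(0.0, (p_lv - p_ao_raw) / params.Z_ao)

    # resample the final cycle to the output grid
    t_out = np.linspace(0.0, params.T, solver.n_samples)
    p_ao = np.interp(t_out, t_cycle, p_ao_raw)
    q = np.interp(t_out, t_cycle, q_raw)
    v_lv = np.interp(t_out, t_cycle, v_lv_raw)

    waveform = WaveformRecord(t=t_out, P_ao=p_ao, Q_lvao=q, T=params.T)
    p_sv = np.interp(t_out, t_cycle, p_sv_raw) if p_sv_raw is not None else None
    summary = derive_outputs(waveform, lv_volume_trace=v_lv, venous_pressure_trace=p_sv)

    return SimulationResult(
        waveform=waveform,
        summary=summary,
        v_lv=v_lv,
        states=states,
        t_cycle=t_cycle,
        trajectory=traj if store_trajectory else None,
        n_cycles=n_cycles,
        converged=converged,
        kind=kind,
        params=params,
    )


def derive_outputs(
    w: WaveformRecord,
    lv_volume_trace: np.ndarray | None = None,
    venous_pressure_trace: np.ndarray | None = None,
) -> SummaryHemodynamics:
    """Cycle summaries: extrema and time averages of pressure, stroke volume, CO."""
    if w.N < 2:
        raise ValueError("waveform must have at least two samples")
    sv = float(np.trapezoid(w.Q_lvao, w.t))
    mvp = None
    if venous_pressure_trace is not None:
        mvp = float(np.trapezoid(venous_pressure_trace, w.t) / (w.t[-1] - w.t[0]))
    return SummaryHemodynamics(
        P_sys=float(np.max(w.P_ao)),
        P_dia=float(np.min(w.P_ao)),
        MAP=float(np.trapezoid(w.P_ao, w.t) / (w.t[-1] - w.t[0])),
        SV=sv,
        CO=sv / w.T,
        ESV_model=float(np.min(lv_volume_trace)) if lv_volume_trace is not None else None,
        MVP=mvp,
    )
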