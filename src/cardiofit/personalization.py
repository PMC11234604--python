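"""Model personalization: cost function, ensemble optimization, BSA indexing.

The model is fitted to one participant-day of measurements by minimizing a
weighted least-squares cost over the pressure and flow waveforms with extra
weight on systolic/diastolic pressure and stroke volume, and (closed loop
only) a soft constraint pulling the mean venous pressure toward a 6 mmHg
physiological target:

    J(θ) = Σ_i ((P_ao,i^m − P_ao,i)/K_p)² + Σ_i ((Q_ao,i^m − Q_ao,i)/K_q)²
         + (7.5² N²/40²) [ ((P_sys^m − P_sys)/K_p,sys)² + ((P_dia^m − P_dia)/K_p,dia)² ]
         + (7.5² N²/40²) [ ((SV^m − SV)/K_SV)² + (1/9) ((6.0 − MVP)/K_MVP)² ]

where m superscripts are measurements and N is the waveform sample count.
Because local minima are common, estimation runs an ensemble of bounded
local optimizations from uniformly sampled starting points; the worst
members are filtered out and the kept members averaged per parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import optimize as _sciopt

from .cv_models import (
    CVParameters,
    MECHANICAL_PARAMS,
    ModelKind,
    SimulationResult,
    SolverConfig,
    WaveformRecord,
    _initial_state,
    simulate,
)

#: cost value returned for non-physical or non-convergent simulations
PENALTY_COST = 1e12

#: default typical parameter values used to center optimization bounds and
#: as the synthetic population means.  Tuned once so each model variant
#: reproduces the hemodynamics of a middle-aged pre-hypertensive adult
#: (SBP ≈ 138, DBP ≈ 87 mmHg, SV ≈ 85 mL, and for the closed loop a mean
#: venous pressure ≈ 6 mmHg).
TYPICAL_PARAMETERS = {
    "C_ao": 1.25,  # mL/mmHg
    "C_sv": 25.0,  # mL/mmHg
    "E_max": 2.7,  # mmHg/mL
    "E_min": 0.04,  # mmHg/mL
    "R_mv": 0.002,  # mmHg s/mL
    "R_sys": 1.13,  # mmHg s/mL
    "T": 0.9,  # s
    "t_peak": 0.32,  # s
    "V_tot": 400.0,  # mL (total stressed volume)
    "Z_ao": 0.035,  # mmHg s/mL
}

#: open-loop variant: no venous compartment, filling from a constant source
#: pressure, so the diastolic parameters differ from the closed loop
TYPICAL_PARAMETERS_OPEN = {
    "C_ao": 1.26,
    "E_max": 2.69,
    "E_min": 0.053,
    "R_mv": 0.0078,
    "R_sys": 1.19,
    "T": 0.9,
    "t_peak": 0.32,
    "Z_ao": 0.035,
}


def typical_reference(kind: ModelKind = "closed") -> dict:
    """Typical parameter values (dict) for the given model variant."""
    return dict(TYPICAL_PARAMETERS if kind == "closed" else TYPICAL_PARAMETERS_OPEN)


def typical_parameters(kind: ModelKind = "closed", **overrides) -> CVParameters:
    """A documented physiological default parameter set for either model."""
    d = typical_reference(kind)
    d.update(overrides)
    return CVParameters(**d)


@dataclass
class CostWeights:
    """Scaling constants of the cost function (units of their residuals)."""

    K_p: float = 100.0  # mmHg, per-sample pressure residual
    K_q: float = 500.0  # mL/s, per-sample flow residual
    K_p_sys: float = 100.0  # mmHg
    K_p_dia: float = 100.0  # mmHg
    K_SV: float = 100.0  # mL
    K_MVP: float = 6.0  # mmHg
    mvp_target: float = 6.0  # mmHg, venous pressure soft constraint
    waveform_weight_ref: float = 40.0  # reference N in the 7.5²N²/40² factor

    def __post_init__(self) -> None:
        for name in ("K_p", "K_q", "K_p_sys", "K_p_dia", "K_SV", "K_MVP", "waveform_weight_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class MeasurementSet:
    """Everything the cost function and conventional estimators consume for
    one participant-day: calibrated pressure/flow waveforms, brachial
    pressures, volumes and anthropometrics."""

    waveform: WaveformRecord
    P_sys_m: float  # mmHg, brachial systolic
    P_dia_m: float  # mmHg, brachial diastolic
    SV_m: float  # mL
    ESV_m: float  # mL
    T: float  # s
    height: float  # cm
    weight: float  # kg
    modality: str = "carotid"  # carotid | finger
    day: str = "1"
    participant_id: str = "P0"

    def __post_init__(self) -> None:
        if not (self.P_sys_m > self.P_dia_m > 0):
            raise ValueError("require P_sys_m > P_dia_m > 0")
        if self.SV_m <= 0 or self.ESV_m <= 0:
            raise ValueError("SV_m and ESV_m must be positive")
        if self.T <= 0 or self.height <= 0 or self.weight <= 0:
            raise ValueError("T, height and weight must be positive")


@dataclass
class ParameterEstimate:
    """One ensemble member: a local optimization outcome."""

    theta: CVParameters
    final_cost: float
    converged: bool
    start_index: int
    seed: int | None = None
    n_evaluations: int = 0


@dataclass
class EnsembleEstimate:
    """Filtered-and-averaged result of the optimization ensemble."""

    members: list[ParameterEstimate]
    kept_mask: np.ndarray
    theta_mean: CVParameters
    spread: dict[str, float]  # per-parameter SD over kept members

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.kept_mask))


class _CostEvaluator:
    """Cost of one measurement; warm-starts each simulation from the previous
    steady state so successive optimizer steps converge in few cycles."""

    def __init__(self, m, weights, model_kind, solver, penalty=PENALTY_COST):
        self.m = m
        self.w = weights or CostWeights()
        self.kind = model_kind
        self.solver = solver or SolverConfig()
        if self.solver.n_samples != m.waveform.N:
            self.solver = SolverConfig(
                dt=self.solver.dt, max_cycles=self.solver.max_cycles, tol=self.solver.tol,
                n_samples=m.waveform.N, p_fill=self.solver.p_fill,
            )
        self.penalty = penalty
        self.n_evaluations = 0
        self._y_last = None

        w = self.w
        self._wvec = np.array(
            [w.K_p, w.K_q, w.K_p_sys, w.K_p_dia, w.K_SV, w.K_MVP,
             w.mvp_target, w.waveform_weight_ref, penalty]
        )

    def __call__(self, theta: CVParameters) -> float:
        from . import _ode

        self.n_evaluations += 1
        m, solver = self.m, self.solver
        closed = self.kind == "closed"
        p = theta.to_array(p_fill=solver.p_fill)
        y0 = self._y_last
        if y0 is None:
            y0 = _initial_state(theta, self.kind, solver.p_fill)
        elif closed:
            total = y0.sum()
            y0 = y0 * (theta.V_tot / total) if total > 0 else _initial_state(theta, self.kind, solver.p_fill)
        j, y_end, converged = _ode._cost_kernel(
            p, y0, closed, solver.dt, solver.max_cycles, solver.tol,
            m.waveform.t, m.waveform.P_ao, m.waveform.Q_lvao,
            m.SV_m, m.P_sys_m, m.P_dia_m, self._wvec,
        )
        self._y_last = y_end if converged else None
        return float(j)


def cost(
    theta: CVParameters,
    m: MeasurementSet,
    w: CostWeights | None = None,
    model_kind: ModelKind | None = None,
    solver: SolverConfig | None = None,
) -> float:
    """Evaluate the personalization cost J(θ) for one measurement set.

    Simulations that do not converge or produce non-physical output map to a
    large penalty value (``PENALTY_COST``) so optimizers can continue.
    """
    kind = model_kind or theta.kind
    return _CostEvaluator(m, w, kind, solver)(theta)


def default_bounds(
    kind: ModelKind = "closed",
    reference: dict | None = None,
    scale: tuple[float, float] = (0.5, 2.0),
    free: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Optimization bounds: (0.5×, 2×) a typical physiological value.

    ``T`` is never free (it is fixed from the measured heart period)."""
    ref = typical_reference(kind)
    if reference:
        ref.update(reference)
    names = [n for n in ref if n != "T"]
    if kind == "open":
        names = [n for n in names if n not in ("C_sv", "V_tot")]
    if free is not None:
        unknown = set(free) - set(names)
        if unknown:
            raise ValueError(f"unknown or non-free parameters: {sorted(unknown)}")
        names = [n for n in names if n in free]
    return {n: (scale[0] * ref[n], scale[1] * ref[n]) for n in names}


def _theta_from_vector(x, names, base: CVParameters) -> CVParameters:
    return base.replace(**{n: float(v) for n, v in zip(names, x)})


def optimize_single(
    m: MeasurementSet,
    x0: CVParameters,
    bounds: dict[str, tuple[float, float]],
    w: CostWeights | None = None,
    model_kind: ModelKind | None = None,
    seed: int | None = None,
    solver: SolverConfig | None = None,
    start_index: int = 0,
    maxfev: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 2,
) -> ParameterEstimate:
    """One bounded derivative-free local minimization of the cost from x0.

    Powell's method on parameters rescaled to the unit cube; the search is
    restarted from its own endpoint (fresh direction set) until the cost
    stops improving, which markedly helps Powell in ≥ 8 dimensions.
    Deterministic for a given starting point.
    """
    kind = model_kind or x0.kind
    names = sorted(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    start = np.array([getattr(x0, n) for n in names], dtype=float)
    if np.any(start < lo) or np.any(start > hi):
        bad = [n for n, s, l, h in zip(names, start, lo, hi) if not (l <= s <= h)]
        raise ValueError(f"x0 outside bounds for parameters: {bad}")

    ev = _CostEvaluator(m, w, kind, solver)
    base = x0.replace(T=m.T)

    def f(u: np.ndarray) -> float:
        x = lo + u * (hi - lo)
        try:
            theta = _theta_from_vector(x, names, base)
        except ValueError:
            return ev.penalty
        return ev(theta)

    u0 = (start - lo) / (hi - lo)
    res = None
    plateaued = False
    success = False
    for _ in range(1 + n_restarts):
        r = _sciopt.minimize(
            f,
            u0,
            method="Powell",
            bounds=[(0.0, 1.0)] * len(names),
            options={"xtol": tol, "ftol": tol, "maxfev": maxfev},
        )
        improved = res is None or r.fun < res.fun * (1.0 - 1e-3)
        if res is None or r.fun < res.fun:
            res = r
            success = bool(r.success)
        if not improved:
            plateaued = True
            break
        u0 = np.clip(r.x, 0, 1)
    x_best = lo + np.clip(res.x, 0, 1) * (hi - lo)
    theta = _theta_from_vector(x_best, names, base)
    # a member counts as converged when it reached a usable (feasible, finite)
    # minimum; ending on the infeasibility penalty plateau means the search
    # never found a simulable parameter region
    del success, plateaued
    return ParameterEstimate(
        theta=theta,
        final_cost=float(res.fun),
        converged=bool(np.isfinite(res.fun) and res.fun < PENALTY_COST),
        start_index=start_index,
        seed=seed,
        n_evaluations=ev.n_evaluations,
    )


def ensemble_estimate(
    m: MeasurementSet,
    n_starts: int = 20,
    bounds: dict[str, tuple[float, float]] | None = None,
    filter_rule: float | Callable[[np.ndarray, np.ndarray], np.ndarray] = 2.0,
    seed: int | None = None,
    w: CostWeights | None = None,
    model_kind: ModelKind = "closed",
    solver: SolverConfig | None = None,
    maxfev: int = 2000,
) -> EnsembleEstimate:
    """Ensemble of local optimizations from seeded uniform starting points.

    ``filter_rule`` is either a factor f (keep converged members with final
    cost ≤ f × the best converged cost) or a callable
    ``(costs, converged) -> keep_mask``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    bounds = bounds or default_bounds(model_kind)
    names = sorted(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    rng = np.random.default_rng(seed)
    starts = lo + rng.random((n_starts, len(names))) * (hi - lo)

    base = typical_parameters(model_kind, T=m.T)
    members = []
    for i in range(n_starts):
        x0 = _theta_from_vector(starts[i], names, base)
        members.append(
            optimize_single(m, x0, bounds, w=w, model_kind=model_kind, seed=seed,
                            solver=solver, start_index=i, maxfev=maxfev)
        )

    costs = np.array([mm.final_cost for mm in members])
    converged = np.array([mm.converged for mm in members])
    if not np.any(converged):
        raise RuntimeError(
            f"no ensemble member converged for participant {m.participant_id} day {m.day}; "
            f"final costs: {costs!r}"
        )
    if callable(filter_rule):
        kept = np.asarray(filter_rule(costs, converged), dtype=bool)
    else:
        best = costs[converged].min()
        kept = converged & (costs <= filter_rule * best + 1e-300)
    if not np.any(kept):
        raise RuntimeError("filter rule rejected every converged member")

    mat = np.array([[getattr(mm.theta, n) for n in names] for mm in members])
    mean_vals = mat[kept].mean(axis=0)
    spread = {n: float(mat[kept, j].std(ddof=0)) for j, n in enumerate(names)}
    theta_mean = _theta_from_vector(mean_vals, names, base)
    return EnsembleEstimate(members=members, kept_mask=kept, theta_mean=theta_mean, spread=spread)


def bsa(height: float, weight: float) -> float:
    """Body surface area (m²) from height (cm) and weight (kg): sqrt(h·w/3600)."""
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height * weight / 3600.0)


def normalize_by_bsa(theta: CVParameters, bsa_value: float) -> CVParameters:
    """Divide the mechanical parameters by BSA (per-m² indexed units)."""
    if theta.bsa_indexed:
        raise ValueError("parameters are already BSA-indexed")
    if bsa_value <= 0:
        raise ValueError("bsa must be positive")
    updates = {
        n: getattr(theta, n) / bsa_value
        for n in MECHANICAL_PARAMS
        if getattr(theta, n) is not None
    }
    return theta.replace(bsa_indexed=True, **updates)


def denormalize_by_bsa(theta: CVParameters, bsa_value: float) -> CVParameters:
    """Inverse of :func:`normalize_by_bsa`."""
    if not theta.bsa_indexed:
        raise ValueError("parameters are not BSA-indexed")
    if bsa_value <= 0:
        raise ValueError("bsa must be positive")
    updates = {
        n: getattr(theta, n) * bsa_value
        for n in MECHANICAL_PARAMS
        if getattr(theta, n) is not None
    }
    return theta.replace(bsa_indexed=False, **updates)


class PersonalizationModel:
    """Fits a circulation model to one participant-day of measurements.

    Parameters
    ----------
    measurement : MeasurementSet
        Calibrated waveforms plus brachial pressures, volumes, anthropometrics.
    model_kind : {"closed", "open"}
        Which circulation model to personalize.
    weights, bounds, solver
        Cost scaling constants, optimization bounds and RK4 settings;
        defaults follow the package configuration.

    Examples
    --------
    >>> model = PersonalizationModel(measurement, model_kind="open")
    >>> res = model.fit(n_starts=20, seed=1)
    >>> res.params.R_sys, res.spread["R_sys"]
    """

    def __init__(
        self,
        measurement: MeasurementSet,
        model_kind: ModelKind = "closed",
        weights: CostWeights | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
        solver: SolverConfig | None = None,
    ):
        self.measurement = measurement
        self.model_kind = model_kind
        self.weights = weights or CostWeights()
        self.bounds = bounds or default_bounds(model_kind)
        self.solver = solver

    def cost(self, theta: CVParameters) -> float:
        return cost(theta, self.measurement, self.weights, self.model_kind, self.solver)

    def fit(
        self,
        n_starts: int = 20,
        seed: int | None = None,
        filter_rule: float | Callable = 2.0,
        maxfev: int = 2000,
    ) -> "PersonalizationResults":
        ens = ensemble_estimate(
            self.measurement,
            n_starts=n_starts,
            bounds=self.bounds,
            filter_rule=filter_rule,
            seed=seed,
            w=self.weights,
            model_kind=self.model_kind,
            solver=self.solver,
            maxfev=maxfev,
        )
        return PersonalizationResults(self, ens, seed=seed)


class PersonalizationResults:
    """Ensemble estimation results for one participant-day."""

    def __init__(self, model: PersonalizationModel, ensemble: EnsembleEstimate, seed=None):
        self.model = model
        self.ensemble = ensemble
        self.seed = seed

    @property
    def params(self) -> CVParameters:
        """Averaged parameter estimate over kept ensemble members."""
        return self.ensemble.theta_mean

    @property
    def spread(self) -> dict[str, float]:
        """Per-parameter SD over kept ensemble members (method variability)."""
        return self.ensemble.spread

    @property
    def final_costs(self) -> np.ndarray:
        return np.array([m.final_cost for m in self.ensemble.members])

    @property
    def bsa(self) -> float:
        m = self.model.measurement
        return bsa(m.height, m.weight)

    @property
    def params_indexed(self) -> CVParameters:
        """BSA-indexed averaged estimate."""
        return normalize_by_bsa(self.params, self.bsa)

    def simulate(self, **kw) -> SimulationResult:
        """Simulate the fitted (averaged) parameters."""
        return simulate(self.params, self.model.model_kind,
                        self.model.solver or SolverConfig(n_samples=self.model.measurement.waveform.N), **kw)

    def summary(self) -> str:
        m = self.model.measurement
        lines = [
            f"Personalization results — participant {m.participant_id}, day {m.day}, "
            f"{m.modality} waveform, {self.model.model_kind}-loop model",
            f"  ensemble: {len(self.ensemble.members)} starts, {self.ensemble.n_kept} kept, "
            f"best cost {self.final_costs.min():.4g}",
            f"  {'parameter':<8} {'estimate':>12} {'spread (SD)':>12}",
        ]
        for n in sorted(self.spread):
            lines.append(f"  {n:<8} {getattr(self.params, n):>12.5g} {self.spread[n]:>12.3g}")
        return "\n".join(lines)
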