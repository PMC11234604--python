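"""Synthetic longitudinal cohort generator.

Stands in for the (confidential) trial data: draws a cohort whose covariates
match the published population statistics of a middle-aged, pre-hypertensive
study group, gives every participant ground-truth mechanical parameters that
decompose as

    θ_ij = μ + α_i + effect_j + ε_ij

(population mean, personal deviation, smooth intervention effect across the
three measurement days, day-to-day random error), forward-simulates each
participant-day through a circulation model and corrupts the model output
with measurement noise at documented magnitudes (ABPM pressure ≈ 0.7%,
stroke volume ≈ 20%, ...).  Everything is reproducible from a single seed.

What this generator does NOT emulate: real finger-to-aorta transfer
dynamics, beat-to-beat variability within a recording, device-specific
artifacts, or any physiological coupling between fitness covariates and the
mechanical parameters (covariates are drawn independently unless configured
otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cv_models import CVParameters, ModelKind, SolverConfig, simulate
from .personalization import MeasurementSet, TYPICAL_PARAMETERS, typical_reference

#: fractional position of each measurement day along the day-1 → day-3
#: intervention effect ramp; "1post"/"3post" are the morning-after-CPET days
DAY_EFFECT_FRACTION = {"1": 0.0, "2": 0.5, "3": 1.0, "1post": 0.0, "3post": 1.0}
POST_CPET_DAYS = ("1post", "3post")
CORE_DAYS = ("1", "2", "3")


@dataclass
class MeasurementNoise:
    """Measurement-error magnitudes (percent of the true value unless noted).

    The percentage defaults mirror documented uncertainty levels for this
    kind of trial instrumentation: ABPM-averaged brachial pressures ≈ 0.7 %,
    stroke volume from 4D echo ≈ 20 %, VO2max ≈ 2.9 %, age ≈ 1.8 %,
    height ≈ 0.6 %, weight ≈ 0.1 %.
    """

    sbp_pct: float = 0.7
    dbp_pct: float = 0.7
    sv_pct: float = 20.0
    esv_pct: float = 10.0
    vo2max_pct: float = 2.9
    age_pct: float = 1.8
    height_pct: float = 0.6
    weight_pct: float = 0.1
    waveform_pressure_sd: float = 1.0  # mmHg, per-sample
    waveform_flow_sd: float = 5.0  # mL/s, per-sample

    @classmethod
    def none(cls) -> "MeasurementNoise":
        return cls(0, 0, 0, 0, 0, 0, 0, 0, 0.0, 0.0)


@dataclass
class ModalityModel:
    """Waveform-shape distortion by measurement site.

    The carotid trace is treated as a mildly smoothed aortic wave; the
    finger trace is low-pass filtered more strongly and its systolic peak
    amplified, a deliberately simple caricature of peripheral pulse
    amplification.  Window lengths are odd sample counts of a periodic
    moving average; ``finger_amp`` scales the above-mean part of the wave.
    """

    carotid_smooth: int = 3
    finger_smooth: int = 7
    finger_amp: float = 0.10

    @classmethod
    def none(cls) -> "ModalityModel":
        return cls(1, 1, 0.0)


@dataclass
class TruthSpec:
    """Ground-truth generative settings for the synthetic cohort.

    ``sigma_alpha`` / ``sigma_eps`` are fractional SDs (relative to the
    population mean) of the personal deviation and the day-to-day error for
    each varying parameter; ``effects`` are fractional day-1 → day-3 changes
    ramped linearly across the measurement days; ``cpet_transient`` is an
    extra fractional offset applied only on morning-after-CPET days.
    """

    param_means: dict = field(default_factory=lambda: dict(TYPICAL_PARAMETERS))
    sigma_alpha: dict = field(
        default_factory=lambda: {"R_sys": 0.10, "C_ao": 0.10, "E_max": 0.10}
    )
    sigma_eps: dict = field(
        default_factory=lambda: {"R_sys": 0.04, "C_ao": 0.04, "E_max": 0.04}
    )
    effects: dict = field(
        default_factory=lambda: {"R_sys": -0.05, "C_ao": 0.05, "E_max": 0.05}
    )
    cpet_transient: dict = field(default_factory=lambda: {"R_sys": -0.05})
    heart_period_sd: float = 0.07  # s, across participants (fixed within)
    # covariate population means/SDs (height cm, weight kg, age y, VO2max mL/kg/min)
    height_mean: float = 174.3
    height_sd: float = 8.9
    weight_mean: float = 85.9
    weight_sd: float = 14.2
    age_mean: float = 55.9
    age_sd: float = 3.9
    vo2max_mean: float = 36.4
    vo2max_sd: float = 6.8
    p_male: float = 13.0 / 25.0
    vo2max_effect: float = 0.08  # fractional day-1 → day-3 improvement
    weight_effect: float = -0.01  # fractional day-1 → day-3 change
    truncation: tuple[float, float] = (0.4, 2.5)  # clip multipliers on parameter draws
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.sigma_alpha, self.sigma_eps):
            if any(v < 0 for v in d.values()):
                raise ValueError("variance-component SDs must be non-negative")
        for name, v in self.effects.items():
            if not np.isfinite(v):
                raise ValueError(f"effect size for {name} must be finite")

    def varying_params(self) -> list[str]:
        return sorted(
            set(self.sigma_alpha) | set(self.sigma_eps)
            | set(self.effects) | set(self.cpet_transient)
        )

    @classmethod
    def for_kind(cls, kind: ModelKind, **kw) -> "TruthSpec":
        """TruthSpec whose population means are the typical values of the
        given model variant (the open loop has no C_sv / V_tot)."""
        return cls(param_means=typical_reference(kind), **kw)


@dataclass
class SyntheticParticipant:
    """One synthetic participant: covariates, ground truth, measurements."""

    participant_id: str
    alpha: dict  # per-parameter fractional personal deviation
    covariates: dict  # day -> {height, weight, age, sex, BMI, VO2max}
    heart_period: float
    truth: dict = field(default_factory=dict)  # day -> CVParameters
    measurements: dict = field(default_factory=dict)  # (day, modality) -> MeasurementSet
    seed_seq: np.random.SeedSequence | None = field(default=None, repr=False)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Normal draw resampled into [lo, hi] (keeps invariants without bias spikes)."""
    x = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
    return float(np.clip(x, lo, hi)) if size is None else np.clip(x, lo, hi)


def sample_cohort(n: int, spec: TruthSpec) -> list[SyntheticParticipant]:
    """Draw n participants: covariates and per-participant parameter deviations.

    Deterministic for a given ``spec.seed``; measurement days are filled in by
    :func:`longitudinal_truth` and :func:`synthesize_measurement`.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    root = np.random.SeedSequence(spec.seed)
    participants = []
    for i, ss in enumerate(root.spawn(n)):
        rng = np.random.default_rng(ss)
        height = _truncated_normal(rng, spec.height_mean, spec.height_sd, 140, 210)
        weight = _truncated_normal(rng, spec.weight_mean, spec.weight_sd, 45, 160)
        age = _truncated_normal(rng, spec.age_mean, spec.age_sd, 40, 75)
        vo2 = _truncated_normal(rng, spec.vo2max_mean, spec.vo2max_sd, 15, 70)
        sex = int(rng.random() < spec.p_male)  # 1 = male
        period = _truncated_normal(
            rng, spec.param_means["T"], spec.heart_period_sd, 0.6, 1.4
        )
        alpha = {
            name: float(rng.normal(0.0, spec.sigma_alpha.get(name, 0.0)))
            for name in spec.varying_params()
        }
        covariates = {}
        for day in CORE_DAYS + POST_CPET_DAYS:
            frac = DAY_EFFECT_FRACTION[day]
            w = weight * (1.0 + frac * spec.weight_effect)
            v = vo2 * (1.0 + frac * spec.vo2max_effect)
            covariates[day] = {
                "height": height,
                "weight": w,
                "age": age,
                "sex": sex,
                "BMI": w / (height / 100.0) ** 2,
                "VO2max": v,
            }
        participants.append(
            SyntheticParticipant(
                participant_id=f"S{i:03d}",
                alpha=alpha,
                covariates=covariates,
                heart_period=period,
                seed_seq=ss,
            )
        )
    return participants


def longitudinal_truth(
    participant: SyntheticParticipant,
    spec: TruthSpec,
    days: tuple[str, ...] = CORE_DAYS,
) -> dict[str, CVParameters]:
    """Ground-truth parameters per measurement day:
    θ_ij = μ·(1 + α_i + effect_j + ε_ij), with fresh day-to-day error ε and
    the intervention effect ramped linearly from day 1 to day 3."""
    rng = np.random.default_rng(participant.seed_seq.spawn(1)[0])
    lo, hi = spec.truncation
    truth = {}
    for day in days:
        frac = DAY_EFFECT_FRACTION[day]
        vals = dict(spec.param_means)
        vals["T"] = participant.heart_period
        for name in spec.varying_params():
            eps = float(rng.normal(0.0, spec.sigma_eps.get(name, 0.0)))
            mult = 1.0 + participant.alpha[name] + frac * spec.effects.get(name, 0.0) + eps
            if day in POST_CPET_DAYS:
                mult += spec.cpet_transient.get(name, 0.0)
            vals[name] = spec.param_means[name] * float(np.clip(mult, lo, hi))
        truth[day] = CVParameters(**vals)
    participant.truth.update(truth)
    return truth


def _periodic_smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    k = np.ones(window) / window
    ext = np.concatenate([x[-(window // 2):], x, x[: window // 2]])
    return np.convolve(ext, k, mode="valid")


def _distort(p: np.ndarray, modality: str, mod: ModalityModel) -> np.ndarray:
    if modality == "carotid":
        return _periodic_smooth(p, mod.carotid_smooth)
    if modality == "finger":
        q = _periodic_smooth(p, mod.finger_smooth)
        mean = q.mean()
        top = q.max() - mean
        if top > 0 and mod.finger_amp > 0:
            q = q + mod.finger_amp * np.maximum(0.0, q - mean)
        return q
    raise ValueError(f"unknown modality {modality!r}")


def synthesize_measurement(
    truth: CVParameters,
    covariates: dict,
    noise: MeasurementNoise,
    modality: str = "carotid",
    seed: int | np.random.SeedSequence | None = None,
    model_kind: ModelKind | None = None,
    solver: SolverConfig | None = None,
    modality_model: ModalityModel | None = None,
    unstressed_volume: float = 15.0,
    day: str = "1",
    participant_id: str = "S000",
) -> MeasurementSet:
    """Forward-simulate the true parameters and corrupt the output into a
    realistic measurement record.

    Pressure and flow waveforms get per-sample noise; the pressure trace is
    distorted by measurement site and then recalibrated to the noisy brachial
    pressures; SV and ESV get multiplicative noise (truncated so the record
    stays physiologically valid); the measured ESV is the minimum simulated
    LV volume plus an unstressed-volume offset.
    """
    solver = solver or SolverConfig()
    sim = simulate(truth, model_kind, solver)
    if not sim.converged:
        raise RuntimeError(
            f"simulation did not converge for participant {participant_id} day {day}"
        )
    rng = np.random.default_rng(seed)
    s = sim.summary

    # noisy summary quantities, resampled until invariants hold
    for _ in range(100):
        sbp = s.P_sys * (1.0 + 0.01 * noise.sbp_pct * rng.standard_normal())
        dbp = s.P_dia * (1.0 + 0.01 * noise.dbp_pct * rng.standard_normal())
        if sbp > dbp > 0:
            break
    sv = s.SV * (1.0 + 0.01 * noise.sv_pct * rng.standard_normal())
    for _ in range(100):
        if sv > 0.1 * s.SV:
            break
        sv = s.SV * (1.0 + 0.01 * noise.sv_pct * rng.standard_normal())
    sv = float(np.clip(sv, 0.05 * s.SV, 3.0 * s.SV))
    esv_true = s.ESV_model + unstressed_volume
    esv = esv_true * (1.0 + 0.01 * noise.esv_pct * rng.standard_normal())
    esv = float(np.clip(esv, 0.2 * esv_true, 3.0 * esv_true))

    mod = modality_model or ModalityModel()
    p_wave = _distort(sim.waveform.P_ao, modality, mod)
    p_wave = p_wave + noise.waveform_pressure_sd * rng.standard_normal(p_wave.shape)
    q_wave = sim.waveform.Q_lvao + noise.waveform_flow_sd * rng.standard_normal(
        sim.waveform.Q_lvao.shape
    )

    # calibrate the (distorted, noisy) pressure trace to the noisy brachial values
    rng_p = np.ptp(p_wave)
    if rng_p > 0:
        p_wave = dbp + (p_wave - p_wave.min()) * (sbp - dbp) / rng_p
    else:  # degenerate flat trace: use the brachial values directly
        p_wave = np.full_like(p_wave, 0.5 * (sbp + dbp))

    waveform = replace(sim.waveform, P_ao=p_wave, Q_lvao=q_wave)
    return MeasurementSet(
        waveform=waveform,
        P_sys_m=float(sbp),
        P_dia_m=float(dbp),
        SV_m=float(sv),
        ESV_m=float(esv),
        T=truth.T,
        height=covariates["height"],
        weight=covariates["weight"],
        modality=modality,
        day=day,
        participant_id=participant_id,
    )


def generate_cohort(
    n: int,
    spec: TruthSpec | None = None,
    days: tuple[str, ...] = CORE_DAYS,
    modalities: tuple[str, ...] = ("carotid",),
    noise: MeasurementNoise | None = None,
    model_kind: ModelKind = "closed",
    solver: SolverConfig | None = None,
    modality_model: ModalityModel | None = None,
    n_cpet: int = 0,
) -> list[SyntheticParticipant]:
    """Full synthetic cohort: covariates, per-day truth and measurement sets.

    The first ``n_cpet`` participants additionally get morning-after-CPET
    measurement days ("1post", "3post")."""
    spec = spec or TruthSpec()
    noise = noise if noise is not None else MeasurementNoise()
    cohort = sample_cohort(n, spec)
    for k, part in enumerate(cohort):
        part_days = tuple(days) + (POST_CPET_DAYS if k < n_cpet else ())
        truth = longitudinal_truth(part, spec, days=part_days)
        day_seeds = part.seed_seq.spawn(len(part_days) * len(modalities))
        i = 0
        for day in part_days:
            for modality in modalities:
                part.measurements[(day, modality)] = synthesize_measurement(
                    truth[day],
                    part.covariates[day],
                    noise,
                    modality=modality,
                    seed=day_seeds[i],
                    model_kind=model_kind,
                    solver=solver,
                    modality_model=modality_model,
                    day=day,
                    participant_id=part.participant_id,
                )
                i += 1
    return cohort


def truth_table(cohort: list[SyntheticParticipant], params=("R_sys", "C_ao", "E_max")) -> pd.DataFrame:
    """Long-format ground-truth table (participant, day, parameter, value)."""
    rows = []
    for part in cohort:
        for day, theta in part.truth.items():
            for p in params:
                rows.append(
                    {
                        "participant": part.participant_id,
                        "day": day,
                        "parameter": p,
                        "value": getattr(theta, p),
                    }
                )
    return pd.DataFrame(rows)


def covariate_table(cohort: list[SyntheticParticipant]) -> pd.DataFrame:
    """Long-format covariate table, one row per participant-day."""
    rows = []
    for part in cohort:
        for day, cov in part.covariates.items():
            rows.append({"participant": part.participant_id, "day": day, **cov})
    return pd.DataFrame(rows)
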