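"""End-to-end pipeline: synthetic cohort → fits → change and regression
analyses → report bundle, plus the file schemas everything is serialized in.

All randomness derives from one top-level seed: the cohort generator fans it
out through a ``numpy`` SeedSequence per participant/day/measurement, and the
per-fit optimization seeds are drawn from a generator seeded with
``seed + 1`` in a fixed iteration order, so a pipeline run is fully
deterministic and byte-identical between repeats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .change_analysis import (
    compute_changes,
    correlation_table,
    cpet_change_report,
    summarize_changes,
)
from .conventional_estimates import conventional_estimates
from .cv_models import SolverConfig, WaveformRecord
from .personalization import (
    CostWeights,
    MeasurementSet,
    PersonalizationModel,
    bsa,
    default_bounds,
    normalize_by_bsa,
)
from .regression_analysis import (
    OLSChangeModel,
    MixedEffectsModel,
    RegressionSpec,
    RTMChangeModel,
    RTMFinalValueModel,
)
from .synthetic_data import (
    MeasurementNoise,
    ModalityModel,
    TruthSpec,
    covariate_table,
    generate_cohort,
    truth_table,
)

logger = logging.getLogger("cardiofit")

WAVEFORM_HEADER = ["time_s", "p_ao_mmHg", "q_lvao_mL_s"]
ESTIMATE_COLUMNS = ["participant", "day", "method", "modality", "parameter", "value"]
ANALYSIS_PARAMS = ("R_sys", "C_ao", "E_max")


class PipelineError(RuntimeError):
    """Stage failure with participant/day context."""

    def __init__(self, stage: str, message: str, participant: str | None = None):
        self.stage = stage
        self.participant = participant
        ctx = f" (participant {participant})" if participant else ""
        super().__init__(f"[{stage}]{ctx} {message}")


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    seed: int = 0
    n_participants: int = 14
    n_cpet: int = 0
    days: tuple[str, ...] = ("1", "2", "3")
    modalities: tuple[str, ...] = ("carotid",)
    model_kinds: tuple[str, ...] = ("closed", "open")
    generator_kind: str = "closed"  # model that generates synthetic measurements
    n_starts: int = 20
    maxfev: int = 2000
    filter_factor: float = 2.0
    noise: MeasurementNoise = field(default_factory=MeasurementNoise)
    modality_model: ModalityModel = field(default_factory=ModalityModel)
    truth: TruthSpec = field(default_factory=TruthSpec)
    solver: SolverConfig = field(default_factory=SolverConfig)
    weights: CostWeights = field(default_factory=CostWeights)
    bound_scale: tuple[float, float] = (0.5, 2.0)
    # analysis toggles
    run_changes: bool = True
    run_correlations: bool = True
    run_cpet: bool = True
    run_rtm: bool = True
    run_regressions: bool = True
    write_waveforms: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.truth = dataclasses.replace(self.truth, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        for k in ("days", "modalities", "model_kinds"):
            d[k] = [str(x) for x in d[k]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for k, sub in (("noise", MeasurementNoise), ("modality_model", ModalityModel),
                       ("truth", TruthSpec), ("solver", SolverConfig), ("weights", CostWeights)):
            if k in d and isinstance(d[k], dict):
                sd = dict(d[k])
                for kk, vv in sd.items():
                    if isinstance(vv, list):
                        sd[kk] = tuple(vv)
                d[k] = sub(**sd)
        for k in ("days", "modalities", "model_kinds", "bound_scale"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific settings (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# file schemas

def write_waveform(w: WaveformRecord, path: str | Path) -> None:
    """Waveform CSV: columns time_s, p_ao_mmHg, q_lvao_mL_s."""
    df = pd.DataFrame({"time_s": w.t, "p_ao_mmHg": w.P_ao, "q_lvao_mL_s": w.Q_lvao})
    df.to_csv(path, index=False)


def read_waveform(path: str | Path) -> WaveformRecord:
    df = pd.read_csv(path, comment="#")
    missing = set(WAVEFORM_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"waveform file {path} lacks columns: {sorted(missing)}")
    t = df["time_s"].to_numpy()
    return WaveformRecord(t=t, P_ao=df["p_ao_mmHg"].to_numpy(),
                          Q_lvao=df["q_lvao_mL_s"].to_numpy(), T=float(t[-1] - t[0]))


def write_table(df: pd.DataFrame, path: str | Path, required: list[str] | None = None,
                config_hash: str | None = None) -> None:
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"table lacks required columns: {sorted(missing)}")
    path = Path(path)
    with open(path, "w") as f:
        if config_hash:
            f.write(f"# config_hash={config_hash}\n")
        df.to_csv(f, index=False)


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"{path} lacks required columns: {sorted(missing)}")
    return df


def measurements_to_frame(cohort) -> pd.DataFrame:
    """One row per participant-day-modality with summary measurement columns."""
    rows = []
    for part in cohort:
        for (day, modality), m in part.measurements.items():
            cov = part.covariates[day]
            rows.append(
                {
                    "participant": part.participant_id,
                    "day": day,
                    "modality": modality,
                    "sbp_mmHg": m.P_sys_m,
                    "dbp_mmHg": m.P_dia_m,
                    "sv_mL": m.SV_m,
                    "esv_mL": m.ESV_m,
                    "heart_period_s": m.T,
                    "height_cm": m.height,
                    "weight_kg": m.weight,
                    "age_y": cov["age"],
                    "sex": cov["sex"],
                    "bmi_kg_m2": cov["BMI"],
                    "vo2max_mL_kg_min": cov["VO2max"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline stages

def _theta_rows(part_id, day, modality, method, theta_indexed) -> list[dict]:
    return [
        {
            "participant": part_id,
            "day": day,
            "method": method,
            "modality": modality,
            "parameter": p,
            "value": getattr(theta_indexed, p),
        }
        for p in ANALYSIS_PARAMS
    ]


def fit_cohort(cohort, cfg: PipelineConfig, model_kind: str) -> pd.DataFrame:
    """Personalize one model variant to every measurement; returns the
    long-format estimates table (BSA-indexed values) for model and
    conventional methods."""
    fit_seed_rng = np.random.default_rng(cfg.seed + 1)
    bounds = default_bounds(model_kind, scale=cfg.bound_scale)
    rows: list[dict] = []
    for part in cohort:
        for (day, modality), m in sorted(part.measurements.items()):
            b = bsa(m.height, m.weight)
            fit_seed = int(fit_seed_rng.integers(0, 2**31 - 1))
            try:
                model = PersonalizationModel(
                    m, model_kind=model_kind, weights=cfg.weights, bounds=bounds,
                    solver=cfg.solver,
                )
                res = model.fit(n_starts=cfg.n_starts, seed=fit_seed,
                                filter_rule=cfg.filter_factor, maxfev=cfg.maxfev)
            except (RuntimeError, ValueError) as exc:
                raise PipelineError("fit", f"day {day} {modality} ({model_kind}): {exc}",
                                    part.participant_id) from exc
            rows += _theta_rows(part.participant_id, day, modality, "model",
                                normalize_by_bsa(res.params, b))
            conv = conventional_estimates(m)
            rows += [
                {"participant": part.participant_id, "day": day, "method": "conventional",
                 "modality": modality, "parameter": p, "value": v}
                for p, v in (("R_sys", conv.R_sys_conv_indexed),
                             ("C_ao", conv.C_ao_conv_indexed),
                             ("E_max", conv.E_max_conv_indexed))
            ]
            logger.info("fitted %s day %s %s (%s): best cost %.3g",
                        part.participant_id, day, modality, model_kind,
                        res.final_costs.min())
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def conventional_only_estimates(cohort) -> pd.DataFrame:
    """Long-format conventional (BSA-indexed) estimates for a cohort."""
    rows = []
    for part in cohort:
        for (day, modality), m in sorted(part.measurements.items()):
            conv = conventional_estimates(m)
            rows += [
                {"participant": part.participant_id, "day": day, "method": "conventional",
                 "modality": modality, "parameter": p, "value": v}
                for p, v in (("R_sys", conv.R_sys_conv_indexed),
                             ("C_ao", conv.C_ao_conv_indexed),
                             ("E_max", conv.E_max_conv_indexed))
            ]
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def recovery_scorecard(estimates: pd.DataFrame, cohort) -> dict:
    """Estimated vs ground-truth comparison: mean and max absolute relative
    error (%) per parameter for the model-based estimates (non-indexed truth
    is re-indexed with each participant-day's BSA)."""
    truth = truth_table(cohort)
    bsa_map = {
        (p.participant_id, day): bsa(p.covariates[day]["height"], p.covariates[day]["weight"])
        for p in cohort
        for day in p.truth
    }
    truth["value"] = [
        v / bsa_map[(pid, d)] for pid, d, v in zip(truth["participant"], truth["day"], truth["value"])
    ]
    model = estimates[estimates["method"] == "model"]
    merged = model.merge(truth, on=["participant", "day", "parameter"], suffixes=("_est", "_true"))
    out = {}
    for p, grp in merged.groupby("parameter"):
        rel = np.abs(grp["value_est"] / grp["value_true"] - 1.0) * 100.0
        out[p] = {
            "mean_abs_rel_err_pct": float(rel.mean()),
            "max_abs_rel_err_pct": float(rel.max()),
            "n": int(len(rel)),
        }
    return out


def _regression_inputs(estimates: pd.DataFrame, cohort, parameter: str, modality: str):
    """Assemble the per-day (LMM) and per-participant change (OLS) tables."""
    model = estimates[
        (estimates["method"] == "model")
        & (estimates["parameter"] == parameter)
        & (estimates["modality"] == modality)
    ]
    cov = covariate_table(cohort)
    sv = pd.DataFrame(
        [
            {"participant": p.participant_id, "day": day, "SV": m.SV_m}
            for p in cohort
            for (day, mod), m in p.measurements.items()
            if mod == modality
        ]
    )
    perday = (
        model.rename(columns={"value": "value"})[["participant", "day", "value"]]
        .merge(cov, on=["participant", "day"])
        .merge(sv, on=["participant", "day"])
        .rename(columns={"VO2max": "VO2max"})
    )
    wide = perday.pivot_table(index="participant", columns="day",
                              values=["value", "BMI", "SV", "VO2max"], aggfunc="first")
    base = perday[perday["day"] == "1"].set_index("participant")
    change = pd.DataFrame(
        {
            "delta": wide["value"]["3"] - wide["value"]["1"],
            "age": base["age"],
            "sex": base["sex"],
            "dBMI": wide["BMI"]["3"] - wide["BMI"]["1"],
            "dSV": wide["SV"]["3"] - wide["SV"]["1"],
            "dVO2max": wide["VO2max"]["3"] - wide["VO2max"]["1"],
        }
    ).dropna()
    return perday, change


def _result_dict(res) -> dict:
    d = {
        "params": {k: float(v) for k, v in res.params.items()},
        "bse": {k: float(v) for k, v in res.bse.items()},
        "pvalues": {k: float(v) for k, v in res.pvalues.items()},
        "significant": {k: bool(v) for k, v in res.significant.items()},
        "n_obs": res.n_obs,
        "converged": res.converged,
        "kind": res.kind,
    }
    for k in ("adj_r2", "fstat", "f_pvalue", "resid_var", "group_var", "n_groups", "group_size"):
        v = getattr(res, k)
        d[k] = None if v is None else float(v)
    return d


def run_pipeline(cfg: PipelineConfig):
    """Run every enabled stage and return (and optionally write) the bundle.

    Bundle keys: cohort measurements and truth tables, one estimates table
    per model kind, change tables/summaries/correlations, CPET report, RTM
    and covariate regression results, and a truth-recovery scorecard.
    """
    logger.info("generating synthetic cohort (n=%d, seed=%d)", cfg.n_participants, cfg.seed)
    try:
        cohort = generate_cohort(
            cfg.n_participants,
            spec=cfg.truth,
            days=cfg.days,
            modalities=cfg.modalities,
            noise=cfg.noise,
            model_kind=cfg.generator_kind,
            solver=cfg.solver,
            modality_model=cfg.modality_model,
            n_cpet=cfg.n_cpet,
        )
    except (RuntimeError, ValueError) as exc:
        raise PipelineError("synth-cohort", str(exc)) from exc

    bundle: dict = {
        "config_hash": cfg.config_hash(),
        "measurements": measurements_to_frame(cohort),
        "truth": truth_table(cohort),
        "estimates": {},
        "changes": {},
        "change_summary": {},
        "correlations": {},
        "cpet": {},
        "rtm": {},
        "regressions": {},
        "recovery": {},
    }

    for kind in cfg.model_kinds:
        est = fit_cohort(cohort, cfg, kind)
        bundle["estimates"][kind] = est
        bundle["recovery"][kind] = recovery_scorecard(est, cohort)

        if cfg.run_changes:
            ct = compute_changes(est)
            bundle["changes"][kind] = ct
            bundle["change_summary"][kind] = summarize_changes(ct)
            if cfg.run_correlations:
                bundle["correlations"][kind] = correlation_table(ct)
            if cfg.run_cpet and cfg.n_cpet > 0:
                bundle["cpet"][kind] = cpet_change_report(ct)

        if cfg.run_rtm:
            rtm = {}
            for param in ANALYSIS_PARAMS:
                for modality in cfg.modalities:
                    sel = est[(est["method"] == "model") & (est["parameter"] == param)
                              & (est["modality"] == modality)][["participant", "day", "value"]]
                    try:
                        rtm[f"{param}/{modality}"] = {
                            "final_value": _result_dict(RTMFinalValueModel(sel).fit()),
                            "change": _result_dict(RTMChangeModel(sel).fit()),
                        }
                    except ValueError as exc:
                        rtm[f"{param}/{modality}"] = {"error": str(exc)}
            bundle["rtm"][kind] = rtm

        if cfg.run_regressions:
            regs = {}
            for param in ANALYSIS_PARAMS:
                for modality in cfg.modalities:
                    perday, change = _regression_inputs(est, cohort, param, modality)
                    for config in "ABCD":
                        key = f"{param}/{modality}/{config}"
                        try:
                            lmm = MixedEffectsModel(
                                perday, RegressionSpec(config=config, dependent=param,
                                                       estimator="lmm")
                            ).fit()
                            ols = OLSChangeModel(
                                change, RegressionSpec(config=config, dependent=param,
                                                       estimator="ols")
                            ).fit()
                            regs[key] = {"lmm": _result_dict(lmm), "ols": _result_dict(ols)}
                        except ValueError as exc:
                            regs[key] = {"error": str(exc)}
            bundle["regressions"][kind] = regs

    if cfg.out_dir:
        _write_bundle(bundle, cohort, cfg)
    return bundle


def _write_bundle(bundle, cohort, cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = bundle["config_hash"]
    save_config(cfg, out / "config.yaml")
    write_table(bundle["measurements"], out / "measurements.csv", config_hash=h)
    write_table(bundle["truth"], out / "truth.csv", config_hash=h)
    for kind in cfg.model_kinds:
        write_table(bundle["estimates"][kind], out / f"estimates_{kind}.csv",
                    required=ESTIMATE_COLUMNS, config_hash=h)
        for name in ("changes", "change_summary", "correlations", "cpet"):
            if kind in bundle[name] and isinstance(bundle[name][kind], pd.DataFrame):
                write_table(bundle[name][kind], out / f"{name}_{kind}.csv", config_hash=h)
    for name in ("rtm", "regressions", "recovery"):
        payload = {"config_hash": h, **{k: v for k, v in bundle[name].items()}}
        (out / f"{name}.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    if cfg.write_waveforms:
        wdir = out / "waveforms"
        wdir.mkdir(exist_ok=True)
        for part in cohort:
            for (day, modality), m in part.measurements.items():
                write_waveform(m.waveform, wdir / f"{part.participant_id}_{day}_{modality}.csv")
    manifest = {"config_hash": h, "files": sorted(p.name for p in out.iterdir())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
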