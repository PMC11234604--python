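"""Reusable validation experiments: parameter recovery, change-correlation
and regression-to-the-mean studies on synthetic cohorts.

These are the package's own evidence that the estimation pipeline works:
each experiment generates data with a known ground truth, runs the relevant
stage, and returns the measured discrepancies.  They are shared between the
test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .change_analysis import CorrelationResult, compute_changes, correlate_changes
from .cv_models import ModelKind
from .personalization import PersonalizationModel
from .regression_analysis import (
    RegressionResult,
    RTMChangeModel,
    RTMFinalValueModel,
    rtm_null_slopes,
)
from .synthetic_data import (
    MeasurementNoise,
    ModalityModel,
    TruthSpec,
    longitudinal_truth,
    sample_cohort,
    synthesize_measurement,
)


def recovery_experiment(
    model_kind: ModelKind,
    n_participants: int = 10,
    n_starts: int = 20,
    seed: int = 1,
    noise: MeasurementNoise | None = None,
    params: tuple[str, ...] = ("R_sys", "C_ao", "E_max"),
) -> pd.DataFrame:
    """Ensemble-estimate each synthetic participant's day-1 parameters from a
    noise-free (by default) measurement generated by the same model variant,
    and report the relative recovery errors.

    Returns one row per participant with the percent error per parameter.
    """
    spec = TruthSpec.for_kind(model_kind, seed=seed)
    cohort = sample_cohort(n_participants, spec)
    noise = noise if noise is not None else MeasurementNoise.none()
    rows = []
    for i, part in enumerate(cohort):
        truth = longitudinal_truth(part, spec, days=("1",))["1"]
        m = synthesize_measurement(
            truth,
            part.covariates["1"],
            noise,
            modality="carotid",
            seed=part.seed_seq.spawn(1)[0],
            model_kind=model_kind,
            modality_model=ModalityModel.none(),
            participant_id=part.participant_id,
        )
        res = PersonalizationModel(m, model_kind=model_kind).fit(
            n_starts=n_starts, seed=seed + i
        )
        row = {"participant": part.participant_id, "n_kept": res.ensemble.n_kept}
        for p in params:
            row[f"err_{p}_pct"] = 100.0 * (getattr(res.params, p) / getattr(truth, p) - 1.0)
        rows.append(row)
    return pd.DataFrame(rows)


def change_correlation_experiment(
    n_participants: int = 30,
    seed: int = 1,
    sigma_eps: float = 0.08,
    method_noise: float = 0.02,
    parameter: str = "R_sys",
) -> CorrelationResult:
    """Correlation between model-based and conventional parameter changes when
    both estimates track a shared day-to-day truth with small independent
    method noise.

    The truth varies across days (fractional day-to-day SD ``sigma_eps``, no
    intervention effect); each method observes the truth with independent
    multiplicative noise of fractional SD ``method_noise`` — a deliberately
    small value reflecting that single-day estimation variability is well
    below true day-to-day variation.
    """
    spec = TruthSpec(
        sigma_eps={parameter: sigma_eps},
        sigma_alpha={parameter: 0.10},
        effects={},
        seed=seed,
    )
    cohort = sample_cohort(n_participants, spec)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for part in cohort:
        truth = longitudinal_truth(part, spec)
        for day, theta in truth.items():
            v = getattr(theta, parameter)
            for method in ("model", "conventional"):
                rows.append(
                    {
                        "participant": part.participant_id,
                        "day": day,
                        "method": method,
                        "modality": "carotid",
                        "parameter": parameter,
                        "value": v * (1.0 + method_noise * rng.standard_normal()),
                    }
                )
    ct = compute_changes(pd.DataFrame(rows))
    wide = ct.pivot_table(index=["participant", "day_pair"], columns="method", values="delta")
    wide = wide.dropna()
    return correlate_changes(
        wide["model"].to_numpy(),
        wide["conventional"].to_numpy(),
        parameter=parameter,
        modality="carotid",
        day_pair="All",
    )


def rtm_null_experiment(
    n_participants: int = 500,
    seed: int = 1,
    sigma_alpha: float = 0.10,
    sigma_eps: float = 0.05,
    parameter: str = "R_sys",
) -> dict:
    """RTM analyses on a null cohort (no intervention effect) of true
    parameter draws, compared with the closed-form expected slopes."""
    spec = TruthSpec(
        sigma_alpha={parameter: sigma_alpha},
        sigma_eps={parameter: sigma_eps},
        effects={},
        seed=seed,
    )
    cohort = sample_cohort(n_participants, spec)
    rows = []
    for part in cohort:
        for day, theta in longitudinal_truth(part, spec).items():
            rows.append(
                {"participant": part.participant_id, "day": day,
                 "value": getattr(theta, parameter)}
            )
    df = pd.DataFrame(rows)
    change: RegressionResult = RTMChangeModel(df).fit()
    final: RegressionResult = RTMFinalValueModel(df).fit()
    theory = rtm_null_slopes(sigma_alpha, sigma_eps)
    return {
        "change_slope": change.slope,
        "change_slope_se": float(change.bse["deviation"]),
        "change_slope_theory": theory["change"],
        "final_value_slope": final.slope,
        "final_value_slope_se": float(final.bse["deviation"]),
        "final_value_slope_theory": theory["final_value"],
        "n": n_participants,
    }
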