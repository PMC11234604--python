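"""Regression-to-the-mean and longitudinal regression analyses.

Two kinds of questions are asked of the per-day parameter estimates:

* Regression to the mean (RTM).  Under the variance decomposition
  θ_ij = μ + α_i + ε_ij (population mean, personal deviation, day-to-day
  error) with no true change, (i) the final-day value regressed on the
  deviation of the personal two-day average from the population mean has a
  positive slope σ_α²/(σ_α² + σ_ε²/2), and (ii) the day-1 → day-3 change
  regressed on the day-1 deviation from the population mean has slope
  −σ_ε²/(σ_α² + σ_ε²).  Strong agreement with these slopes flags apparent
  "changes" that are artifacts of extreme first observations.

* Covariate regressions in four fixed configurations (A: age, sex, BMI;
  B adds SV; C adds VO2max; D adds both): ordinary least squares for the
  day-1 → day-3 change per participant, and a random-intercept linear
  mixed-effects model (REML) for the repeated per-day values.  Dependent
  variables are Z-score standardized; regressors are Z-scored (OLS) or
  grand-mean centered (LMM).

Model fitting is delegated to statsmodels (OLS / MixedLM); this module owns
the configuration, standardization and reporting conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: regressor sets per configuration letter.  The "results" labeling has
#: B = +SV and C = +VO2max; the alternative "methods" labeling swaps B and C.
_BASE_REGRESSORS = ("age", "sex", "BMI")
_CONFIG_EXTRAS = {
    "results": {"A": (), "B": ("SV",), "C": ("VO2max",), "D": ("SV", "VO2max")},
    "methods": {"A": (), "B": ("VO2max",), "C": ("SV",), "D": ("SV", "VO2max")},
}


@dataclass
class RegressionSpec:
    """Which regression to run: configuration letter, dependent variable,
    estimator, and the letter→regressor labeling convention."""

    config: Literal["A", "B", "C", "D"] = "A"
    dependent: str = "R_sys"
    estimator: Literal["ols", "lmm"] = "ols"
    labeling: Literal["results", "methods"] = "results"

    def __post_init__(self) -> None:
        if self.config not in "ABCD":
            raise ValueError("config must be one of A, B, C, D")
        if self.labeling not in _CONFIG_EXTRAS:
            raise ValueError("labeling must be 'results' or 'methods'")

    @property
    def regressors(self) -> tuple[str, ...]:
        return _BASE_REGRESSORS + _CONFIG_EXTRAS[self.labeling][self.config]


@dataclass
class RegressionResult:
    """Unified result record for the RTM, OLS and LMM analyses."""

    params: pd.Series  # coefficients incl. intercept ("const")
    bse: pd.Series  # standard errors
    pvalues: pd.Series
    adj_r2: float | None = None  # may be negative; never clipped
    fstat: float | None = None
    f_pvalue: float | None = None
    resid_var: float | None = None  # "unexplained" variance
    group_var: float | None = None  # random-intercept variance (LMM)
    n_obs: int = 0
    n_groups: int | None = None
    group_size: float | None = None
    converged: bool = True
    kind: str = "ols"

    @property
    def significant(self) -> pd.Series:
        """p < 0.05 flags per coefficient."""
        return self.pvalues < 0.05

    @property
    def slope(self) -> float:
        """Convenience: the single non-intercept coefficient (RTM models)."""
        others = [k for k in self.params.index if k != "const"]
        if len(others) != 1:
            raise AttributeError("slope is only defined for single-regressor models")
        return float(self.params[others[0]])

    def summary(self) -> str:
        lines = [f"{self.kind} regression — n = {self.n_obs}"]
        if self.n_groups is not None:
            lines[0] += f", groups = {self.n_groups} (avg size {self.group_size:.1f})"
        lines.append(f"  {'term':<12} {'coef':>10} {'SE':>10} {'p':>10}  sig")
        for k in self.params.index:
            star = "*" if self.pvalues[k] < 0.05 else ""
            lines.append(
                f"  {k:<12} {self.params[k]:>10.4f} {self.bse[k]:>10.4f} "
                f"{self.pvalues[k]:>10.4g}  {star}"
            )
        if self.adj_r2 is not None:
            lines.append(f"  adj. r2 = {self.adj_r2:.4f}")
        if self.fstat is not None:
            lines.append(f"  F = {self.fstat:.4f} (p = {self.f_pvalue:.4g})")
        if self.group_var is not None:
            lines.append(f"  group variance = {self.group_var:.4f}")
        if self.resid_var is not None:
            lines.append(f"  unexplained variance = {self.resid_var:.4f}")
        if not self.converged:
            lines.append("  WARNING: estimator did not converge")
        return "\n".join(lines)


def standardize(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    mode: Literal["zscore", "center"] = "zscore",
) -> pd.DataFrame:
    """Z-score ((x − mean)/SD, population SD) or grand-mean center columns."""
    out = table.copy()
    cols = columns if columns is not None else list(out.select_dtypes("number").columns)
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"column {c!r} needs at least 2 values")
        mu = x.mean()
        if mode == "zscore":
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"column {c!r} has zero SD; cannot Z-score")
            out[c] = (x - mu) / sd
        elif mode == "center":
            out[c] = x - mu
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify a minimal set of offending columns by greedy removal
        bad = []
        cols = list(X.columns)
        for c in cols:
            others = [o for o in cols if o != c and o not in bad]
            if np.linalg.matrix_rank(X[others].to_numpy(dtype=float)) == rank:
                bad.append(c)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad or cols}")


def _ols_result(y: np.ndarray, X: pd.DataFrame, kind: str) -> RegressionResult:
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        adj_r2=float(fit.rsquared_adj),
        fstat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        resid_var=float(fit.mse_resid),
        n_obs=int(fit.nobs),
        kind=kind,
    )


class RTMFinalValueModel:
    """OLS of the final-day value on the deviation of the personal average
    (first two days only) from the population mean over all days.

    ``data`` is long format with columns participant, day ("1","2","3"),
    value — one parameter / method / modality at a time.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data

    def _wide(self) -> pd.DataFrame:
        data = self.data.assign(day=self.data["day"].astype(str))
        wide = data.pivot_table(index="participant", columns="day", values="value")
        wide = wide.dropna(subset=["1", "2", "3"])
        if len(wide) < 3:
            raise ValueError("need at least 3 participants with all three days")
        return wide

    def fit(self) -> RegressionResult:
        wide = self._wide()
        pop_mean = self.data["value"].mean()  # over all participant-days
        dev = (wide["1"] + wide["2"]) / 2.0 - pop_mean
        if dev.std(ddof=0) == 0:
            raise ValueError("personal-average deviations have zero variance")
        X = pd.DataFrame({"const": 1.0, "deviation": dev})
        return _ols_result(wide["3"].to_numpy(), X, kind="rtm-final-value")


class RTMChangeModel:
    """OLS of the day-1 → day-3 change on the day-1 deviation from the
    population mean; a strongly negative slope flags regression to the mean."""

    def __init__(self, data: pd.DataFrame):
        self.data = data

    def fit(self) -> RegressionResult:
        data = self.data.assign(day=self.data["day"].astype(str))
        wide = data.pivot_table(index="participant", columns="day", values="value")
        wide = wide.dropna(subset=["1", "3"])
        if len(wide) < 3:
            raise ValueError("need at least 3 participants with days 1 and 3")
        pop_mean = self.data["value"].mean()
        dev = wide["1"] - pop_mean
        if dev.std(ddof=0) == 0:
            raise ValueError("day-1 deviations have zero variance")
        X = pd.DataFrame({"const": 1.0, "deviation": dev})
        return _ols_result((wide["3"] - wide["1"]).to_numpy(), X, kind="rtm-change")


class MixedEffectsModel:
    """Random-intercept linear mixed model of the per-day parameter values.

    ``data``: one row per participant-day with columns ``participant``,
    ``value`` (the dependent parameter) and the configuration's regressors.  The
    dependent is Z-scored, regressors are grand-mean centered (sex coded 0/1
    first), and the model is estimated by REML with personal deviations
    allowed in the intercept only.
    """

    def __init__(self, data: pd.DataFrame, spec: RegressionSpec):
        self.spec = spec
        self.data = data

    def fit(self) -> RegressionResult:
        cols = list(self.spec.regressors)
        d = self.data.dropna(subset=["value", "participant", *cols]).copy()
        counts = d.groupby("participant").size()
        if (counts < 2).all():
            raise ValueError("mixed model needs repeated measures (>= 2 days) per participant")
        d = standardize(d, ["value"], mode="zscore")
        d = standardize(d, cols, mode="center")
        X = sm.add_constant(d[cols])
        _check_rank(X)
        model = sm.MixedLM(d["value"].to_numpy(), X, groups=d["participant"])
        with np.errstate(all="ignore"):
            fit = model.fit(reml=True)
        group_var = float(np.asarray(fit.cov_re)[0, 0])
        return RegressionResult(
            params=fit.fe_params,
            bse=fit.bse_fe,
            pvalues=fit.pvalues[fit.fe_params.index],
            resid_var=float(fit.scale),
            group_var=group_var,
            n_obs=int(fit.nobs),
            n_groups=int(len(counts)),
            group_size=float(counts.mean()),
            converged=bool(fit.converged),
            kind=f"lmm-{self.spec.config}",
        )


class OLSChangeModel:
    """OLS of the standardized day-1 → day-3 parameter change on age, sex and
    the per-configuration change covariates (ΔBMI, and ΔSV / ΔVO2max).

    ``data``: one row per participant with columns ``delta`` (the dependent
    change), ``age``, ``sex``, ``dBMI`` and, as required, ``dSV`` /
    ``dVO2max``.  Dependent and regressors are Z-scored.
    """

    def __init__(self, data: pd.DataFrame, spec: RegressionSpec):
        self.spec = spec
        self.data = data

    @property
    def regressors(self) -> list[str]:
        mapping = {"age": "age", "sex": "sex", "BMI": "dBMI", "SV": "dSV", "VO2max": "dVO2max"}
        return [mapping[r] for r in self.spec.regressors]

    def fit(self) -> RegressionResult:
        cols = self.regressors
        d = self.data.dropna(subset=["delta", *cols]).copy()
        if len(d) <= len(cols) + 1:
            raise ValueError("need more participants than regressors + intercept")
        d = standardize(d, ["delta", *cols], mode="zscore")
        X = sm.add_constant(d[cols])
        _check_rank(X)
        res = _ols_result(d["delta"].to_numpy(), X, kind=f"ols-change-{self.spec.config}")
        return res


def fit_lmm(spec: RegressionSpec, data: pd.DataFrame) -> RegressionResult:
    """Functional wrapper around :class:`MixedEffectsModel`."""
    return MixedEffectsModel(data, spec).fit()


def fit_ols_change(spec: RegressionSpec, data: pd.DataFrame) -> RegressionResult:
    """Functional wrapper around :class:`OLSChangeModel`."""
    return OLSChangeModel(data, spec).fit()


def rtm_final_value_model(data: pd.DataFrame) -> RegressionResult:
    """Functional wrapper around :class:`RTMFinalValueModel`."""
    return RTMFinalValueModel(data).fit()


def rtm_change_model(data: pd.DataFrame) -> RegressionResult:
    """Functional wrapper around :class:`RTMChangeModel`."""
    return RTMChangeModel(data).fit()


def rtm_null_slopes(sigma_alpha: float, sigma_eps: float) -> dict[str, float]:
    """Closed-form expected RTM slopes under the null (no true change):
    final-value slope σ_α²/(σ_α² + σ_ε²/2), change slope −σ_ε²/(σ_α² + σ_ε²)."""
    va, ve = sigma_alpha**2, sigma_eps**2
    return {
        "final_value": va / (va + ve / 2.0),
        "change": -ve / (va + ve),
    }
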