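"""Parameter changes between measurement days and their summaries.

Operates on long-format estimate tables with columns
``participant, day, method, modality, parameter, value`` where ``method`` is
"model" (personalized estimates) or "conventional" (bedside formulas).
Changes Δ_{i,j} = value_day_j − value_day_i are computed for every available
day pair, summarized per parameter/method/modality, and the model-based and
conventional change vectors are correlated (Pearson r with t-based p value
and Fisher-z confidence interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

#: ordered day pairs and their labels; the CPET pairs compare a measurement
#: day with the morning after the cardiopulmonary exercise test
DAY_PAIRS = {
    ("1", "2"): "1-2",
    ("1", "3"): "1-3",
    ("2", "3"): "2-3",
    ("1", "1post"): "CPET-week0",
    ("3", "3post"): "CPET-week12",
}
CORE_PAIRS = ("1-2", "1-3", "2-3")

_EST_COLUMNS = ["participant", "day", "method", "modality", "parameter", "value"]


@dataclass
class CorrelationResult:
    """Pearson correlation of paired change vectors."""

    r: float
    p_value: float
    ci95: tuple[float, float]
    n: int
    parameter: str | None = None
    modality: str | None = None
    day_pair: str | None = None


def compute_changes(estimates: pd.DataFrame) -> pd.DataFrame:
    """Signed parameter changes for every available day pair.

    Missing days simply drop the affected pairs (pairwise-complete, no
    imputation).  Returns columns
    ``participant, parameter, method, modality, day_pair, delta``.
    """
    missing = set(_EST_COLUMNS) - set(estimates.columns)
    if missing:
        raise ValueError(f"estimates table lacks columns: {sorted(missing)}")
    estimates = estimates.assign(day=estimates["day"].astype(str))
    wide = estimates.pivot_table(
        index=["participant", "parameter", "method", "modality"],
        columns="day",
        values="value",
        aggfunc="first",
    )
    rows = []
    for (part, param, method, modality), vals in wide.iterrows():
        for (d_i, d_j), label in DAY_PAIRS.items():
            if d_i in vals.index and d_j in vals.index:
                vi, vj = vals[d_i], vals[d_j]
                if pd.notna(vi) and pd.notna(vj):
                    rows.append(
                        {
                            "participant": part,
                            "parameter": param,
                            "method": method,
                            "modality": modality,
                            "day_pair": label,
                            "delta": vj - vi,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["participant", "parameter", "method", "modality", "day_pair", "delta"]
    )


def summarize_changes(
    ct: pd.DataFrame,
    pairs: tuple[str, ...] = CORE_PAIRS,
    by: tuple[str, ...] = ("parameter", "method", "modality"),
) -> pd.DataFrame:
    """Extrema and means of the (signed and unsigned) changes.

    Deltas are pooled across participants and the given day pairs; SDs are
    population SDs (ddof 0).
    """
    sel = ct[ct["day_pair"].isin(pairs)] if pairs is not None else ct
    if sel.empty:
        raise ValueError("no change rows for the requested day pairs")

    def _agg(g: pd.Series) -> pd.Series:
        d = g.to_numpy(dtype=float)
        return pd.Series(
            {
                "max_abs_change": np.max(np.abs(d)),
                "min_abs_change": np.min(np.abs(d)),
                "max_change": np.max(d),
                "min_change": np.min(d),
                "mean_change": np.mean(d),
                "sd_change": np.std(d, ddof=0),
                "mean_abs_change": np.mean(np.abs(d)),
                "sd_abs_change": np.std(np.abs(d), ddof=0),
                "n": len(d),
            }
        )

    return sel.groupby(list(by))["delta"].apply(_agg).unstack().reset_index()


def correlate_changes(
    model_deltas: np.ndarray,
    conv_deltas: np.ndarray,
    **metadata,
) -> CorrelationResult:
    """Pearson correlation of paired model vs conventional changes.

    r from the covariance formula; two-sided p from the t transform with
    n − 2 df; 95% CI from the Fisher z-transform (exact ±1 correlations get
    a degenerate CI and p = 0).
    """
    x = np.asarray(model_deltas, dtype=float)
    y = np.asarray(conv_deltas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("model and conventional deltas must be paired 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in one of the change vectors")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))

    if abs(r) == 1.0:
        p = 0.0
        ci = (r, r)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * _stats.t.sf(abs(t), n - 2))
        if n > 3:
            z = np.arctanh(r)
            half = _stats.norm.ppf(0.975) / np.sqrt(n - 3)
            ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
        else:
            ci = (-1.0, 1.0)
    return CorrelationResult(r=r, p_value=p, ci95=ci, n=n, **metadata)


def correlation_table(
    ct: pd.DataFrame,
    pairs: tuple[str, ...] = CORE_PAIRS,
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Model-vs-conventional change correlations per parameter, modality and
    day pair, plus an "All" row pooling every day pair."""
    rows = []
    for (param, modality), grp in ct.groupby(["parameter", "modality"]):
        wide = grp.pivot_table(
            index=["participant", "day_pair"], columns="method", values="delta"
        )
        if not {"model", "conventional"}.issubset(wide.columns):
            continue
        wide = wide.dropna(subset=["model", "conventional"])
        blocks = [(p, wide[wide.index.get_level_values("day_pair") == p]) for p in pairs]
        if include_pooled:
            blocks.append(("All", wide[wide.index.get_level_values("day_pair").isin(pairs)]))
        for label, block in blocks:
            if len(block) < 3:
                continue
            res = correlate_changes(
                block["model"].to_numpy(),
                block["conventional"].to_numpy(),
                parameter=param,
                modality=modality,
                day_pair=label,
            )
            rows.append(
                {
                    "parameter": param,
                    "modality": modality,
                    "day_pair": label,
                    "r": res.r,
                    "p_value": res.p_value,
                    "ci95_low": res.ci95[0],
                    "ci95_high": res.ci95[1],
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def cpet_change_report(ct: pd.DataFrame) -> pd.DataFrame:
    """Exercise-test change summary: mean (SD) and mean absolute change for
    the two morning-after-CPET pairs and, for the same participants, the
    plain day-1 → day-3 change measured before each CPET."""
    cpet_pairs = ["CPET-week0", "CPET-week12"]
    have_post = ct[ct["day_pair"].isin(cpet_pairs)]
    if have_post.empty:
        warnings.warn("cohort contains no post-CPET measurement days", stacklevel=2)
        return pd.DataFrame(
            columns=["parameter", "method", "group", "mean_change", "sd_change",
                     "mean_abs_change", "sd_abs_change", "n"]
        )
    cpet_participants = have_post["participant"].unique()
    pre = ct[(ct["day_pair"] == "1-3") & ct["participant"].isin(cpet_participants)].copy()
    pre["day_pair"] = "preCPET-0-12"
    sel = pd.concat([have_post, pre], ignore_index=True)

    rows = []
    for (param, method, group), grp in sel.groupby(["parameter", "method", "day_pair"]):
        d = grp["delta"].to_numpy(dtype=float)
        rows.append(
            {
                "parameter": param,
                "method": method,
                "group": group,
                "mean_change": np.mean(d),
                "sd_change": np.std(d, ddof=0),
                "mean_abs_change": np.mean(np.abs(d)),
                "sd_abs_change": np.std(np.abs(d), ddof=0),
                "n": len(d),
            }
        )
    return pd.DataFrame(rows)
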