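"""Behavioral and molecular phenotype statistics.

Percent maximum possible effect (%MPE) from tail-flick latencies,
tolerance classification at the 100% MPE boundary, dose-response ED50
shift with a slope-difference test, consumption-vs-tolerance regression,
and butyrate biosynthetic capacity from qPCR gene copies normalized to
16S copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_MPE_EPS = 1e-9


def percent_mpe(latency: float, baseline: float, cutoff: float) -> float:
    """100 * (latency - baseline) / (cutoff - baseline), clamped to
    [0, 100]."""
    if cutoff <= baseline:
        raise ValueError("cutoff must exceed baseline latency")
    if np.any(np.asarray(latency) < 0):
        raise ValueError("latency must be >= 0")
    raw = 100.0 * (np.asarray(latency, dtype=float) - baseline) \
        / (cutoff - baseline)
    out = np.clip(raw, 0.0, 100.0)
    return float(out) if np.isscalar(latency) else out


def classify_tolerance(end_mpe: float) -> str:
    """non_tolerant iff end-of-paradigm %MPE equals 100 (within eps)."""
    if not 0.0 <= end_mpe <= 100.0:
        raise ValueError("end_mpe must lie in [0, 100]")
    return "non_tolerant" if end_mpe >= 100.0 - _MPE_EPS else "tolerant"


@dataclass
class DoseResponseFit:
    slope: float
    intercept: float
    slope_se: float
    ed50: float | None     # dose where fitted %MPE crosses 50
    ed50_ci: tuple[float, float] | None
    n: int


def _fit_dose_response(doses, mpes) -> DoseResponseFit:
    doses = np.asarray(doses, dtype=float)
    mpes = np.asarray(mpes, dtype=float)
    if len(np.unique(doses)) < 2:
        raise ValueError("need >= 2 dose levels")
    res = stats.linregress(doses, mpes)
    if res.slope == 0:
        ed50, ci = None, None
    else:
        ed50 = (50.0 - res.intercept) / res.slope
        if ed50 <= 0:
            ed50, ci = None, None
        else:
            # delta-method 95% CI on the crossing dose
            n = len(doses)
            resid = mpes - (res.intercept + res.slope * doses)
            s2 = (resid ** 2).sum() / max(n - 2, 1)
            xbar = doses.mean()
            sxx = ((doses - xbar) ** 2).sum()
            var_pred = s2 * (1 / n + (ed50 - xbar) ** 2 / sxx)
            half = 1.96 * np.sqrt(var_pred) / abs(res.slope)
            ci = (ed50 - half, ed50 + half)
    return DoseResponseFit(slope=float(res.slope),
                           intercept=float(res.intercept),
                           slope_se=float(res.stderr),
                           ed50=ed50, ed50_ci=ci, n=len(doses))


def exclude_ceiling_floor(frame: pd.DataFrame) -> pd.DataFrame:
    """Drop mice with identical %MPE at both doses (ceiling/floor)."""
    def varies(group):
        return group["mpe"].nunique() > 1
    return frame.groupby("mouse_id").filter(varies)


def ed50_shift(day1: pd.DataFrame, day10: pd.DataFrame,
               apply_exclusion: bool = True):
    """Dose-response regressions for two days and a two-tailed test of
    slope change.

    Each frame needs columns ``mouse_id``, ``dose``, ``mpe``. Mice at
    ceiling/floor on both doses are excluded before fitting. Returns
    (fit_day1, fit_day10, p_slope_change).
    """
    if apply_exclusion:
        day1 = exclude_ceiling_floor(day1)
        day10 = exclude_ceiling_floor(day10)
    fit1 = _fit_dose_response(day1["dose"], day1["mpe"])
    fit10 = _fit_dose_response(day10["dose"], day10["mpe"])
    # pooled-SE t statistic on the slope difference
    se = np.sqrt(fit1.slope_se ** 2 + fit10.slope_se ** 2)
    df = fit1.n + fit10.n - 4
    if se == 0:
        p = 1.0
    else:
        t = (fit10.slope - fit1.slope) / se
        p = float(2 * stats.t.sf(abs(t), df))
    return fit1, fit10, p


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def consumption_correlation(consumption, tolerance_metric
                            ) -> RegressionResult:
    """Least-squares line + Pearson test of consumption vs tolerance."""
    x = np.asarray(consumption, dtype=float)
    y = np.asarray(tolerance_metric, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 mice")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in consumption")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2),
                            p=float(res.pvalue), n=len(x))


@dataclass
class CapacityResult:
    group_means: dict[str, float]
    fold_differences: dict[tuple[str, str], float]
    t_statistic: float
    p: float
    per_gene_means: dict[str, dict[str, float]]


def butyrate_capacity(records: pd.DataFrame, group_column: str = "tolerance"
                      ) -> CapacityResult:
    """Per-sample capacity = (bcoat + buk) / 16S copies; group means,
    fold ratios and a two-tailed two-sample t-test (first two groups).
    Per-gene normalized means are also reported."""
    req = {"bcoat_copies", "buk_copies", "s16_copies", group_column}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (records["s16_copies"] <= 0).any():
        raise ValueError("zero or negative 16S copies")
    df = records.copy()
    df["capacity"] = (df["bcoat_copies"] + df["buk_copies"]) \
        / df["s16_copies"]
    groups = sorted(df[group_column].unique())
    means = {g: float(df.loc[df[group_column] == g, "capacity"].mean())
             for g in groups}
    folds = {}
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            folds[(gi, gj)] = (means[gi] / means[gj]
                               if means[gj] > 0 else np.inf)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    a = df.loc[df[group_column] == groups[0], "capacity"]
    b = df.loc[df[group_column] == groups[1], "capacity"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group for the t-test")
    t_res = stats.ttest_ind(a, b)
    per_gene = {}
    for gene in ("bcoat", "buk"):
        ratio = df[f"{gene}_copies"] / df["s16_copies"]
        per_gene[gene] = {
            g: float(ratio[df[group_column] == g].mean()) for g in groups}
    return CapacityResult(group_means=means, fold_differences=folds,
                          t_statistic=float(t_res.statistic),
                          p=float(t_res.pvalue),
                          per_gene_means=per_gene)
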