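"""Taylor's power law stability analyses.

The law V = a * M^b links a taxon's variance to its mean abundance; on
log scale ln V = b ln M + ln a, so b is a slope recoverable by ordinary
least squares across taxa. The Type I extension pools samples per group
(cross-population variability); the Type IV extension fits each mouse x
phase over its timepoints (within-individual temporal stability). The
change-in-slope statistic standardizes each Type IV slope against the
pre-phase population mean; positive values indicate instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gutdyn.tables_io import CountTable, SampleMetadata, relative_abundance


@dataclass
class TaylorFit:
    unit: str
    a: float        # scalar parameter (V = a M^b)
    b: float        # slope
    r2: float
    n_taxa_used: int
    n_taxa_excluded: int = 0
    log_means: np.ndarray | None = None
    log_vars: np.ndarray | None = None


@dataclass
class SlopeChange:
    mouse_id: str
    phase: str
    b: float
    delta_b: float


def taylor_fit(matrix: np.ndarray, unit: str = "",
               min_taxa: int = 5) -> TaylorFit:
    """OLS of ln V on ln M across taxa (columns) of a samples x taxa
    matrix. Taxa with zero mean or zero variance are excluded and
    counted."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be samples x taxa")
    M = X.mean(axis=0)
    V = X.var(axis=0, ddof=1)
    usable = (M > 0) & (V > 0) & np.isfinite(M) & np.isfinite(V)
    n_used = int(usable.sum())
    if n_used < min_taxa:
        raise ValueError(
            f"only {n_used} taxa with positive mean and variance "
            f"(need >= {min_taxa})")
    lm = np.log(M[usable])
    lv = np.log(V[usable])
    # closed-form simple regression; slope b, intercept ln a
    lm_c = lm - lm.mean()
    b = float((lm_c @ (lv - lv.mean())) / (lm_c @ lm_c))
    ln_a = float(lv.mean() - b * lm.mean())
    resid = lv - (b * lm + ln_a)
    ss_tot = float(((lv - lv.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return TaylorFit(unit=unit, a=float(np.exp(ln_a)), b=b, r2=r2,
                     n_taxa_used=n_used,
                     n_taxa_excluded=int(len(M) - n_used),
                     log_means=lm, log_vars=lv)


def _abundance_matrix(table: CountTable, scale: str) -> np.ndarray:
    if scale == "relative":
        return relative_abundance(table)
    if scale == "counts":
        return table.counts.astype(float)
    raise ValueError(f"unknown scale {scale!r}")


def taylor_type1(table: CountTable, metadata: SampleMetadata,
                 grouping: tuple[str, ...] = ("tolerance", "phase"),
                 scale: str = "relative",
                 min_samples: int = 5) -> list[TaylorFit]:
    """Cross-population fit: per group, M and V across all its samples."""
    meta = metadata.aligned_to(table)
    X = _abundance_matrix(table, scale)
    fits = []
    for key, idx in meta.groupby(list(grouping)).groups.items():
        rows = meta.index.get_indexer(idx)
        if len(rows) < min_samples:
            raise ValueError(f"group {key} has < {min_samples} samples")
        label = key if isinstance(key, str) else ":".join(map(str, key))
        fits.append(taylor_fit(X[rows], unit=label))
    return fits


def taylor_type4(table: CountTable, metadata: SampleMetadata,
                 scale: str = "relative",
                 min_timepoints: int = 2) -> list[TaylorFit]:
    """Within-individual fit: per mouse x phase over its timepoints.

    The default admits 2 timepoints (sample variance is defined there)
    because the pre phase of a weekly schedule spans only two weeks and
    must anchor the slope standardization.
    """
    meta = metadata.aligned_to(table)
    X = _abundance_matrix(table, scale)
    fits = []
    for (mouse, phase), idx in meta.groupby(
            ["mouse_id", "phase"], sort=True).groups.items():
        rows = meta.index.get_indexer(idx)
        if len(rows) < min_timepoints:
            continue
        fits.append(taylor_fit(X[rows], unit=f"{mouse}:{phase}"))
    if not fits:
        raise ValueError("no mouse x phase unit has enough timepoints")
    return fits


def standardize_slopes(fits: list[TaylorFit]) -> list[SlopeChange]:
    """delta_b = b(mouse, phase) - mean of all mice's pre-phase b."""
    parsed = []
    for fit in fits:
        mouse, _, phase = fit.unit.partition(":")
        if not phase:
            raise ValueError(f"unit {fit.unit!r} is not 'mouse:phase'")
        parsed.append((mouse, phase, fit.b))
    pre = [b for _, phase, b in parsed if phase == "pre"]
    if not pre:
        raise ValueError("no pre-phase fits to standardize against")
    pre_mean = float(np.mean(pre))
    return [SlopeChange(mouse_id=m, phase=p, b=b, delta_b=b - pre_mean)
            for m, p, b in parsed]


def slope_change_summary(changes: list[SlopeChange],
                         metadata: SampleMetadata | None = None
                         ) -> pd.DataFrame:
    """Group mean delta_b with 95% CI per (tolerance group, phase)."""
    df = pd.DataFrame([vars(c) for c in changes])
    if metadata is not None:
        tol = (metadata.frame[["mouse_id", "tolerance"]]
               .drop_duplicates("mouse_id"))
        df = df.merge(tol, on="mouse_id", how="left")
        keys = ["tolerance", "phase"]
    else:
        keys = ["phase"]
    def ci95(v):
        v = np.asarray(v, dtype=float)
        if len(v) < 2:
            return np.nan
        return 1.96 * v.std(ddof=1) / np.sqrt(len(v))
    return (df.groupby(keys)["delta_b"]
            .agg(mean="mean", ci95=ci95, n="size")
            .reset_index())


def fits_to_frame(fits: list[TaylorFit]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(unit=f.unit, a=f.a, b=f.b, r2=f.r2,
             n_taxa_used=f.n_taxa_used, n_taxa_excluded=f.n_taxa_excluded)
        for f in fits])
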