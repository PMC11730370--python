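"""Bayesian change-point analysis via the Barry-Hartigan product
partition model.

A univariate series is modeled as independent Gaussian blocks with
block-specific means. A Gibbs sampler sweeps the binary change-indicator
vector; at each position the conditional odds of a change integrate the
block sums of squares over uniform priors U(0, p0) on the change
probability and U(0, w0) on the signal-to-noise ratio. Posterior change
probabilities are the fraction of post-burn-in sweeps with a change at
each position; posterior means average shrunken block means.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, betainc

from gutdyn.diversity import shannon
from gutdyn.tables_io import CountTable, SampleMetadata, subset_samples

_GL_POINTS = 24


@dataclass
class BcpConfig:
    """Sampler parameters (reference-implementation defaults)."""

    p0: float = 0.2
    w0: float = 0.2
    burn_in: int = 50
    mcmc: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must lie in (0, 1]")
        if not 0 < self.w0 <= 1:
            raise ValueError("w0 must lie in (0, 1]")
        if self.mcmc <= 0:
            raise ValueError("mcmc must be > 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass
class BcpResult:
    n: int
    posterior_prob: np.ndarray  # position 0 is NaN (no change possible)
    posterior_mean: np.ndarray

    def __post_init__(self) -> None:
        probs = self.posterior_prob[1:]
        if np.nanmin(probs, initial=0.0) < -1e-12 or \
                np.nanmax(probs, initial=0.0) > 1 + 1e-12:
            raise ValueError("posterior probabilities outside [0, 1]")


class _SegmentStats:
    """O(1) segment sums of squares from prefix sums."""

    def __init__(self, x: np.ndarray):
        self.n = len(x)
        self.cs = np.concatenate(([0.0], np.cumsum(x)))
        self.cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
        self.xbar = float(x.mean())

    def within(self, lo: int, hi: int) -> float:
        """Sum of squared deviations from the segment mean on [lo, hi)."""
        m = hi - lo
        s = self.cs[hi] - self.cs[lo]
        s2 = self.cs2[hi] - self.cs2[lo]
        return max(s2 - s * s / m, 0.0)

    def between(self, lo: int, hi: int) -> float:
        """n_seg * (segment mean - grand mean)^2 on [lo, hi)."""
        m = hi - lo
        mean = (self.cs[hi] - self.cs[lo]) / m
        return m * (mean - self.xbar) ** 2

    def mean(self, lo: int, hi: int) -> float:
        return (self.cs[hi] - self.cs[lo]) / (hi - lo)


def _gl_grid(w0: float):
    nodes, weights = np.polynomial.legendre.leggauss(_GL_POINTS)
    w = 0.5 * w0 * (nodes + 1.0)
    return w, 0.5 * w0 * weights, np.log(w)


def _log_w_integral(half_b: float, W: float, B: float, n: int,
                    w, logw, gl_logweights) -> float:
    """log of int_0^w0 w^half_b (W + B w)^{-(n-1)/2} dw (Gauss-Legendre)."""
    terms = half_b * logw - 0.5 * (n - 1) * np.log(W + B * w) + gl_logweights
    peak = terms.max()
    return peak + np.log(np.exp(terms - peak).sum())


def bcp(series, config: BcpConfig | None = None) -> BcpResult:
    """Run the product-partition change-point sampler on a 1-D series."""
    config = config or BcpConfig()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("series must be 1-D with length >= 3")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = len(x)
    stats = _SegmentStats(x)
    # for any partition, within-SS + between-SS equals the total SS
    total_ss = stats.within(0, n)
    constant = total_ss < 1e-300

    w_nodes, gl_weights, logw = _gl_grid(config.w0)
    gl_logweights = np.log(gl_weights)
    rng = np.random.default_rng(config.seed)

    # log of int_0^p0 p^(a-1) (1-p)^(b-1) dp, cached per change count
    p_int_cache: dict[int, float] = {}

    def log_p_integral(a: int, b: int) -> float:
        key = a
        if key not in p_int_cache:
            frac = betainc(a, b, config.p0)
            p_int_cache[key] = (betaln(a, b) + np.log(frac)
                                if frac > 0 else -np.inf)
        return p_int_cache[key]

    rho = np.zeros(n, dtype=bool)  # rho[i]: block starts at position i
    cps: list[int] = []            # sorted changepoint positions (1..n-1)
    prob_acc = np.zeros(n)
    mean_acc = np.zeros(n)
    kept = 0

    # running within / between sums of squares for the current partition
    def partition_ss():
        bounds = [0, *cps, n]
        W = sum(stats.within(lo, hi)
                for lo, hi in zip(bounds[:-1], bounds[1:]))
        B = sum(stats.between(lo, hi)
                for lo, hi in zip(bounds[:-1], bounds[1:]))
        return W, B

    W_cur, B_cur = partition_ss()

    for sweep in range(config.burn_in + config.mcmc):
        for i in range(1, n):
            j = bisect_left(cps, i)
            prev = cps[j - 1] if j > 0 else 0
            has_change = j < len(cps) and cps[j] == i
            nxt_idx = j + 1 if has_change else j
            nxt = cps[nxt_idx] if nxt_idx < len(cps) else n

            w_merged = stats.within(prev, nxt)
            b_merged = stats.between(prev, nxt)
            w_split = stats.within(prev, i) + stats.within(i, nxt)
            b_split = stats.between(prev, i) + stats.between(i, nxt)
            if has_change:
                W_rest = W_cur - w_split
                B_rest = B_cur - b_split
            else:
                W_rest = W_cur - w_merged
                B_rest = B_cur - b_merged

            b = len(cps) + (0 if has_change else 1)  # changes if split
            log_odds = (log_p_integral(b + 1, n - b)
                        - log_p_integral(b, n - b + 1))
            if not constant:
                W1 = W_rest + w_split
                B1 = B_rest + b_split
                W0 = W_rest + w_merged
                B0 = B_rest + b_merged
                log_odds += (
                    _log_w_integral(b / 2.0, W1, B1, n,
                                    w_nodes, logw, gl_logweights)
                    - _log_w_integral((b - 1) / 2.0, W0, B0, n,
                                      w_nodes, logw, gl_logweights))
            else:
                # zero-variance limit: the (W + Bw) factors cancel and
                # the w-ratio collapses to sqrt(w0) * (b+1)/(b+2)
                log_odds += 0.5 * np.log(config.w0) + np.log(
                    (b + 1) / (b + 2))

            p_change = 1.0 / (1.0 + np.exp(-log_odds))
            new_change = rng.random() < p_change
            if new_change and not has_change:
                insort(cps, i)
                W_cur = W_rest + w_split
                B_cur = B_rest + b_split
                rho[i] = True
            elif not new_change and has_change:
                cps.pop(j)
                W_cur = W_rest + w_merged
                B_cur = B_rest + b_merged
                rho[i] = False
            # unchanged state: W_cur, B_cur already correct

        if sweep >= config.burn_in:
            kept += 1
            prob_acc[1:] += rho[1:]
            mean_acc += _conditional_means(stats, cps, n, constant,
                                           w_nodes, logw, gl_logweights,
                                           config.w0)

    posterior_prob = prob_acc / kept
    posterior_prob[0] = np.nan
    return BcpResult(n=n, posterior_prob=posterior_prob,
                     posterior_mean=mean_acc / kept)


def _conditional_means(stats, cps, n, constant,
                       w_nodes, logw, gl_logweights, w0) -> np.ndarray:
    """Block means shrunk toward the grand mean by the posterior of the
    signal-to-noise ratio w given the current partition."""
    bounds = [0, *cps, n]
    if constant:
        return np.full(n, stats.xbar)
    W = sum(stats.within(lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:]))
    B = sum(stats.between(lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:]))
    b = len(cps)
    if W + B > 1e-300:
        log_num = _log_w_integral(b / 2.0 + 1.0, W, B, n,
                                  w_nodes, logw, gl_logweights)
        log_den = _log_w_integral(b / 2.0, W, B, n,
                                  w_nodes, logw, gl_logweights)
        w_hat = float(np.exp(log_num - log_den))
    else:
        w_hat = w0 / 2.0
    out = np.empty(n)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out[lo:hi] = stats.xbar + (1.0 - w_hat) * (
            stats.mean(lo, hi) - stats.xbar)
    return out


def flag_changepoints(result: BcpResult, threshold: float = 0.70
                      ) -> list[int]:
    """Positions whose posterior change probability exceeds ``threshold``.

    The study uses 0.70 for alpha-diversity series and 0.790 for
    per-taxon abundance series; both are just values of ``threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    probs = result.posterior_prob
    return [int(i) for i in range(1, result.n) if probs[i] > threshold]


@dataclass
class GroupSeries:
    group: str
    positions: np.ndarray       # sequential sample number within group
    values: np.ndarray          # statistic per sample
    mean_by_week: pd.DataFrame  # week, mean, sem (for plotting)
    sample_ids: list[str] = field(default_factory=list)


def series_from_cohort(table: CountTable, metadata: SampleMetadata,
                       statistic: str, group: str,
                       group_column: str = "tolerance",
                       taxon: str | None = None) -> GroupSeries:
    """Per-group sequential series of an alpha statistic or a taxon's
    relative abundance, ordered by (week, mouse_id)."""
    meta = metadata.aligned_to(table)
    mask = meta[group_column] == group
    if not mask.any():
        raise ValueError(f"no samples for group {group!r}")
    sub_meta = meta[mask].copy()
    order = sub_meta.sort_values(["week", "mouse_id"]).index
    sub_meta = sub_meta.loc[order]
    sub = subset_samples(table, list(sub_meta["sample_id"]))
    if statistic == "shannon":
        values = shannon(sub).to_numpy()
    elif statistic == "taxon_abundance":
        if taxon is None or taxon not in table.taxon_ids:
            raise ValueError("taxon_abundance requires a known taxon")
        j = sub.taxon_ids.index(taxon)
        totals = sub.counts.sum(axis=1)
        values = sub.counts[:, j] / np.maximum(totals, 1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    by_week = (pd.DataFrame({"week": sub_meta["week"].to_numpy(),
                             "value": values})
               .groupby("week")["value"]
               .agg(mean="mean", sem=lambda v: v.std(ddof=1)
                    / np.sqrt(len(v)))
               .reset_index())
    return GroupSeries(group=group,
                       positions=np.arange(len(values)),
                       values=values,
                       mean_by_week=by_week,
                       sample_ids=list(sub_meta["sample_id"]))


def result_to_frame(result: BcpResult, threshold: float = 0.70
                    ) -> pd.DataFrame:
    flags = set(flag_changepoints(result, threshold))
    return pd.DataFrame({
        "position": np.arange(result.n),
        "posterior_prob": result.posterior_prob,
        "posterior_mean": result.posterior_mean,
        "flag": [i in flags for i in range(result.n)],
    })
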