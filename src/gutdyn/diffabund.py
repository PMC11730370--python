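"""Beta-binomial regression for differential abundance and variability.

Each taxon's counts (out of per-sample library sizes) are fit to a
beta-binomial likelihood with logit links for both the mean mu and the
overdispersion phi; shape parameters are alpha = mu(1-phi)/phi and
beta = (1-mu)(1-phi)/phi. Differential abundance uses a Wald test on a
mean-model coefficient (observed information); differential variability
uses a likelihood-ratio test between nested dispersion designs with
identical mean designs. Benjamini-Hochberg controls FDR across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, psi, expit, logit
from scipy.stats import chi2

from gutdyn.diversity import _bh_adjust
from gutdyn.tables_io import CountTable, SampleMetadata

_PHI_FLOOR = 1e-8


@dataclass
class BetaBinomialFit:
    taxon_id: str
    mean_coefficients: np.ndarray
    mean_se: np.ndarray
    dispersion_coefficients: np.ndarray
    dispersion_se: np.ndarray
    log_likelihood: float
    converged: bool
    n_obs: int = 0
    gradient_norm: float = np.nan


@dataclass
class DifferentialResult:
    taxon_id: str
    test: str                 # wald_abundance | lrt_variability
    statistic: float
    p: float
    effect: float             # covariate coefficient (log-odds)
    se: float = np.nan
    q: float = np.nan
    converged: bool = True


def _loglik_and_grad(theta, y, n, Xm, Xd):
    """Negative beta-binomial log-likelihood and analytic gradient."""
    k = Xm.shape[1]
    beta, gamma = theta[:k], theta[k:]
    # clip linear predictors: keeps gammaln/psi arguments finite when the
    # optimizer probes extreme coefficients
    mu = expit(np.clip(Xm @ beta, -30.0, 30.0))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    phi = np.clip(expit(np.clip(Xd @ gamma, -30.0, 30.0)),
                  _PHI_FLOOR, 1 - _PHI_FLOOR)
    scale = (1 - phi) / phi
    a = mu * scale
    b = (1 - mu) * scale
    ll = (gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
          + gammaln(y + a) + gammaln(n - y + b) - gammaln(n + a + b)
          - gammaln(a) - gammaln(b) + gammaln(a + b))
    dll_da = psi(y + a) - psi(n + a + b) - psi(a) + psi(a + b)
    dll_db = psi(n - y + b) - psi(n + a + b) - psi(b) + psi(a + b)
    # chain rule through (mu, phi) and the logit links
    d_eta_m = (dll_da - dll_db) * scale * mu * (1 - mu)
    d_eta_d = (-(dll_da * mu + dll_db * (1 - mu)) / phi) * (1 - phi)
    grad = np.concatenate([Xm.T @ d_eta_m, Xd.T @ d_eta_d])
    return -ll.sum(), -grad


def _check_design(X, name):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"{name} is rank deficient")
    return X


def fit_betabinomial(counts, totals, X_mean, X_disp,
                     taxon_id: str = "", max_iter: int = 500,
                     gtol: float = 1e-8) -> BetaBinomialFit:
    """Maximum-likelihood beta-binomial fit (BFGS from a method-of-
    moments start). Non-convergence is flagged, not raised."""
    y = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    if (y < 0).any() or (y > n).any():
        raise ValueError("need 0 <= counts <= totals")
    if y.sum() == 0:
        raise ValueError(f"taxon {taxon_id!r} has all-zero counts")
    Xm = _check_design(X_mean, "X_mean")
    Xd = _check_design(X_disp, "X_disp")

    mu0 = float(np.clip(y.sum() / n.sum(), 1e-6, 1 - 1e-6))
    theta0 = np.zeros(Xm.shape[1] + Xd.shape[1])
    theta0[0] = logit(mu0)
    theta0[Xm.shape[1]] = logit(0.05)

    res = minimize(_loglik_and_grad, theta0, args=(y, n, Xm, Xd),
                   jac=True, method="BFGS",
                   options={"gtol": gtol, "maxiter": max_iter})
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    # Newton polish when BFGS stalls on float64 precision loss
    for _ in range(10):
        if grad_norm < 1e-6:
            break
        H = _numeric_hessian(theta, y, n, Xm, Xd)
        try:
            step = np.linalg.solve(H, _loglik_and_grad(theta, y, n,
                                                       Xm, Xd)[1])
        except np.linalg.LinAlgError:
            break
        cand = theta - step
        f_cand, g_cand = _loglik_and_grad(cand, y, n, Xm, Xd)
        if not np.isfinite(f_cand) or f_cand > res.fun + 1e-6:
            break
        theta, res.fun = cand, f_cand
        grad_norm = float(np.max(np.abs(g_cand)))
    res.x = theta
    # gradient norms scale with |loglik|; 1e-3 is convergence in practice
    converged = bool(res.success or grad_norm < 1e-3)

    hess = _numeric_hessian(res.x, y, n, Xm, Xd)
    se = np.full(len(res.x), np.nan)
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        converged = False
    k = Xm.shape[1]
    return BetaBinomialFit(
        taxon_id=taxon_id,
        mean_coefficients=res.x[:k], mean_se=se[:k],
        dispersion_coefficients=res.x[k:], dispersion_se=se[k:],
        log_likelihood=float(-res.fun), converged=converged,
        n_obs=len(y), gradient_norm=grad_norm)


def _numeric_hessian(theta, y, n, Xm, Xd, eps: float = 1e-5) -> np.ndarray:
    """Observed information: central differences of the analytic
    gradient of the negative log-likelihood."""
    p = len(theta)
    H = np.empty((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = eps
        _, g_plus = _loglik_and_grad(theta + step, y, n, Xm, Xd)
        _, g_minus = _loglik_and_grad(theta - step, y, n, Xm, Xd)
        H[:, j] = (g_plus - g_minus) / (2 * eps)
    return (H + H.T) / 2


def predicted_mu_phi(fit: BetaBinomialFit, X_mean, X_disp):
    mu = expit(np.asarray(X_mean) @ fit.mean_coefficients)
    phi = expit(np.asarray(X_disp) @ fit.dispersion_coefficients)
    return mu, phi


def wald_test(fit: BetaBinomialFit, coefficient_index: int
              ) -> DifferentialResult:
    """Wald chi-square test of one mean-model coefficient."""
    if not fit.converged:
        raise ValueError(f"fit for {fit.taxon_id!r} did not converge")
    beta = float(fit.mean_coefficients[coefficient_index])
    se = float(fit.mean_se[coefficient_index])
    if beta == 0.0:
        return DifferentialResult(fit.taxon_id, "wald_abundance",
                                  0.0, 1.0, 0.0, se)
    stat = (beta / se) ** 2
    return DifferentialResult(fit.taxon_id, "wald_abundance",
                              float(stat), float(chi2.sf(stat, 1)),
                              beta, se)


def lrt_variability(fit_null: BetaBinomialFit, fit_alt: BetaBinomialFit,
                    df: int | None = None,
                    tol: float = 1e-4) -> DifferentialResult:
    """Likelihood-ratio test between nested dispersion designs."""
    if df is None:
        df = (len(fit_alt.dispersion_coefficients)
              - len(fit_null.dispersion_coefficients))
    if df < 0:
        raise ValueError("alternative must nest the null")
    stat = 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood)
    if stat < -tol * max(1.0, abs(fit_null.log_likelihood)):
        raise ValueError(
            "alternative log-likelihood below null: optimizer failure")
    stat = max(stat, 0.0)
    if df == 0:
        return DifferentialResult(fit_alt.taxon_id, "lrt_variability",
                                  0.0, 1.0, 0.0)
    effect = (float(fit_alt.dispersion_coefficients[-1])
              if len(fit_alt.dispersion_coefficients) else 0.0)
    return DifferentialResult(fit_alt.taxon_id, "lrt_variability",
                              float(stat), float(chi2.sf(stat, df)),
                              effect)


def _encode(meta: pd.DataFrame, columns) -> np.ndarray:
    """Intercept + treatment-coded categorical columns."""
    parts = [np.ones((len(meta), 1))]
    for col in columns:
        dummies = pd.get_dummies(meta[col].astype(str), prefix=col,
                                 drop_first=True)
        if dummies.shape[1]:
            parts.append(dummies.to_numpy(dtype=float))
    return np.hstack(parts)


def differential_screen(table: CountTable, metadata: SampleMetadata,
                        covariate: str,
                        controls: tuple[str, ...] = ("phase", "batch"),
                        tests: tuple[str, ...] = ("wald_abundance",
                                                  "lrt_variability"),
                        min_total: int = 10) -> pd.DataFrame:
    """Per-taxon screen: Wald on the covariate's mean coefficient and/or
    LRT on its dispersion coefficient, controls in both designs, BH
    q-values computed across converged taxa within each test."""
    meta = metadata.aligned_to(table)
    for col in (covariate, *controls):
        if col not in meta.columns:
            raise ValueError(f"column {col!r} absent from metadata")
    X_controls = _encode(meta, controls)
    X_full = np.hstack([X_controls,
                        _encode(meta, (covariate,))[:, 1:]])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design rank deficient after encoding")
    n_cov = X_full.shape[1] - X_controls.shape[1]
    totals = table.counts.sum(axis=1)

    records = []
    for j, taxon in enumerate(table.taxon_ids):
        y = table.counts[:, j]
        if y.sum() < min_total:
            continue
        try:
            fit_alt = fit_betabinomial(y, totals, X_full, X_full,
                                       taxon_id=taxon)
        except ValueError:
            continue
        if "wald_abundance" in tests:
            if fit_alt.converged:
                for c in range(n_cov):
                    res = wald_test(fit_alt,
                                    X_controls.shape[1] + c)
                    records.append(res)
            else:
                records.append(DifferentialResult(
                    taxon, "wald_abundance", np.nan, np.nan, np.nan,
                    converged=False))
        if "lrt_variability" in tests:
            try:
                fit_null = fit_betabinomial(y, totals, X_full,
                                            X_controls, taxon_id=taxon)
                res = lrt_variability(fit_null, fit_alt, df=n_cov)
                res.converged = fit_alt.converged and fit_null.converged
                records.append(res)
            except ValueError:
                records.append(DifferentialResult(
                    taxon, "lrt_variability", np.nan, np.nan, np.nan,
                    converged=False))

    df = pd.DataFrame([vars(r) for r in records])
    if df.empty:
        return df
    for test in df["test"].unique():
        mask = (df["test"] == test) & df["converged"] & df["p"].notna()
        if mask.any():
            df.loc[mask, "q"] = _bh_adjust(df.loc[mask, "p"].to_numpy())
    return df


def rank_biomarkers(results: pd.DataFrame, q_cutoff: float = 0.05
                    ) -> pd.DataFrame:
    """Significant taxa ordered by |effect|, annotated with direction.

    Effect-size ranking stand-in for LDA scoring: the covariate's
    log-odds coefficient orders candidates; its sign gives the
    increased/decreased annotation.
    """
    if results.empty:
        return results.assign(direction=pd.Series(dtype=str))
    sig = results[(results["q"] < q_cutoff) & results["converged"]].copy()
    sig["direction"] = np.where(sig["effect"] > 0, "increased", "decreased")
    return (sig.reindex(sig["effect"].abs()
                        .sort_values(ascending=False).index)
            .reset_index(drop=True))
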