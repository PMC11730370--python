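import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import betabinom

from gutdyn import diffabund as da


def _shapes(mu, phi):
    return mu * (1 - phi) / phi, (1 - mu) * (1 - phi) / phi


def _simulate(mu, phi, n_samples, depth, rng):
    a, b = _shapes(mu, phi)
    return betabinom.rvs(depth, a, b, size=n_samples,
                         random_state=rng), np.full(n_samples, depth)


class TestLikelihood:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        y, n = _simulate(0.2, 0.1, 50, 300, rng)
        Xm = np.c_[np.ones(50), rng.normal(size=50)]
        Xd = np.ones((50, 1))
        theta = np.array([-1.0, 0.3, -2.0])
        f0, g0 = da._loglik_and_grad(theta, y.astype(float),
                                     n.astype(float), Xm, Xd)
        eps = 1e-6
        for j in range(3):
            step = np.zeros(3)
            step[j] = eps
            f_plus, _ = da._loglik_and_grad(theta + step, y.astype(float),
                                            n.astype(float), Xm, Xd)
            f_minus, _ = da._loglik_and_grad(theta - step,
                                             y.astype(float),
                                             n.astype(float), Xm, Xd)
            numeric = (f_plus - f_minus) / (2 * eps)
            assert g0[j] == pytest.approx(numeric, rel=1e-4)

    def test_binomial_limit_of_likelihood(self):
        # as phi -> 0 the beta-binomial ll approaches the binomial ll
        from scipy.stats import binom
        y = np.array([3.0, 7.0, 5.0])
        n = np.array([10.0, 10.0, 10.0])
        Xm = np.ones((3, 1))
        Xd = np.ones((3, 1))
        mu = 0.5
        ll_binom = binom.logpmf(y, n, mu).sum()
        neg_ll, _ = da._loglik_and_grad(
            np.array([0.0, -18.0]), y, n, Xm, Xd)
        assert -neg_ll == pytest.approx(ll_binom, abs=1e-4)


class TestFitBetabinomial:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        mus, phis = [], []
        for _ in range(40):
            y, n = _simulate(0.1, 0.05, 200, 500, rng)
            X = np.ones((200, 1))
            fit = da.fit_betabinomial(y, n, X, X)
            mus.append(expit(fit.mean_coefficients[0]))
            phis.append(expit(fit.dispersion_coefficients[0]))
        assert abs(np.mean(mus) - 0.1) < 0.02
        assert abs(np.mean(phis) - 0.05) < 0.02

    def test_binomial_limit_mu_matches_mle(self):
        rng = np.random.default_rng(2)
        y = rng.binomial(400, 0.2, size=300).astype(float)
        n = np.full(300, 400.0)
        X = np.ones((300, 1))
        fit = da.fit_betabinomial(y, n, X, X)
        assert expit(fit.mean_coefficients[0]) == pytest.approx(
            y.sum() / n.sum(), abs=1e-4)

    def test_optimum_beats_perturbations(self):
        rng = np.random.default_rng(3)
        y, n = _simulate(0.15, 0.08, 150, 400, rng)
        X = np.ones((150, 1))
        fit = da.fit_betabinomial(y, n, X, X)
        theta_hat = np.r_[fit.mean_coefficients,
                          fit.dispersion_coefficients]
        f_hat, _ = da._loglik_and_grad(theta_hat, y.astype(float),
                                       n.astype(float), X, X)
        for _ in range(100):
            theta = theta_hat + rng.normal(scale=0.05, size=2)
            f, _ = da._loglik_and_grad(theta, y.astype(float),
                                       n.astype(float), X, X)
            assert f >= f_hat - 1e-9

    def test_all_zero_taxon_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            da.fit_betabinomial(np.zeros(10), np.full(10, 100),
                                np.ones((10, 1)), np.ones((10, 1)))

    def test_counts_exceeding_totals_error(self):
        with pytest.raises(ValueError):
            da.fit_betabinomial(np.array([5.0]), np.array([3.0]),
                                np.ones((1, 1)), np.ones((1, 1)))

    def test_rank_deficient_design(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            da.fit_betabinomial(np.ones(10), np.full(10, 10), X,
                                np.ones((10, 1)))


class TestWald:
    def test_zero_coefficient_p_one(self):
        fit = da.BetaBinomialFit(
            taxon_id="t", mean_coefficients=np.array([0.5, 0.0]),
            mean_se=np.array([0.1, 0.2]),
            dispersion_coefficients=np.array([-2.0]),
            dispersion_se=np.array([0.1]),
            log_likelihood=-10.0, converged=True)
        res = da.wald_test(fit, 1)
        assert res.p == 1.0 and res.statistic == 0.0

    def test_nonconverged_raises(self):
        fit = da.BetaBinomialFit(
            taxon_id="t", mean_coefficients=np.array([0.5]),
            mean_se=np.array([0.1]),
            dispersion_coefficients=np.array([-2.0]),
            dispersion_se=np.array([0.1]),
            log_likelihood=-10.0, converged=False)
        with pytest.raises(ValueError, match="converge"):
            da.wald_test(fit, 0)

    def test_group_effect_detected(self):
        rng = np.random.default_rng(4)
        g = np.r_[np.zeros(40), np.ones(40)]
        Xm = np.c_[np.ones(80), g]
        y0, n0 = _simulate(0.05, 0.05, 40, 800, rng)
        y1, n1 = _simulate(0.10, 0.05, 40, 800, rng)  # 2-fold effect
        y = np.r_[y0, y1]
        n = np.r_[n0, n1]
        fit = da.fit_betabinomial(y, n, Xm, Xm)
        res = da.wald_test(fit, 1)
        assert res.p < 0.01
        assert res.effect > 0


class TestLrt:
    def test_identical_designs_statistic_zero(self):
        rng = np.random.default_rng(5)
        y, n = _simulate(0.1, 0.1, 60, 500, rng)
        X = np.ones((60, 1))
        fit = da.fit_betabinomial(y, n, X, X)
        res = da.lrt_variability(fit, fit, df=0)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_group_dispersion_detected(self):
        rng = np.random.default_rng(6)
        g = np.r_[np.zeros(50), np.ones(50)]
        Xm = np.ones((100, 1))
        Xd_alt = np.c_[np.ones(100), g]
        y0, _ = _simulate(0.1, 0.02, 50, 600, rng)
        y1, _ = _simulate(0.1, 0.2, 50, 600, rng)
        y = np.r_[y0, y1]
        n = np.full(100, 600.0)
        alt = da.fit_betabinomial(y, n, Xm, Xd_alt)
        null = da.fit_betabinomial(y, n, Xm, np.ones((100, 1)))
        res = da.lrt_variability(null, alt)
        assert res.p < 0.01

    def test_nonnested_raises(self):
        fit_small = da.BetaBinomialFit(
            "t", np.zeros(1), np.zeros(1), np.zeros(1), np.zeros(1),
            -5.0, True)
        fit_big = da.BetaBinomialFit(
            "t", np.zeros(1), np.zeros(1), np.zeros(2), np.zeros(2),
            -4.0, True)
        with pytest.raises(ValueError, match="nest"):
            da.lrt_variability(fit_big, fit_small)


class TestDifferentialScreen:
    def test_missing_covariate_errors(self, small_cohort):
        table, meta = small_cohort[0], small_cohort[1]
        with pytest.raises(ValueError, match="absent"):
            da.differential_screen(table, meta, covariate="nope")

    def test_truth_biomarkers_recovered(self, small_cohort):
        table, meta, truth = (small_cohort[0], small_cohort[1],
                              small_cohort[5])
        res = da.differential_screen(table, meta, covariate="tolerance",
                                     controls=("phase",),
                                     tests=("wald_abundance",))
        sig = set(res.loc[(res["q"] < 0.05) & res["converged"],
                          "taxon_id"])
        diff_truth = set(truth["differential_taxa"])
        recovered = len(sig & diff_truth) / len(diff_truth)
        assert recovered >= 0.5

    def test_null_cohort_near_zero_discoveries(self):
        from gutdyn.synthetic_cohort import null_config, generate_cohort
        cfg = null_config(n_mice_tolerant=4, n_mice_nontolerant=3,
                          n_taxa=50, depth_mean=4_000, seed=17)
        table, meta, *_ = generate_cohort(cfg)
        res = da.differential_screen(table, meta, covariate="tolerance",
                                     controls=("phase",),
                                     tests=("wald_abundance",))
        ok = res[res["converged"] & res["q"].notna()]
        assert (ok["q"] < 0.05).mean() <= 0.05

    def test_q_monotone_in_p(self, small_cohort):
        table, meta = small_cohort[0], small_cohort[1]
        res = da.differential_screen(table, meta, covariate="tolerance",
                                     controls=("phase",),
                                     tests=("wald_abundance",))
        ok = res[res["converged"] & res["p"].notna()]
        order = ok.sort_values("p")
        assert (order["q"].diff().dropna() >= -1e-12).all()

    def test_directions_match_archetypes(self, small_cohort):
        table, meta, truth = (small_cohort[0], small_cohort[1],
                              small_cohort[5])
        res = da.differential_screen(table, meta, covariate="tolerance",
                                     controls=("phase",),
                                     tests=("wald_abundance",))
        ranked = da.rank_biomarkers(res)
        # covariate dummy is tolerance=tolerant: markers increase
        marker = ranked[ranked["taxon_id"].isin(
            truth["taxa_by_archetype"]["tolerant_marker"])]
        assert (marker["direction"] == "increased").all()
        prot = ranked[ranked["taxon_id"].isin(
            truth["taxa_by_archetype"]["nontolerant_protective"])]
        assert (prot["direction"] == "decreased").all()


class TestRankBiomarkers:
    def test_empty_input(self):
        out = da.rank_biomarkers(pd.DataFrame())
        assert out.empty

    def test_ordering_is_permutation_of_significant(self):
        res = pd.DataFrame({
            "taxon_id": list("abcd"),
            "test": ["wald_abundance"] * 4,
            "statistic": [9, 4, 1, 16],
            "p": [0.002, 0.03, 0.4, 0.001],
            "q": [0.004, 0.04, 0.4, 0.004],
            "effect": [1.0, -2.0, 0.1, 3.0],
            "se": [0.3] * 4,
            "converged": [True] * 4})
        ranked = da.rank_biomarkers(res)
        assert list(ranked["taxon_id"]) == ["d", "b", "a"]
        assert list(ranked["direction"]) == \
            ["increased", "decreased", "increased"]
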