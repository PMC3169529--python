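"""Twin mixed model: covariance construction, ML fits, LRT, Bayesian
posterior, variance decomposition, and replication-mode tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinmqtl import simulate, study, varcomp
from twinmqtl.design import CohortDesign, DesignError, VCParams
from twinmqtl.varcomp import (
    BIO_COMPONENTS, PosteriorSample, PriorSpec, VCModelSpec,
    bonferroni_threshold, build_covariance, decompose_biological,
    effect_size_no_replicates, familial_share_summary, fit_bayes, fit_ml,
    format_proportion, lrt_snp, parse_proportion, replication_test,
)


def _mini_meta(rows):
    cols = ["record_id", "subject_id", "pair_id", "zygosity", "twin_index",
            "visit", "aliquot", "plate", "time"]
    return pd.DataFrame(rows, columns=cols)


PARAMS = VCParams(sigma_f=0.6, sigma_e=0.5, sigma_vc=0.4, sigma_vi=0.3,
                  sigma_eps=0.2)


class TestBuildCovariance:
    def test_same_subject_same_visit_aliquots(self):
        meta = _mini_meta([
            ["r1", "s1", "p1", "MZ", 1, 1, 1, 1, 10],
            ["r2", "s1", "p1", "MZ", 1, 1, 2, 1, 10]])
        cov = build_covariance(meta, PARAMS)
        expect = 0.6 ** 2 + 0.5 ** 2 + 0.4 ** 2 + 0.3 ** 2
        assert cov[0, 1] == pytest.approx(expect)
        assert cov[0, 0] == pytest.approx(expect + 0.2 ** 2)

    def test_mz_cotwins_same_visit(self):
        meta = _mini_meta([
            ["r1", "s1", "p1", "MZ", 1, 1, 1, 1, 10],
            ["r2", "s2", "p1", "MZ", 2, 1, 1, 1, 10]])
        cov = build_covariance(meta, PARAMS)
        assert cov[0, 1] == pytest.approx(0.6 ** 2 + 0.4 ** 2)

    def test_dz_cotwins_familial_correlation(self):
        meta = _mini_meta([
            ["r1", "s1", "p1", "DZ", 1, 1, 1, 1, 10],
            ["r2", "s2", "p1", "DZ", 2, 2, 1, 1, 10]])
        cov = build_covariance(meta, PARAMS)
        assert cov[0, 1] == pytest.approx(0.5 * 0.6 ** 2)

    def test_unknown_zygosity_raises(self):
        meta = _mini_meta([["r1", "s1", "p1", "XX", 1, 1, 1, 1, 10]])
        with pytest.raises(DesignError):
            build_covariance(meta, PARAMS)

    def test_matches_monte_carlo_covariance(self):
        # simulation oracle: covariance of 50,000 phenotype draws from the
        # generator must match the analytic assembly within 3 SE
        design = CohortDesign(1, 1, 1, visits_per_pair=2,
                              aliquots_per_sample=2)
        meta = simulate.simulate_cohort(design, seed=1)
        assert len(meta) >= 12
        g = pd.Series(0.0, index=meta["subject_id"].unique())
        draws = np.stack([
            simulate.simulate_phenotypes(meta, g, PARAMS, seed=s).to_numpy()
            for s in range(50_000 // 10)
        ])
        # 5,000 independent cohort draws -> MC SE of covariance entries
        emp = np.cov(draws.T)
        ana = build_covariance(meta, PARAMS)
        n = draws.shape[0]
        for i in range(len(meta)):
            for j in range(len(meta)):
                se = np.sqrt((ana[i, i] * ana[j, j] + ana[i, j] ** 2) / n)
                assert emp[i, j] == pytest.approx(ana[i, j], abs=3.5 * se)


class TestLikelihood:
    def test_equals_bruteforce_mvn_density(self):
        # <= 15 records: blockwise likelihood vs a directly assembled
        # multivariate-normal log-density
        design = CohortDesign(2, 1, 1, visits_per_pair=1,
                              aliquots_per_sample=2)
        meta = simulate.simulate_cohort(design, seed=2)
        assert len(meta) <= 15
        rng = np.random.default_rng(3)
        g = pd.Series(rng.integers(0, 3, meta["subject_id"].nunique()),
                      index=meta["subject_id"].unique(), dtype=float)
        spec = VCModelSpec(meta, g, components=("f", "e", "eps"))
        X, _ = spec.design_matrix()
        y = rng.normal(size=len(meta))
        beta = rng.normal(size=X.shape[1])
        sds = np.array([0.7, 0.5, 0.0, 0.0, 0.4])
        lik = varcomp._Likelihood(y, X, spec)
        got = lik.loglik_resid(sds, y - X @ beta)
        params = VCParams(sigma_f=0.7, sigma_e=0.5, sigma_eps=0.4)
        cov = build_covariance(meta, params)
        want = stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=cov)
        assert got == pytest.approx(want, abs=1e-8)


class TestFitML:
    def test_boundary_components_shrink_to_zero(self):
        # generate with sigma_f = sigma_vc = sigma_vi = 0: their estimates
        # hit the boundary while sigma_e and sigma_eps recover truth
        design = CohortDesign(100, 100, 0, visits_per_pair=2,
                              aliquots_per_sample=2)
        meta = simulate.simulate_cohort(design, seed=4)
        g = pd.Series(0.0, index=meta["subject_id"].unique())
        truth = VCParams(sigma_e=0.8, sigma_eps=0.4)
        y = simulate.simulate_phenotypes(meta, g, truth, seed=5)
        spec = VCModelSpec(meta, None, include_time=False)
        fit = fit_ml(y.to_numpy(), spec)
        assert fit.sds["vc"] < 0.1
        assert fit.sds["vi"] < 0.1
        assert fit.sds["e"] == pytest.approx(0.8, abs=0.1)
        assert fit.sds["eps"] == pytest.approx(0.4, abs=0.05)

    def test_single_record_per_subject_unidentifiable(self):
        design = CohortDesign(5, 5, 0, visits_per_pair=1,
                              aliquots_per_sample=1)
        meta = simulate.simulate_cohort(design, seed=6)
        with pytest.raises(DesignError, match="unidentifiable"):
            VCModelSpec(meta, None)

    def test_optimum_dominates_truth(self, small_cohort, small_genotypes,
                                     vc_truth):
        g = small_genotypes.dosages.iloc[:, 0]
        spec = VCModelSpec(small_cohort, g)
        X, _ = spec.design_matrix()
        for seed in range(3):
            y = simulate.simulate_phenotypes(small_cohort, g, vc_truth,
                                             seed=seed)
            fit = fit_ml(y.to_numpy(), spec)
            lik = varcomp._Likelihood(y.to_numpy(), X, spec)
            ll_truth, _ = lik.profile_loglik(vc_truth.sds())
            assert fit.loglik >= ll_truth - 1e-6


class TestLRT:
    def test_zero_statistic_gives_p_one(self, small_cohort):
        # orthogonalized dosage: beta_g MLE ~ 0, LR statistic ~ 0, p ~ 1
        rng = np.random.default_rng(7)
        subs = small_cohort["subject_id"].unique()
        g = pd.Series(rng.integers(0, 3, len(subs)), index=subs,
                      dtype=float)
        y = simulate.simulate_phenotypes(
            small_cohort, pd.Series(0.0, index=subs),
            VCParams(sigma_e=0.5, sigma_eps=0.5), seed=8)
        spec = VCModelSpec(small_cohort, g, components=("e", "vi", "eps"))
        _, _, p, full, null = lrt_snp(y.to_numpy(), spec)
        assert 2 * (full.loglik - null.loglik) >= -1e-6
        assert p > 0.01  # null data: no signal

    def test_power_at_large_effect(self):
        # beta_g sized for rho^2 ~ 0.5: LRT p far below 1e-6
        design = CohortDesign(50, 20, 0, visits_per_pair=2,
                              aliquots_per_sample=2)
        var_g = 2 * 0.3 * 0.7
        truth = VCParams(beta_g=np.sqrt(1.0 / var_g), sigma_e=0.5,
                         sigma_f=0.5, sigma_vc=0.3, sigma_vi=0.3,
                         sigma_eps=0.3)
        pvals = []
        for rep in range(10):
            meta = simulate.simulate_cohort(design, seed=20 + rep)
            gm = simulate.simulate_genotypes(meta, 1, maf=0.3, seed=40 + rep)
            g = gm.dosages.iloc[:, 0]
            y = simulate.simulate_phenotypes(meta, g, truth, seed=60 + rep)
            spec = VCModelSpec(meta, g)
            _, _, p, _, _ = lrt_snp(y.to_numpy(), spec)
            pvals.append(p)
        assert np.median(pvals) < 1e-6


class TestBayes:
    def test_prior_only_recovers_uniform_sds(self, small_cohort):
        y = np.random.default_rng(9).normal(size=len(small_cohort))
        spec = VCModelSpec(small_cohort, None)
        priors = PriorSpec(k=10.0)
        post = fit_bayes(y, spec, priors=priors, chains=1, iterations=4000,
                         seed=10, prior_only=True)
        s_y = np.std(y, ddof=1)
        u = post.sds["f"].to_numpy() / (10.0 * s_y)
        d, p = stats.kstest(u, "uniform")
        assert p > 0.001

    def test_posterior_close_to_ml_on_large_design(self, vc_truth):
        # Bernstein-von-Mises-style check: with plenty of data the posterior
        # concentrates near the ML estimates
        design = CohortDesign(70, 30, 0, visits_per_pair=2,
                              aliquots_per_sample=2)
        meta = simulate.simulate_cohort(design, seed=11)
        gm = simulate.simulate_genotypes(meta, 1, maf=0.3, seed=12)
        g = gm.dosages.iloc[:, 0]
        y = simulate.simulate_phenotypes(meta, g, vc_truth, seed=13)
        spec = VCModelSpec(meta, g)
        ml = fit_ml(y.to_numpy(), spec)
        post = fit_bayes(y.to_numpy(), spec, chains=2, iterations=1500,
                         seed=14)
        assert post.beta["beta_g"].mean() == pytest.approx(
            ml.beta["beta_g"], abs=2 * post.beta["beta_g"].std())
        for c in ("f", "e", "eps"):
            spread = max(post.sds[c].std(), 0.02)
            assert post.sds[c].mean() == pytest.approx(
                ml.sds[c], abs=3 * spread)

    def test_reproducible_given_seed(self, small_cohort, small_genotypes,
                                     vc_truth):
        g = small_genotypes.dosages.iloc[:, 0]
        y = simulate.simulate_phenotypes(small_cohort, g, vc_truth, seed=15)
        spec = VCModelSpec(small_cohort, g)
        a = fit_bayes(y.to_numpy(), spec, chains=1, iterations=200, seed=16)
        b = fit_bayes(y.to_numpy(), spec, chains=1, iterations=200, seed=16)
        pd.testing.assert_frame_equal(a.sds, b.sds)


class TestDecomposition:
    def _posterior(self, beta_g, f, e, vi, vc, n=100):
        beta = pd.DataFrame({"intercept": np.zeros(n),
                             "beta_g": np.full(n, beta_g)})
        sds = pd.DataFrame({
            "f": np.full(n, f), "e": np.full(n, e), "vc": np.full(n, vc),
            "vi": np.full(n, vi), "eps": np.full(n, 0.3)})
        return PosteriorSample(beta, sds, pd.Series(dtype=float),
                               pd.Series(dtype=float), True)

    def test_degenerate_familial_only(self):
        post = self._posterior(beta_g=0.0, f=0.7, e=0.0, vi=0.0, vc=0.0)
        dec = decompose_biological(post, np.array([0, 1, 2, 1, 0]))
        assert dec.summary.loc["familial", "mean"] == pytest.approx(1.0)
        for c in ("snp", "indiv_env", "indiv_visit", "common_visit"):
            assert dec.summary.loc[c, "mean"] == pytest.approx(0.0)

    def test_proportions_sum_to_one_per_draw(self):
        rng = np.random.default_rng(17)
        beta = pd.DataFrame({"beta_g": rng.normal(size=200)})
        sds = pd.DataFrame(
            {c: np.abs(rng.normal(size=200))
             for c in ("f", "e", "vc", "vi", "eps")})
        post = PosteriorSample(beta, sds, pd.Series(dtype=float),
                               pd.Series(dtype=float), True)
        dec = decompose_biological(post, rng.integers(0, 3, 50))
        np.testing.assert_allclose(dec.draws.sum(axis=1), 1.0)

    def test_format_contract(self):
        assert format_proportion(0.64, 0.55, 0.72) == "64% (55–72)"
        assert parse_proportion("64% (55–72)") == (64, 55, 72)

    def test_experimental_variance_excluded_from_denominator(self):
        post = self._posterior(beta_g=1.0, f=1.0, e=0.0, vi=0.0, vc=0.0)
        g = np.array([0.0, 2.0] * 10)  # var ~ 1.05 (ddof=1)
        dec = decompose_biological(post, g)
        var_g = np.var(g, ddof=1)
        expect_snp = var_g / (var_g + 1.0)
        assert dec.summary.loc["snp", "mean"] == pytest.approx(expect_snp)


class TestFamilialShare:
    def test_single_row(self):
        t = pd.DataFrame({"snp_pct": [50.0], "familial_pct": [50.0]})
        out = familial_share_summary(t)
        assert out["mean_snp_share_pct"] == pytest.approx(50.0)
        assert out["snp_share_range_pct"] == (50.0, 50.0)

    def test_zero_total_rejected(self):
        t = pd.DataFrame({"snp_pct": [0.0], "familial_pct": [0.0]})
        with pytest.raises(DesignError):
            familial_share_summary(t)

    def test_reference_table_means(self):
        rows = study.replicated_biocrates_rows()
        out = familial_share_summary(rows)
        assert out["n"] == 13
        assert round(out["mean_snp_share_pct"]) == 25
        assert round(out["mean_familial_pct"]) == 44


class TestReplication:
    def test_bonferroni_thresholds(self):
        assert bonferroni_threshold(0.05, 4) == pytest.approx(0.0125)
        assert bonferroni_threshold(0.05, 15) == pytest.approx(0.0033,
                                                               abs=5e-5)

    def test_null_pvalues_uniform_with_covariates(self):
        rng = np.random.default_rng(18)
        n = 100
        pvals = []
        for _ in range(500):
            age = rng.uniform(45, 76, n)
            sex = rng.integers(0, 2, n).astype(float)
            g = rng.binomial(2, 0.3, n).astype(float)
            y = 0.02 * age + 0.5 * sex + rng.normal(size=n)
            _, _, p = replication_test(y, g, pd.DataFrame({"age": age,
                                                           "sex": sex}))
            pvals.append(p)
        d, p_ks = stats.kstest(pvals, "uniform")
        assert p_ks > 0.01

    def test_collinear_covariates_rejected(self):
        n = 30
        g = np.arange(n, dtype=float) % 3
        cov = pd.DataFrame({"a": np.ones(n)})
        with pytest.raises(DesignError):
            replication_test(np.random.default_rng(19).normal(size=n), g,
                             cov)


class TestEffectSize:
    def test_noiseless_identity(self):
        g = np.array([0.0, 1.0, 2.0] * 20)
        rho2_total, rho2_bio = effect_size_no_replicates(g, g)
        assert rho2_total == pytest.approx(1.0)
        assert rho2_bio == pytest.approx(1.0)

    def test_zero_experimental_fraction_is_identity(self):
        rng = np.random.default_rng(20)
        g = rng.binomial(2, 0.3, 200).astype(float)
        y = 0.5 * g + rng.normal(size=200)
        t, b = effect_size_no_replicates(y, g, experimental_fraction=0.0)
        assert t == b

    def test_rescaling_by_experimental_fraction(self):
        rng = np.random.default_rng(21)
        g = rng.binomial(2, 0.3, 200).astype(float)
        y = 0.5 * g + rng.normal(size=200)
        t, b = effect_size_no_replicates(y, g, experimental_fraction=0.2)
        assert b == pytest.approx(t / 0.8)

    def test_unbiased_at_large_n(self):
        # simulation at known rho^2 = 0.2
        rng = np.random.default_rng(22)
        n = 5000
        var_g = 2 * 0.3 * 0.7
        beta = np.sqrt(0.2 / 0.8 / var_g)
        ests = []
        for _ in range(20):
            g = rng.binomial(2, 0.3, n).astype(float)
            y = beta * g + rng.normal(size=n)
            t, _ = effect_size_no_replicates(y, g)
            ests.append(t)
        assert np.mean(ests) == pytest.approx(0.2, abs=0.01)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(DesignError):
            effect_size_no_replicates(np.zeros(10), np.zeros(10),
                                      experimental_fraction=1.0)
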