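"""Twin mixed-effects models for mQTL hit regions.

The phenotype of aliquot l, visit k, twin j in pair i is modelled as

    y_ijkl = beta0 + beta_g * g_ij + plate_{p(ijkl)} + beta_time * t_ik
             + f_ij + e_ij + v_ik + w_ijk + eps_ijkl

with independent zero-mean Gaussian random effects: familial f (correlation
1 between MZ co-twins, rho_DZ — default 1/2 — between DZ co-twins),
individual-environment e, common-visit v (shared by co-twins at a visit,
since twins attend together), individual-visit w, and experimental eps (per
aliquot).  This induces the classical twin-model covariance structure,
extended for longitudinal visits and technical replication.

The model is fitted by maximum likelihood (profiled fixed effects, log-SD
parameterization) for likelihood-ratio SNP tests, and by MCMC
(Metropolis-within-Gibbs: Gaussian conjugate updates for fixed effects,
adaptive random-walk updates for the standard deviations under uniform
priors) for posterior variance decompositions.  Biological variance is
defined as beta_g^2 * Var(g) + sigma_f^2 + sigma_e^2 + sigma_vc^2 +
sigma_vi^2 — experimental variance is excluded — and each component is
reported as a posterior proportion of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DesignError, VCParams

COMPONENTS = ("f", "e", "vc", "vi", "eps")
_LOG2PI = float(np.log(2.0 * np.pi))


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def _block_kernels(block: pd.DataFrame, dz_corr: float) -> np.ndarray:
    """The five m×m structure matrices K such that the block covariance is
    sum_c sigma_c^2 * K_c, ordered as COMPONENTS."""
    m = len(block)
    zyg = block["zygosity"].iloc[0]
    if zyg not in ("MZ", "DZ", "NA"):
        raise DesignError(f"unknown zygosity {zyg!r}")
    subj = block["subject_id"].to_numpy()
    visit = block["visit"].to_numpy()
    same_subj = subj[:, None] == subj[None, :]
    same_visit = visit[:, None] == visit[None, :]
    if zyg == "MZ":
        kf = np.ones((m, m))
    elif zyg == "DZ":
        kf = np.where(same_subj, 1.0, dz_corr)
    else:
        kf = same_subj.astype(float)
    ke = same_subj.astype(float)
    kvc = same_visit.astype(float)          # within a pair block
    kvi = (same_subj & same_visit).astype(float)
    keps = np.eye(m)
    return np.stack([kf, ke, kvc, kvi, keps])


def build_covariance(meta: pd.DataFrame, params: VCParams) -> np.ndarray:
    """Record-level covariance matrix implied by the variance components,
    in the row order of ``meta``."""
    meta = meta.reset_index(drop=True)
    n = len(meta)
    cov = np.zeros((n, n))
    sds2 = params.sds() ** 2
    for _, block in meta.groupby("pair_id", sort=False):
        pos = block.index.to_numpy()
        K = _block_kernels(block, params.dz_familial_corr)
        cov[np.ix_(pos, pos)] = np.tensordot(sds2, K, axes=1)
    return cov


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class VCModelSpec:
    """Design matrices and block structure for the twin mixed model.

    ``dosage`` maps subject_id -> SNP dosage (omit for the null model).
    ``covariates`` is an optional per-record DataFrame (e.g. age, sex) for
    replication-mode fits.  ``components`` restricts which random effects are
    estimated; unlisted SDs are fixed at zero.
    """

    meta: pd.DataFrame
    dosage: Mapping[str, float] | pd.Series | None = None
    include_plate: bool = True
    include_time: bool = True
    covariates: pd.DataFrame | None = None
    components: Sequence[str] = COMPONENTS
    dz_familial_corr: float = 0.5

    def __post_init__(self) -> None:
        bad = set(self.components) - set(COMPONENTS)
        if bad:
            raise DesignError(f"unknown components {sorted(bad)}")
        self.meta = self.meta.reset_index(drop=True)
        self._check_identifiable()

    # -- fixed-effect design ---------------------------------------------
    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        m = self.meta
        cols = [np.ones(len(m))]
        names = ["intercept"]
        if self.dosage is not None:
            g = pd.Series(self.dosage)
            missing = set(m["subject_id"]) - set(g.index)
            if missing:
                raise DesignError(f"missing dosage for {sorted(missing)[:5]}")
            cols.append(g.loc[m["subject_id"]].to_numpy(dtype=float))
            names.append("beta_g")
        if self.include_plate:
            plates = sorted(m["plate"].unique())
            for p in plates[1:]:            # reference-level coding
                cols.append((m["plate"] == p).to_numpy(dtype=float))
                names.append(f"plate_{p}")
        if self.include_time and m["time"].nunique() > 1:
            cols.append(m["time"].to_numpy(dtype=float))
            names.append("beta_time")
        if self.covariates is not None:
            for c in self.covariates.columns:
                cols.append(self.covariates[c].to_numpy(dtype=float))
                names.append(str(c))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("fixed-effect design matrix is rank deficient")
        return X, names

    def without_snp(self) -> "VCModelSpec":
        return VCModelSpec(self.meta, None, self.include_plate,
                           self.include_time, self.covariates,
                           self.components, self.dz_familial_corr)

    # -- identifiability ---------------------------------------------------
    def _check_identifiable(self) -> None:
        m = self.meta
        comp = set(self.components)
        problems = []
        multi_aliquot = (m.groupby(["subject_id", "visit"]).size() > 1).any()
        multi_visit = (m.groupby("subject_id")["visit"].nunique() > 1).any()
        has_pairs = (m.groupby("pair_id")["subject_id"].nunique() > 1).any()
        if {"eps", "vi"} <= comp and not multi_aliquot:
            problems.append("eps/vi (no replicated aliquots)")
        if {"e", "vi"} <= comp and not multi_visit:
            problems.append("e/vi (no repeated visits)")
        if {"f", "vc"} <= comp and not (has_pairs and multi_visit):
            problems.append("f/vc (no longitudinal pair structure)")
        if {"f", "e"} <= comp and not has_pairs:
            problems.append("f/e (no twin pairs)")
        if problems:
            raise DesignError(
                "unidentifiable variance components: " + "; ".join(problems))

    # -- block structure ---------------------------------------------------
    def blocks(self) -> list[dict]:
        """Pattern-grouped pair blocks for fast batched likelihoods."""
        groups: dict[tuple, dict] = {}
        for _, block in self.meta.groupby("pair_id", sort=False):
            tw = block["twin_index"].to_numpy()
            key = (block["zygosity"].iloc[0],
                   tuple(zip(tw - tw.min(), block["visit"], block["aliquot"])))
            entry = groups.setdefault(key, {"positions": [], "K": None})
            if entry["K"] is None:
                entry["K"] = _block_kernels(block, self.dz_familial_corr)
            entry["positions"].append(block.index.to_numpy())
        return list(groups.values())


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

class _Likelihood:
    """Blockwise Gaussian likelihood with pattern batching."""

    def __init__(self, y: np.ndarray, X: np.ndarray, spec: VCModelSpec):
        self.y = np.asarray(y, dtype=float)
        self.X = X
        self.n = self.y.size
        self.groups = []
        for g in spec.blocks():
            pos = np.stack(g["positions"])       # (k, m)
            self.groups.append({"pos": pos, "K": g["K"]})
        self.active = np.array([c in spec.components for c in COMPONENTS])

    def _factorize(self, sds: np.ndarray) -> list[tuple]:
        sds2 = sds ** 2
        out = []
        for g in self.groups:
            sigma = np.tensordot(sds2, g["K"], axes=1)
            sigma = sigma + np.eye(sigma.shape[0]) * 1e-12 * max(sds2.max(), 1.0)
            try:
                L = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError as exc:
                raise FitError("covariance not positive definite") from exc
            out.append((g["pos"], L))
        return out

    def loglik_resid(self, sds: np.ndarray, resid: np.ndarray) -> float:
        ll = -0.5 * self.n * _LOG2PI
        for pos, L in self._factorize(sds):
            R = resid[pos]                       # (k, m)
            W = _tri_solve(L, R.T)               # (m, k)
            ll -= pos.shape[0] * np.log(np.diag(L)).sum()
            ll -= 0.5 * float((W ** 2).sum())
        return ll

    def normal_equations(self, sds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """X' Sigma^-1 X and X' Sigma^-1 y, batched over pattern groups."""
        p = self.X.shape[1]
        XtSiX = np.zeros((p, p))
        XtSiy = np.zeros(p)
        for pos, L in self._factorize(sds):
            k, m = pos.shape
            Xp = self.X[pos]                    # (k, m, p)
            Wx = _tri_solve(L, Xp.transpose(1, 0, 2).reshape(m, k * p)
                            ).reshape(m, k, p)
            Wy = _tri_solve(L, self.y[pos].T)   # (m, k)
            XtSiX += np.einsum("mkp,mkq->pq", Wx, Wx)
            XtSiy += np.einsum("mkp,mk->p", Wx, Wy)
        return XtSiX, XtSiy

    def gls(self, sds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """GLS fixed-effect estimates and their covariance at given SDs."""
        XtSiX, XtSiy = self.normal_equations(sds)
        beta = np.linalg.solve(XtSiX, XtSiy)
        return beta, np.linalg.inv(XtSiX)

    def profile_loglik(self, sds: np.ndarray) -> tuple[float, np.ndarray]:
        beta, _ = self.gls(sds)
        resid = self.y - self.X @ beta
        return self.loglik_resid(sds, resid), beta


def _tri_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular
    return solve_triangular(L, b, lower=True, check_finite=False)


# ---------------------------------------------------------------------------
# maximum likelihood and LRT
# ---------------------------------------------------------------------------

@dataclass
class VCFit:
    beta: pd.Series
    beta_cov: np.ndarray
    sds: pd.Series
    loglik: float
    converged: bool
    n_restarts: int = 0

    def se(self, name: str) -> float:
        i = list(self.beta.index).index(name)
        return float(np.sqrt(self.beta_cov[i, i]))


_Z_FLOOR = -15.0   # sigma = s_y * exp(-15) ~ numerically zero


def fit_ml(y: pd.Series | np.ndarray, spec: VCModelSpec,
           n_starts: int = 3, seed: int = 0) -> VCFit:
    """Maximum-likelihood fit over fixed effects and non-negative SDs.

    SDs are parameterized as sigma_c = s_y * exp(z_c) with z bounded below
    (boundary estimates come back as ~0); fixed effects are profiled out by
    GLS inside the objective.  Deterministic given starts; extra random
    starts are tried on poor convergence.
    """
    yv = y.to_numpy(dtype=float) if isinstance(y, pd.Series) else np.asarray(y, float)
    X, names = spec.design_matrix()
    lik = _Likelihood(yv, X, spec)
    s_y = float(np.std(yv, ddof=1))
    if s_y == 0:
        raise FitError("phenotype is constant")
    active = lik.active
    k = int(active.sum())

    def sds_from_z(z: np.ndarray) -> np.ndarray:
        sds = np.zeros(len(COMPONENTS))
        sds[active] = s_y * np.exp(z)
        return sds

    def objective(z: np.ndarray) -> float:
        try:
            ll, _ = lik.profile_loglik(sds_from_z(z))
        except FitError:
            return 1e12
        return -ll

    rng = np.random.default_rng(seed)
    starts = [np.full(k, np.log(0.4))]
    for _ in range(n_starts - 1):
        starts.append(rng.uniform(-3.0, 0.5, size=k))
    best = None
    n_tried = 0
    for z0 in starts:
        res = optimize.minimize(objective, z0, method="L-BFGS-B",
                                bounds=[(_Z_FLOOR, 4.0)] * k,
                                options={"maxiter": 500})
        n_tried += 1
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success:
            break  # further starts only on convergence failure
    if best is None or not np.isfinite(best.fun):
        raise FitError("ML optimization failed to converge after "
                       f"{n_tried} starts")
    sds = sds_from_z(best.x)
    ll, beta = lik.profile_loglik(sds)
    _, beta_cov = lik.gls(sds)
    full_sds = pd.Series(sds, index=list(COMPONENTS))
    return VCFit(pd.Series(beta, index=names), beta_cov, full_sds,
                 float(ll), bool(best.success), n_tried - 1)


def lrt_snp(y: pd.Series | np.ndarray, spec: VCModelSpec,
            seed: int = 0) -> tuple[float, float, float, VCFit, VCFit]:
    """Likelihood-ratio test of the SNP effect.

    Fits the model with and without the dosage term; the statistic
    2 (l_full - l_null) is referred to chi-square with 1 df.  Returns
    (beta_g, SE, p, full fit, null fit).
    """
    if spec.dosage is None:
        raise DesignError("lrt_snp requires a spec with a dosage term")
    full = fit_ml(y, spec, seed=seed)
    null = fit_ml(y, spec.without_snp(), seed=seed)
    stat = 2.0 * (full.loglik - null.loglik)
    if stat < -1e-6:
        full = fit_ml(y, spec, n_starts=6, seed=seed + 1)
        stat = 2.0 * (full.loglik - null.loglik)
        if stat < -1e-6:
            raise FitError("full-model likelihood below null beyond tolerance")
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return float(full.beta["beta_g"]), full.se("beta_g"), p, full, null


# ---------------------------------------------------------------------------
# Bayesian fit
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Uniform(0, k * s_y) priors on each SD; Gaussian prior on the fixed
    effects centred at their least-squares estimates with variance
    v * s_y^2 per coefficient."""

    k: float = 100.0
    v: float = 1e6

    def __post_init__(self) -> None:
        if self.k <= 0 or self.v <= 0:
            raise DesignError("prior multipliers must be positive")


@dataclass
class PosteriorSample:
    beta: pd.DataFrame      # draws × fixed effects
    sds: pd.DataFrame       # draws × components
    accept_rate: pd.Series
    rhat: pd.Series
    converged: bool


def fit_bayes(y: pd.Series | np.ndarray, spec: VCModelSpec,
              priors: PriorSpec | None = None, chains: int = 2,
              iterations: int = 4000, burn_in: int | None = None,
              seed: int = 0, prior_only: bool = False) -> PosteriorSample:
    """MCMC over fixed effects and SDs.

    Fixed effects get exact Gaussian (conjugate) Gibbs updates given the
    covariance; each SD gets an adaptive random-walk Metropolis update under
    its Uniform(0, k*s_y) prior, with the marginal (random effects
    integrated out) blockwise likelihood.  ``prior_only`` disables the
    likelihood, so the sampler should recover the priors.  Split-chain
    R-hat on the SDs is reported; values above 1.05 emit a warning.
    """
    priors = priors or PriorSpec()
    yv = y.to_numpy(dtype=float) if isinstance(y, pd.Series) else np.asarray(y, float)
    X, names = spec.design_matrix()
    lik = _Likelihood(yv, X, spec)
    s_y = float(np.std(yv, ddof=1))
    upper = priors.k * s_y
    active = lik.active
    p = X.shape[1]
    beta_ls, *_ = np.linalg.lstsq(X, yv, rcond=None)
    prior_prec = np.eye(p) / (priors.v * s_y ** 2)
    if burn_in is None:
        burn_in = iterations // 4

    all_beta, all_sds, acc_rates = [], [], []
    for chain in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        beta = beta_ls.copy()
        sds = np.zeros(len(COMPONENTS))
        sds[active] = 0.5 * s_y
        steps = np.full(len(COMPONENTS), 0.2 * s_y)
        resid = yv - X @ beta
        cur_ll = 0.0 if prior_only else lik.loglik_resid(sds, resid)
        n_acc = np.zeros(len(COMPONENTS))
        n_try = np.zeros(len(COMPONENTS))
        bdraws = np.empty((iterations, p))
        sdraws = np.empty((iterations, len(COMPONENTS)))
        for it in range(burn_in + iterations):
            # --- Gibbs update of fixed effects -------------------------
            if prior_only:
                beta = beta_ls + rng.normal(size=p) * np.sqrt(priors.v) * s_y
            else:
                XtSiX, XtSiy = lik.normal_equations(sds)
                prec = XtSiX + prior_prec
                cov = np.linalg.inv(prec)
                cov = 0.5 * (cov + cov.T)
                mean = cov @ (XtSiy + prior_prec @ beta_ls)
                beta = rng.multivariate_normal(mean, cov, method="cholesky")
                resid = yv - X @ beta
                cur_ll = lik.loglik_resid(sds, resid)
            # --- Metropolis updates of SDs -----------------------------
            for c in np.flatnonzero(active):
                prop = sds.copy()
                prop[c] = sds[c] + rng.normal(0.0, steps[c])
                n_try[c] += 1
                if prop[c] < 0.0 or prop[c] > upper:
                    continue
                new_ll = 0.0 if prior_only else lik.loglik_resid(prop, resid)
                if np.log(rng.random()) < new_ll - cur_ll:
                    sds, cur_ll = prop, new_ll
                    n_acc[c] += 1
            if it < burn_in:
                if (it + 1) % 50 == 0:       # adapt toward ~44% acceptance
                    rate = np.divide(n_acc, np.maximum(n_try, 1))
                    steps *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
                    n_acc[:] = 0
                    n_try[:] = 0
            else:
                bdraws[it - burn_in] = beta
                sdraws[it - burn_in] = sds
        all_beta.append(bdraws)
        all_sds.append(sdraws)
        acc_rates.append(np.divide(n_acc, np.maximum(n_try, 1)))

    beta_df = pd.DataFrame(np.concatenate(all_beta), columns=names)
    sds_df = pd.DataFrame(np.concatenate(all_sds), columns=list(COMPONENTS))
    rhat = pd.Series({c: _split_rhat([s[:, i] for s in all_sds])
                      for i, c in enumerate(COMPONENTS) if active[i]})
    converged = bool((rhat.dropna() < 1.05).all())
    if not converged:
        warnings.warn(f"MCMC convergence suspect: max R-hat = "
                      f"{rhat.max():.3f}", stacklevel=2)
    return PosteriorSample(beta_df, sds_df,
                           pd.Series(np.mean(acc_rates, axis=0),
                                     index=list(COMPONENTS)),
                           rhat, converged)


def _split_rhat(chains: list[np.ndarray]) -> float:
    """Potential scale reduction factor on split chains."""
    halves = []
    for c in chains:
        h = len(c) // 2
        halves.extend([c[:h], c[h:2 * h]])
    m = len(halves)
    n = len(halves[0])
    if n < 2:
        return float("nan")
    means = np.array([h.mean() for h in halves])
    vars_ = np.array([h.var(ddof=1) for h in halves])
    W = vars_.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return float("nan")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------

BIO_COMPONENTS = ("snp", "familial", "indiv_env", "indiv_visit", "common_visit")


@dataclass
class VCDecomposition:
    """Posterior proportions of biological variance.

    ``draws`` has one row per retained posterior draw and one column per
    biological component; rows are non-negative and sum to one.  ``summary``
    gives mean, quartiles and the central 95% interval per component.
    """

    draws: pd.DataFrame
    summary: pd.DataFrame
    n_excluded: int = 0

    def format_row(self, component: str) -> str:
        s = self.summary.loc[component]
        return format_proportion(s["mean"], s["q2.5"], s["q97.5"])


def format_proportion(mean: float, lo: float, hi: float) -> str:
    """Render a proportion with its 95% interval, e.g. 0.64 (0.55, 0.72) ->
    '64% (55-72)'."""
    return (f"{round(mean * 100):.0f}% "
            f"({round(lo * 100):.0f}–{round(hi * 100):.0f})")


def parse_proportion(text: str) -> tuple[int, int, int]:
    """Inverse of :func:`format_proportion` on the integer-percent scale."""
    head, rest = text.split("% (")
    lo, hi = rest.rstrip(")").split("–")
    return int(head), int(lo), int(hi)


def decompose_biological(posterior: PosteriorSample,
                         dosages: pd.Series | np.ndarray) -> VCDecomposition:
    """Per-draw decomposition of biological variance.

    sigma2_SNP = beta_g^2 * Var(g) with Var(g) the empirical (sample)
    dosage variance across subjects; the biological total adds the familial,
    individual-environment, individual-visit and common-visit variances —
    not the experimental one.  Draws with zero biological variance are
    excluded and counted.
    """
    if "beta_g" not in posterior.beta.columns:
        raise DesignError("posterior lacks a beta_g (SNP) term")
    g = np.asarray(dosages, dtype=float)
    var_g = float(np.var(g, ddof=1))
    s2_snp = posterior.beta["beta_g"].to_numpy() ** 2 * var_g
    sd = posterior.sds
    comps = np.column_stack([
        s2_snp,
        sd["f"].to_numpy() ** 2,
        sd["e"].to_numpy() ** 2,
        sd["vi"].to_numpy() ** 2,
        sd["vc"].to_numpy() ** 2,
    ])
    total = comps.sum(axis=1)
    keep = total > 0
    props = comps[keep] / total[keep, None]
    draws = pd.DataFrame(props, columns=list(BIO_COMPONENTS))
    summary = pd.DataFrame({
        "mean": draws.mean(),
        "q25": draws.quantile(0.25),
        "median": draws.quantile(0.50),
        "q75": draws.quantile(0.75),
        "q2.5": draws.quantile(0.025),
        "q97.5": draws.quantile(0.975),
    })
    return VCDecomposition(draws, summary, int((~keep).sum()))


def familial_share_summary(table: pd.DataFrame,
                           subset: Sequence | None = None) -> dict:
    """Mean and range of the SNP's share of total familial variation, and of
    the non-SNP familial percentage, across decomposition rows.

    ``table`` needs columns ``snp_pct`` and ``familial_pct`` (percent scale);
    a row's share is snp / (snp + familial), i.e. the fraction of total
    familial variation — mQTL plus residual familial — explained by the SNP.
    """
    t = table if subset is None else table.loc[list(subset)]
    if len(t) == 0:
        raise DesignError("empty subset")
    tot = t["snp_pct"] + t["familial_pct"]
    if (tot == 0).any():
        raise DesignError("row with zero SNP + familial variance")
    share = 100.0 * t["snp_pct"] / tot
    return {
        "mean_snp_share_pct": float(share.mean()),
        "snp_share_range_pct": (float(share.min()), float(share.max())),
        "mean_familial_pct": float(t["familial_pct"].mean()),
        "familial_range_pct": (float(t["familial_pct"].min()),
                               float(t["familial_pct"].max())),
        "n": int(len(t)),
    }


# ---------------------------------------------------------------------------
# replication-mode tests and effect sizes
# ---------------------------------------------------------------------------

def replication_test(y: pd.Series | np.ndarray, g: np.ndarray,
                     covariates: pd.DataFrame | None = None
                     ) -> tuple[float, float, float]:
    """Covariate-adjusted OLS replication test.

    Regresses the (inverse-normal) phenotype on dosage plus covariates
    (age, sex, ...) and returns (beta, SE, two-sided p) for the dosage slope.
    """
    import statsmodels.api as sm
    yv = np.asarray(y, dtype=float)
    cols = {"const": np.ones(yv.size), "g": np.asarray(g, dtype=float)}
    if covariates is not None:
        for c in covariates.columns:
            cols[str(c)] = covariates[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("collinear covariates in replication model")
    fit = sm.OLS(yv, X).fit()
    return float(fit.params["g"]), float(fit.bse["g"]), float(fit.pvalues["g"])


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test level controlling the family-wise error at ``alpha`` over
    ``m`` tests: alpha / m."""
    if m < 1:
        raise DesignError("m must be >= 1")
    return alpha / m


def effect_size_no_replicates(y: np.ndarray, g: np.ndarray,
                              covariates: pd.DataFrame | None = None,
                              experimental_fraction: float = 0.0
                              ) -> tuple[float, float]:
    """Effect size for a cohort without technical replication.

    Fits OLS of y on dosage (plus covariates), estimates the proportion of
    *total* variance explained by the SNP as Var(beta_hat * g) / Var(y),
    then rescales to a proportion of *biological* variance by dividing by
    (1 - experimental_fraction).  Returns (rho2_total, rho2_biological).
    """
    if not 0.0 <= experimental_fraction < 1.0:
        raise DesignError("experimental_fraction must lie in [0, 1)")
    beta, _, _ = replication_test(y, g, covariates)
    yv = np.asarray(y, dtype=float)
    rho2_total = float(np.var(beta * np.asarray(g, float), ddof=1)
                       / np.var(yv, ddof=1))
    return rho2_total, rho2_total / (1.0 - experimental_fraction)
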