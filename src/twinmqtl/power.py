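"""Power of the additive single-SNP test under Bonferroni multiplicity.

Effect size is parameterized by rho^2, the proportion of trait variance
explained by genotype (the squared genotype-trait correlation).  The
two-sided slope test at per-test level alpha = alpha_family / m_tests is an
F(1, n-2) test with noncentrality lambda = n * rho^2 / (1 - rho^2); power is
the upper tail of the noncentral F at the central-F critical value.  The
detectable effect size is the smallest rho^2 reaching a target power,
obtained by bisection, and maps out the power/sample-size trade-off between
a small deeply-phenotyped twin study and a large single-visit cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class PowerError(ValueError):
    pass


@dataclass
class PowerQuery:
    n: int
    rho2: float
    alpha_family: float = 0.05
    m_tests: int = 1
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho2 < 1.0:
            raise PowerError("rho2 must lie in [0, 1)")
        if self.n < 4:
            raise PowerError("n must be >= 4")
        if self.m_tests < 1:
            raise PowerError("m_tests must be >= 1")


def power_additive(q: PowerQuery) -> float:
    """Rejection probability of the per-test slope test at level
    alpha_family / m_tests, for a SNP explaining rho2 of trait variance in a
    sample of n subjects."""
    if q.n <= 3:
        raise PowerError("n must exceed 3")
    alpha = q.alpha_family / q.m_tests
    fcrit = stats.f.isf(alpha, 1, q.n - 2)
    if q.rho2 == 0.0:
        return alpha
    lam = q.n * q.rho2 / (1.0 - q.rho2)
    return float(stats.ncf.sf(fcrit, 1, q.n - 2, lam))


def detectable_r2(n: int, alpha_family: float = 0.05, m_tests: int = 1,
                  target_power: float = 0.80, tol: float = 1e-6) -> float:
    """Smallest rho^2 detectable with the target power, by bisection."""
    alpha = alpha_family / m_tests
    if not alpha < target_power < 1.0:
        raise PowerError("target power must lie in (per-test alpha, 1)")

    def gap(r2: float) -> float:
        return power_additive(PowerQuery(n, r2, alpha_family, m_tests,
                                         target_power)) - target_power

    hi = 1.0 - 1e-9
    if gap(hi) < 0:
        raise PowerError(f"target power unattainable at n={n}")
    return float(optimize.brentq(gap, 0.0, hi, xtol=tol))


def detectable_r2_curve(n_grid, alpha_family: float = 0.05,
                        m_tests: int = 1,
                        target_power: float = 0.80) -> pd.DataFrame:
    """Detectable effect size across a sample-size grid (one study's power
    curve), as a TSV-ready table."""
    rows = []
    for n in n_grid:
        try:
            r2 = detectable_r2(int(n), alpha_family, m_tests, target_power)
        except PowerError:
            r2 = float("nan")
        rows.append({"n": int(n), "detectable_rho2": r2})
    return pd.DataFrame(rows)


def power_additive_mc(n: int, rho2: float, alpha: float,
                      n_sims: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo rejection rate of the same test, by simulating OLS
    regressions with a Gaussian regressor at the specified rho^2.  Used as
    an independent check on the noncentral-F formula."""
    rng = np.random.default_rng(seed)
    beta = np.sqrt(rho2 / (1.0 - rho2))
    tcrit = stats.t.isf(alpha / 2.0, n - 2)
    rejected = 0
    chunk = max(1, min(n_sims, 20_000_000 // max(n, 1)))
    done = 0
    while done < n_sims:
        b = min(chunk, n_sims - done)
        g = rng.standard_normal((b, n))
        y = beta * g + rng.standard_normal((b, n))
        gc = g - g.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = (gc * yc).sum(axis=1) / np.sqrt(
            (gc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        rejected += int(np.sum(np.abs(t) > tcrit))
        done += b
    return rejected / n_sims
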