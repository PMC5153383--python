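"""Cohort statistics: normality screening, paired comparison, rank
correlation, and regression against a constant model.

All tests are two-sided with significance declared at α = 0.05.  The
Kolmogorov–Smirnov normality screen uses the Lilliefors correction by
default because the comparison distribution's mean and SD are estimated from
the sample (the uncorrected KS test is anticonservative in that setting);
the uncorrected variant remains available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "StatResult",
    "ks_normality",
    "paired_t",
    "spearman",
    "regress_vs_constant",
    "RegressionResult",
    "correlation_gate",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _clean1d(x, min_n: int, name: str = "sample") -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def ks_normality(sample, lilliefors: bool = True) -> StatResult:
    """KS distance of the sample against a normal law with sample-estimated
    mean/SD; p by the Lilliefors approximation (default) or the plain KS
    distribution (anticonservative, for comparison only)."""
    x = _clean1d(sample, 4)
    if np.std(x, ddof=1) == 0:
        raise ValueError("sample has zero variance")
    if lilliefors:
        stat, p = _lilliefors(x, dist="norm")
        method = "lilliefors"
    else:
        stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        method = "ks-estimated-params"
    return StatResult(float(stat), float(min(p, 1.0)), x.size, method)


def paired_t(pre, post) -> StatResult:
    """Two-sided paired-sample t test on (pre − post), df = n − 1."""
    a = _clean1d(pre, 2, "pre")
    b = _clean1d(post, 2, "post")
    if a.size != b.size:
        raise ValueError("pre and post must have equal length")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("paired differences have zero variance")
    t, p = sps.ttest_rel(a, b)
    return StatResult(float(t), float(p), a.size, "paired-t")


def spearman(x, y, exact: bool = False) -> StatResult:
    """Spearman rank correlation with mid-rank tie correction.

    p comes from the t approximation; ``exact=True`` enumerates all pairings
    (full permutation null, supported for n <= 8).
    """
    xa = _clean1d(x, 4, "x")
    ya = _clean1d(y, 4, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("a fully tied vector has no rank correlation")
    rho, p = sps.spearmanr(xa, ya)
    if exact:
        n = xa.size
        if n > 8:
            raise ValueError("exact permutation p-value supported for n <= 8")
        rx = sps.rankdata(xa)
        ry = sps.rankdata(ya)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12:
                count += 1
        p = count / total
        return StatResult(float(rho), float(p), n, "spearman-exact")
    return StatResult(float(rho), float(p), xa.size, "spearman")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def regress_vs_constant(x, y) -> RegressionResult:
    """Least-squares line y = a + b·x with the F test of the fit against the
    constant model: F = (n−2)·R²/(1−R²) on (1, n−2) df."""
    xa = _clean1d(x, 3, "x")
    ya = _clean1d(y, 3, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(xa) == 0:
        raise ValueError("x is constant; the regression is undefined")
    fit = sps.linregress(xa, ya)
    r2 = fit.rvalue ** 2
    n = xa.size
    if r2 >= 1.0:
        f = float("inf")
        p = 0.0
    else:
        f = (n - 2) * r2 / (1.0 - r2)
        p = float(sps.f.sf(f, 1, n - 2))
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(r2), f_statistic=float(f), p_value=p, n=n)


def correlation_gate(rho: float) -> bool:
    """Follow-up-regression gate: |ρ| strictly greater than 0.5."""
    return abs(rho) > 0.5
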