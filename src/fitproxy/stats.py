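"""Comparison statistics for fitness proxies.

Pearson correlations with Fisher-z confidence intervals, CI-overlap and
Steiger dependent-correlation comparison, z-scoring, maximum-likelihood
binary logistic regression with Wald intervals, Fisher's exact test and the
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

Z975 = sps.norm.ppf(0.975)


@dataclass(frozen=True)
class CorrelationEstimate:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class ComparisonResult:
    different: bool
    method: str
    statistic: float | None = None
    p: float | None = None


@dataclass(frozen=True)
class LogisticFit:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p: float
    separation: bool = False


def zscore(x) -> np.ndarray:
    """Standardise to mean 0, sample SD 1 (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("z-scoring needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance vector")
    return (x - x.mean()) / sd


def pearson_ci(x, y) -> CorrelationEstimate:
    """Pearson r with Fisher-z 95% CI and two-sided p (t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("Pearson CI needs n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input to correlation")
    r, p = sps.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        half = Z975 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationEstimate(r=r, n=n, ci_low=float(lo), ci_high=float(hi),
                               p=float(p))


def compare_correlations(
    a: CorrelationEstimate,
    b: CorrelationEstimate,
    method: str = "ci_overlap",
    r_ab: float | None = None,
) -> ComparisonResult:
    """Decide whether two correlations differ.

    ``ci_overlap`` declares a difference iff the 95% CIs are disjoint (a
    conservative criterion).  ``dependent_test`` is Steiger's z for two
    correlations sharing one variable on the same sample; it additionally
    needs ``r_ab``, the correlation between the two predictors.
    """
    if method == "ci_overlap":
        disjoint = a.ci_high < b.ci_low or b.ci_high < a.ci_low
        return ComparisonResult(different=bool(disjoint), method=method)
    if method != "dependent_test":
        raise ValueError(f"unknown method {method!r}")
    if a.n != b.n:
        raise ValueError("dependent test requires estimates on the same sample")
    if r_ab is None:
        raise ValueError("dependent test needs r_ab between the two predictors")
    n = a.n
    r1, r2 = a.r, b.r
    rbar = (r1 + r2) / 2.0
    # Steiger (1980): covariance of the two dependent correlations
    num = r_ab * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_ab**2)
    s = num / (1 - rbar**2) ** 2
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    zstat = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - s)))
    p = 2 * sps.norm.sf(abs(zstat))
    return ComparisonResult(
        different=bool(p < 0.05), method=method, statistic=float(zstat),
        p=float(p),
    )


def logistic_fit(y, x) -> LogisticFit:
    """ML binary logistic regression of y on x with Wald 95% CIs.

    Complete separation is detected and flagged instead of returning the
    divergent estimates.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class")
    design = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:
            return LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               separation=True)
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    # divergent slope / exploding SE marks (quasi-)complete separation
    if not np.isfinite(se) or abs(slope) > 30 or se > 1e3:
        return LogisticFit(slope, float(fit.params[0]), np.nan, np.nan, np.nan,
                           separation=True)
    return LogisticFit(
        slope=slope,
        intercept=float(fit.params[0]),
        ci_low=slope - Z975 * se,
        ci_high=slope + Z975 * se,
        p=float(fit.pvalues[1]),
        separation=False,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Uses the dominant convention: sum of hypergeometric probabilities of all
    tables no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or (t != np.round(t)).any():
            raise ValueError("counts must be nonnegative integers")
        t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("Fisher exact test undefined for an empty margin")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(p)


def rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum W (Mann-Whitney U of the first sample, midrank ties)
    and two-sided p.

    Exact enumeration for combined n <= 20 without ties; otherwise the normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size + y.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)
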