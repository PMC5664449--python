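"""Statistical primitives shared by the occupancy, tail-length and stability analyses.

All comparisons in the pipeline reduce to a small set of two-sample tests and
rank statistics on per-gene value vectors (log2 fold changes, tail lengths,
relative occupancies).  This module wraps the scipy implementations behind the
conventions used throughout the package -- two-sided tests, average ranks with
tie correction, and explicit exact modes for small samples -- and adds the
combinatorial helpers (hypergeometric enrichment, Benjamini-Hochberg) used by
the gene-set analysis.

Exact-mode p-values for the Kolmogorov-Smirnov and Mann-Whitney tests are
computed by full enumeration of group-label assignments, which handles ties
correctly and is feasible for the small samples where exactness matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "CorrelationResult",
    "ks_two_sample",
    "mann_whitney_u",
    "spearman",
    "fisher_r_to_z_compare",
    "hypergeometric_enrichment",
    "bh_fdr",
    "box_summary",
    "ecdf",
]

#: number of label assignments above which exact enumeration falls back to scipy
_MAX_ENUMERATION = 200_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample hypothesis test."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with its two-sided p-value.

    ``defined`` is False when either input vector is constant, in which case
    ``rho`` and ``p_value`` are NaN.
    """

    rho: float
    n: int
    p_value: float
    defined: bool = True


def _as_vector(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Max absolute difference of the two empirical CDFs."""
    grid = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def ks_two_sample(a: Sequence[float], b: Sequence[float], method: str = "asymp") -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    ``method='asymp'`` (default) uses the asymptotic Kolmogorov distribution,
    appropriate for the large per-gene collections compared here.
    ``method='exact'`` enumerates all assignments of the pooled values to the
    two groups (tie-safe) when feasible, otherwise defers to scipy's exact
    mode.
    """
    av = _as_vector(a, "a")
    bv = _as_vector(b, "b")
    d_obs = _ks_statistic(av, bv)
    if method == "asymp":
        res = sps.ks_2samp(av, bv, alternative="two-sided", method="asymp")
        p = float(res.pvalue)
    elif method == "exact":
        p = _enumerate_p(av, bv, _ks_statistic, d_obs)
        if p is None:
            res = sps.ks_2samp(av, bv, alternative="two-sided", method="exact")
            p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(d_obs, min(p, 1.0), av.size, bv.size, f"ks_two_sample[{method}]")


def _enumerate_p(a, b, stat_fn, observed, center=None):
    """Exact p by enumerating all C(n1+n2, n1) group assignments.

    Returns None when enumeration would exceed the feasibility cap.  When
    ``center`` is given the tail is two-sided around it (|T - center| >=
    |observed - center|), otherwise the tail is T >= observed (suitable for
    the KS statistic, which is already non-directional).
    """
    pooled = np.concatenate([a, b])
    n1 = a.size
    n = pooled.size
    if math.comb(n, n1) > _MAX_ENUMERATION:
        return None
    idx = np.arange(n)
    count = 0
    total = 0
    eps = 1e-12
    for chosen in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        t = stat_fn(pooled[mask], pooled[~mask])
        if center is None:
            hit = t >= observed - eps
        else:
            hit = abs(t - center) >= abs(observed - center) - eps
        count += hit
        total += 1
    return count / total


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of the first group, with average ranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: a.size].sum()
    return float(r1 - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    method: str = "asymp",
) -> TestResult:
    """Two-sided rank test between two per-gene value vectors.

    Unpaired: Mann-Whitney U with average ranks and tie-corrected normal
    approximation (or an exact enumeration of label assignments for small
    samples).  Paired: the Wilcoxon signed-rank test on per-gene differences,
    the standard paired analogue of the U test; vectors must be aligned by
    gene and of equal length.
    """
    av = _as_vector(a, "a")
    bv = _as_vector(b, "b")
    if paired:
        if av.size != bv.size:
            raise ValueError("paired test requires equal-length, gene-aligned vectors")
        diffs = av - bv
        if np.all(diffs == 0):
            return TestResult(0.0, 1.0, av.size, bv.size, "wilcoxon_signed_rank")
        res = sps.wilcoxon(av, bv, alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue), av.size, bv.size, "wilcoxon_signed_rank")
    u_obs = _u_statistic(av, bv)
    if method == "exact":
        center = av.size * bv.size / 2.0
        p = _enumerate_p(av, bv, _u_statistic, u_obs, center=center)
        if p is None:
            res = sps.mannwhitneyu(av, bv, alternative="two-sided", method="exact")
            p = float(res.pvalue)
    elif method == "asymp":
        res = sps.mannwhitneyu(av, bv, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(u_obs, min(p, 1.0), av.size, bv.size, f"mann_whitney_u[{method}]")


def spearman(x: Sequence[float], y: Sequence[float], method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use averages for ties.  ``method='t'`` (default) uses the t
    approximation; ``method='exact'`` enumerates all permutations of one
    vector (only sensible for n <= 8).  A constant input yields an undefined
    (flagged) result rather than an error, since constant features do occur
    in degenerate simulations.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(math.nan, n, math.nan, defined=False)
    rho, p = sps.spearmanr(xv, yv)
    rho = float(rho)
    if method == "exact":
        if math.factorial(n) > _MAX_ENUMERATION:
            raise ValueError("exact Spearman p is only available for small n")
        rx = sps.rankdata(xv)
        ry = sps.rankdata(yv)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    return CorrelationResult(rho, n, float(p))


def fisher_r_to_z_compare(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Compare two independent correlation coefficients via Fisher's r-to-z.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal
    p-value.  Used to contrast, e.g., the bound-vs-total tail correlations of
    two different proteins measured on different gene sets.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError(f"|r| must be < 1, got {r}")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 per correlation")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), n1, n2, "fisher_r_to_z")


def hypergeometric_enrichment(
    hits_in_set: int, set_size: int, hits_total: int, background: int, mode: str = "upper"
) -> float:
    """Upper-tail hypergeometric p: probability of >= hits_in_set overlaps.

    ``background`` genes, of which ``hits_total`` are "interesting" (e.g. the
    extreme-residual genes) and ``set_size`` belong to the annotated set;
    ``hits_in_set`` is the observed overlap.

    ``mode='upper'`` (default) is the conservative tail probability used for
    inference.  ``mode='mid'`` is Lancaster's mid-p (P(X > k) + 0.5 P(X = k)),
    the standard device for checking the null calibration of a discrete test:
    the conservative p cannot be uniform under the null because its CDF steps
    below the diagonal between achievable values, whereas the mid-p is
    uniform to within half an atom.
    """
    for name, v in (
        ("hits_in_set", hits_in_set),
        ("set_size", set_size),
        ("hits_total", hits_total),
        ("background", background),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if hits_in_set > min(set_size, hits_total):
        raise ValueError("hits_in_set exceeds min(set_size, hits_total)")
    if max(set_size, hits_total) > background:
        raise ValueError("set_size and hits_total must not exceed background")
    if hits_in_set < set_size + hits_total - background:
        raise ValueError("inconsistent counts: overlap below forced minimum")
    if mode == "upper":
        return float(sps.hypergeom.sf(hits_in_set - 1, background, hits_total, set_size))
    if mode == "mid":
        sf = sps.hypergeom.sf(hits_in_set, background, hits_total, set_size)
        pmf = sps.hypergeom.pmf(hits_in_set, background, hits_total, set_size)
        return float(sf + 0.5 * pmf)
    raise ValueError(f"unknown mode {mode!r}")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty sample")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def box_summary(values: Sequence[float]) -> dict:
    """Median, quartiles and Tukey whiskers (most extreme points within 1.5 IQR).

    The convention used for every box summary in the pipeline's outputs.
    """
    v = _as_vector(values, "values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    within = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(within.min()),
        "whisker_high": float(within.max()),
        "n": int(v.size),
    }


def ecdf(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF evaluated at the sorted observed values."""
    v = np.sort(_as_vector(values, "values"))
    return v, np.arange(1, v.size + 1) / v.size
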