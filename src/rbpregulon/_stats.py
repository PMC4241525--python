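"""Shared statistical primitives: coefficient of deviation and correlations.

The correlation layer mirrors R's ``cor.test``: Pearson with a t-based
two-sided p-value, or Spearman on average ranks with an exact permutation
p-value at small n and the asymptotic t approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

#: sample sizes at or below which the Spearman p-value is computed by
#: exhaustive permutation of one rank vector (10! = 3.6M permutations).
EXACT_P_MAX_N = 10

_CHUNK = 200_000


def coefficient_of_deviation(x: np.ndarray, ddof: int = 1) -> float:
    """SD divided by mean (the coefficient of variation).

    Uses the sample (n-1) standard deviation by default. Returns 0.0 for a
    constant vector and raises on a mean of exactly zero.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    sd = x.std(ddof=ddof)
    if sd == 0.0:
        return 0.0
    if mean == 0.0:
        raise ZeroDivisionError("coefficient of deviation undefined for zero mean")
    return float(sd / mean)


@dataclass(frozen=True)
class Correlation:
    """A correlation coefficient with its two-sided p-value.

    ``degenerate`` is True when either input vector is constant, in which
    case rho and p carry 0.0/1.0 placeholders and must not be interpreted.
    """

    rho: float
    p_value: float
    method: str
    n: int
    degenerate: bool = False


def _rankdata(x: np.ndarray) -> np.ndarray:
    """Average ranks (ties share the mean of their positions), 1-based."""
    return stats.rankdata(x, method="average")


def _pearson_rho(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


@lru_cache(maxsize=8)
def _tie_free_null(n: int) -> np.ndarray:
    """Sorted null distribution of Spearman rho over all n! permutations,
    valid for any tie-free input of length n."""
    r = np.arange(1, n + 1, dtype=float)
    return np.sort(_perm_rhos(r, r))


def _perm_rhos(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """Pearson correlation of rx against every permutation of ry."""
    n = len(rx)
    out = np.empty(0)
    xc = rx - rx.mean()
    sx = np.sqrt((xc**2).sum())
    yc_all = ry - ry.mean()
    sy = np.sqrt((yc_all**2).sum())
    perms = itertools.permutations(range(n))
    chunks = []
    while True:
        block = np.array(list(itertools.islice(perms, _CHUNK)), dtype=np.intp)
        if block.size == 0:
            break
        permuted = ry[block]  # (chunk, n)
        num = (permuted - ry.mean()) @ xc
        chunks.append(num / (sx * sy))
    out = np.concatenate(chunks)
    return np.clip(out, -1.0, 1.0)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided permutation p-value for Spearman rho.

    For tie-free data the null depends only on n, so the distribution is
    cached; with ties the observed rank vectors are enumerated directly.
    """
    n = len(rx)
    tie_free = len(set(rx)) == n and len(set(ry)) == n
    thr = abs(rho) - 1e-12
    if tie_free:
        null = _tie_free_null(n)
        # null is sorted: count |rho_perm| >= |rho_obs|
        count = np.count_nonzero(np.abs(null) >= thr)
        return count / len(null)
    null = _perm_rhos(rx, ry)
    return float(np.count_nonzero(np.abs(null) >= thr) / len(null))


def correlation(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "spearman",
) -> Correlation:
    """Correlate two equal-length vectors with a two-sided p-value.

    method='spearman' ranks both vectors (average ranks for ties) and uses
    an exact permutation p for n <= 10, the t approximation above.
    method='pearson' matches scipy.stats.pearsonr.
    Constant input on either side yields a degenerate result rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return Correlation(0.0, 1.0, method, n, degenerate=True)

    if method == "pearson":
        rho, p = stats.pearsonr(x, y)
        return Correlation(float(rho), float(p), method, n)
    if method != "spearman":
        raise ValueError(f"unknown correlation method: {method!r}")

    rx, ry = _rankdata(x), _rankdata(y)
    rho = _pearson_rho(rx, ry)
    if n <= EXACT_P_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        # t approximation, as cor.test uses for larger samples
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return Correlation(rho, min(p, 1.0), "spearman", n)


def variance_ratio_test(
    numerator: np.ndarray, denominator: np.ndarray
) -> tuple[float, float]:
    """Two-sided F-test of equal variances: F = var(num)/var(den),
    df = (n_num - 1, n_den - 1).

    Zero denominator variance yields (inf, 0.0); both variances zero is the
    fully degenerate case and yields (1.0, 1.0).
    """
    a = np.asarray(numerator, dtype=float)
    b = np.asarray(denominator, dtype=float)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0, 1.0
    if vb == 0.0:
        return float("inf"), 0.0
    f = va / vb
    dist = stats.f(len(a) - 1, len(b) - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))
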