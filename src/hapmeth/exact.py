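"""Exact-test primitives: vectorised two-sided Fisher tests and BH adjustment.

Window and per-cytosine differential-methylation tests reduce to two-sided
Fisher's exact tests on 2x2 tables of (methylated, unmethylated) read counts.
A sliding-window genome scan produces tens of thousands of tables per
comparison, so the p-values are computed in bulk: the two-sided p-value sums
every hypergeometric term whose probability does not exceed the observed
one, and because the pmf is unimodal those terms form the two tails outside
a contiguous interval around the mode. The tail boundaries are located by a
vectorised binary search on the log-pmf and the tail masses summed with the
hypergeometric CDF/SF, making each table O(log support) instead of
O(support).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

__all__ = ["fisher_exact_2x2", "bh_adjust"]

# Terms mathematically equal to the observed one must be included in the
# two-sided sum even when floating-point log-probabilities differ in the last
# bits; the relative tolerance matches the convention of scipy and R.
_TIE_RTOL = 1e-7

_logfact = gammaln(np.arange(2, dtype=np.float64) + 1.0)


def _log_factorials(n: int) -> np.ndarray:
    """Lookup table of log(k!) for k = 0..n, grown on demand and cached."""
    global _logfact
    if n >= _logfact.shape[0]:
        _logfact = gammaln(np.arange(max(n + 1, 2 * _logfact.shape[0]), dtype=np.float64) + 1.0)
    return _logfact


def fisher_exact_2x2(tables: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p-values for a batch of 2x2 tables.

    Parameters
    ----------
    tables
        Integer array of shape (n, 4) holding rows ``(a, b, c, d)`` of the
        table ``[[a, b], [c, d]]``. In the methylation setting a row is
        ``(mc1, cov1 - mc1, mc2, cov2 - mc2)``.

    Returns
    -------
    ndarray of shape (n,) with two-sided p-values. A degenerate table whose
    support is a single point has p = 1.
    """
    t = np.asarray(tables, dtype=np.int64)
    if t.ndim == 1:
        t = t[None, :]
    if t.shape[-1] != 4:
        raise ValueError("tables must have four columns (a, b, c, d)")
    if (t < 0).any():
        raise ValueError("negative counts in contingency table")

    a, b, c, d = t[:, 0], t[:, 1], t[:, 2], t[:, 3]
    total = a + b + c + d
    row1 = a + b
    col1 = a + c
    lf = _log_factorials(int(total.max(initial=1)))

    # log P(X = k) for X ~ Hypergeom(N, K, n), constant part per table
    log_denom = lf[total] - lf[col1] - lf[total - col1]
    lo = np.maximum(0, row1 + col1 - total)
    hi = np.minimum(row1, col1)

    def logpmf(k):
        return (lf[row1] - lf[k] - lf[row1 - k]
                + lf[total - row1] - lf[col1 - k] - lf[total - row1 - col1 + k]
                - log_denom)

    thresh = logpmf(a) + np.log1p(_TIE_RTOL)
    # pmf is non-decreasing on [lo, mode] and non-increasing on [mode, hi]
    mode = np.clip((row1 + 1) * (col1 + 1) // (total + 2), lo, hi)

    def last_true(left, right):
        # largest k in [left, right] with logpmf(k) <= thresh on the rising
        # flank; returns left - 1 when none qualifies
        ok = logpmf(left) <= thresh
        kl = np.where(ok, left, left - 1)
        l = np.where(ok, left, left)
        r = right.copy()
        while True:
            active = l < r
            if not active.any():
                break
            mid = (l + r + 1) // 2
            good = (logpmf(np.clip(mid, lo, hi)) <= thresh) & active
            l = np.where(good, mid, l)
            r = np.where(active & ~good, mid - 1, r)
        return np.where(ok, l, kl)

    def first_true(left, right):
        # smallest k in [left, right] with logpmf(k) <= thresh on the
        # falling flank; returns right + 1 when none qualifies
        ok = logpmf(right) <= thresh
        l = left.copy()
        r = right.copy()
        while True:
            active = l < r
            if not active.any():
                break
            mid = (l + r) // 2
            good = (logpmf(np.clip(mid, lo, hi)) <= thresh) & active
            r = np.where(good, mid, r)
            l = np.where(active & ~good, mid + 1, l)
        return np.where(ok, r, right + 1)

    k_left = last_true(lo, mode)
    k_right = first_true(mode, hi)
    p_left = np.where(k_left >= lo,
                      hypergeom.cdf(np.maximum(k_left, lo), total, row1, col1),
                      0.0)
    p_right = np.where(k_right <= hi,
                       hypergeom.sf(np.minimum(k_right, hi) - 1, total, row1, col1),
                       0.0)
    p = np.minimum(p_left + p_right, 1.0)
    return np.where(total > 0, p, 1.0)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Implements q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the sorted
    p-values, mapped back to input order; ties are handled by a stable sort
    so the result is invariant to input order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q
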