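"""Straightforward O(N^2) pair counting — the correctness oracle.

Every pair of templates (i, j) with i < j is checked directly.  The
m-dimensional check short-circuits on the first failing coordinate, and a
successful match triggers exactly one more scalar comparison for the
(m+1)-dimensional extension.  All other backends must reproduce these counts
integer-for-integer.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import MatchCounts, TimeSeries, as_series

__all__ = ["count_matches_bruteforce", "per_template_profile"]


def _validate(series: TimeSeries, m: int, r_abs: float) -> np.ndarray:
    series = as_series(series)
    if m < 1:
        raise ValueError("m must be >= 1")
    if r_abs <= 0:
        raise ValueError("tolerance must be positive")
    if series.n < m + 2:
        raise ValueError(f"series too short: n={series.n} < m + 2 = {m + 2}")
    return series.values


@njit(cache=True)
def _count(x, m, r):  # pragma: no cover - exercised through the wrapper
    n = x.shape[0]
    t = n - m
    b = np.int64(0)
    a = np.int64(0)
    comps = np.int64(0)
    for i in range(t):
        for j in range(i + 1, t):
            ok = True
            for k in range(m):
                comps += 1
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                comps += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return b, a, comps


@njit(cache=True)
def _profile(x, m, r):  # pragma: no cover
    n = x.shape[0]
    t = n - m
    nm = np.zeros(t, dtype=np.int64)
    nm1 = np.zeros(t, dtype=np.int64)
    for i in range(t):
        for j in range(i + 1, t):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                nm[i] += 1
                nm[j] += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    nm1[i] += 1
                    nm1[j] += 1
    return nm, nm1


def count_matches_bruteforce(series: TimeSeries, m: int, r_abs: float) -> MatchCounts:
    """Count similar template pairs by exhaustive enumeration."""
    x = _validate(series, m, r_abs)
    b, a, comps = _count(x, m, float(r_abs))
    return MatchCounts(b_pairs=int(b), a_pairs=int(a), element_comparisons=int(comps))


def per_template_profile(series: TimeSeries, m: int, r_abs: float) -> np.ndarray:
    """Ordered per-template counts (n_i^m, n_i^{m+1}), shape (N - m, 2).

    Both directions of every unordered pair are attributed, so each column
    sums to twice the corresponding pair count.
    """
    x = _validate(series, m, r_abs)
    nm, nm1 = _profile(x, m, float(r_abs))
    return np.stack((nm, nm1), axis=1)
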