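"""Lightweight backend: one value-sort of the raw series.

The raw series is sorted once (stable, O(N log N)).  For the element at
sorted rank i, the only possible partners with a similar first coordinate
are the ranks j > i with ``ordx[j] <= ordx[i] + r`` — a contiguous block
located by binary search.  The lower side (``ordx[j] >= ordx[i] - r``) is
omitted because those pairs were already enumerated when the smaller rank
acted as the probe.  Each surviving rank pair maps back to original
positions (a, b); the pair is skipped unless both are valid template starts
(``<= N - m`` in 1-based terms), and is then verified on the remaining
``m - 1`` coordinates and the m+1 extension.

Distinct ranks always map to distinct positions, so self-pairs cannot
occur; duplicate values at distinct positions are legitimate matches.  The
backend shines for m = 1 (verification is then just the extension check)
and for short series, where its minimal bookkeeping beats the tree- and
bucket-based machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import MatchCounts, TimeSeries, as_series
from .bruteforce import _validate

__all__ = ["SortedView", "build_sorted_view", "count_matches_lightweight"]


@dataclass(frozen=True)
class SortedView:
    """Value-sorted copy of a series with the original-position map.

    ``ordx`` is non-decreasing and a permutation of the series values;
    ``posx[i]`` is the 0-based original position of ``ordx[i]``, so
    ``x[posx[i]] == ordx[i]``.  Ties keep original order (stable sort) —
    any deterministic tie rule yields identical final counts.
    """

    ordx: np.ndarray
    posx: np.ndarray


def build_sorted_view(series: TimeSeries) -> SortedView:
    """Stable-sort the series values and remember where each came from."""
    x = as_series(series).values
    posx = np.argsort(x, kind="stable").astype(np.int64)
    return SortedView(ordx=x[posx], posx=posx)


@njit(cache=True)
def _count_lw(x, ordx, posx, m, r):  # pragma: no cover
    n = x.shape[0]
    t = n - m
    b = np.int64(0)
    a = np.int64(0)
    comps = np.int64(0)
    for i in range(n):
        ai = posx[i]
        if ai >= t:
            continue
        base = ordx[i]
        # binary search: first rank > i with ordx[j] - ordx[i] > r; the
        # predicate uses the same subtraction expression as the verification
        # step so boundary pairs resolve identically in floating point
        lo = i + 1
        hi = n
        while lo < hi:
            mid = (lo + hi) // 2
            if ordx[mid] - base <= r:
                lo = mid + 1
            else:
                hi = mid
        for j in range(i + 1, lo):
            bj = posx[j]
            if bj >= t:
                continue
            # first coordinate already within r by construction of the block
            ok = True
            for k in range(1, m):
                comps += 1
                if abs(x[ai + k] - x[bj + k]) > r:
                    ok = False
                    break
            if ok:
                b += 1
                comps += 1
                if abs(x[ai + m] - x[bj + m]) <= r:
                    a += 1
    return b, a, comps


def count_matches_lightweight(series: TimeSeries, m: int, r_abs: float) -> MatchCounts:
    """Count similar template pairs via the sorted-series candidate window."""
    x = _validate(series, m, r_abs)
    view = build_sorted_view(as_series(series))
    b, a, comps = _count_lw(x, view.ordx, view.posx, m, float(r_abs))
    return MatchCounts(b_pairs=int(b), a_pairs=int(a), element_comparisons=int(comps))
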