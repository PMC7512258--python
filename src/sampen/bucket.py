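"""Bucket-assisted backend: neighbour pruning via the integrated series.

Each template is summarised by its integrated value

    X_i = x_i + x_{i+1} + ... + x_{i+m-1}

If two templates are similar (every coordinate within r), then
|X_i - X_j| <= m * r.  Mapping each template into a bucket of width
``r / rsplit`` (after shifting so min(X) = 1) therefore confines the
partners of any template to the ``m * rsplit`` buckets at or below its own
(plus its own bucket), so whole buckets of hopeless candidates are skipped.
The split factor refines the pruning: larger ``rsplit`` means narrower
buckets and a proportionally tighter neighbour span.

Within each bucket the members are sorted by the first element of the
template, so the first-coordinate test reduces to locating a contiguous
window — by binary search for cross-bucket probes, by an early-exit scan for
within-bucket pairs.  Only candidates surviving that window get the
remaining ``m - 1`` coordinates verified.

Numerical note: the ±m·rsplit bucket bound is proved in exact arithmetic.
The integrated values are computed with one identical per-window summation
for every template (no rolling updates), and the neighbour span is extended
by one guard bucket below, which immunises the exactness contract against a
template landing within one ULP of a bucket boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import MatchCounts, TimeSeries, as_series
from .bruteforce import _validate

__all__ = ["BucketGrid", "integrate_series", "build_buckets", "count_matches_bucket"]


@njit(cache=True)
def _integrate(x, m):  # pragma: no cover
    t = x.shape[0] - m
    out = np.empty(t, dtype=np.float64)
    for i in range(t):
        s = 0.0
        for k in range(m):
            s += x[i + k]
        out[i] = s
    return out


def integrate_series(series: TimeSeries, m: int) -> np.ndarray:
    """Window sums X_i over the N - m template starts (one expression for all i)."""
    x = _validate(series, m, 1.0)
    return _integrate(x, m)


@dataclass(frozen=True)
class BucketGrid:
    """Bucket membership of the templates of one series.

    ``offset`` is the shift applied to the integrated series so that its
    minimum maps to 1 (``X' = X - offset``); ``width = r_abs / rsplit``;
    bucket ids are ``ceil(X'_i / width)`` (1-based).  Only occupied buckets
    are materialised: ``members`` lists template starts grouped by bucket and
    sorted within each bucket by the template's first element (ties by start
    index); ``uids``/``ustart`` delimit the groups.  ``span`` is the number
    of buckets below the current one that must be searched, ``m * rsplit``
    plus one guard bucket.
    """

    m: int
    r_abs: float
    rsplit: int
    X: np.ndarray
    offset: float
    width: float
    n_buckets: int
    span: int
    bucket_ids: np.ndarray
    members: np.ndarray
    uids: np.ndarray
    ustart: np.ndarray

    def members_of(self, bucket_id: int) -> np.ndarray:
        """Template starts (0-based) in the given 1-based bucket, sorted order."""
        pos = np.searchsorted(self.uids, bucket_id)
        if pos == self.uids.size or self.uids[pos] != bucket_id:
            return np.empty(0, dtype=np.int64)
        return self.members[self.ustart[pos]:self.ustart[pos + 1]].copy()

    def buckets(self) -> dict:
        """Mapping 1-based bucket id -> list of member template starts."""
        return {
            int(u): self.members[self.ustart[i]:self.ustart[i + 1]].tolist()
            for i, u in enumerate(self.uids)
        }


def build_buckets(
    X: np.ndarray, series: TimeSeries, r_abs: float, rsplit: int
) -> BucketGrid:
    """Assign templates to buckets and sort each bucket by first element."""
    series = as_series(series)
    if rsplit < 1:
        raise ValueError("rsplit must be >= 1")
    if r_abs <= 0:
        raise ValueError("tolerance must be positive")
    X = np.asarray(X, dtype=np.float64)
    t = X.shape[0]
    m = series.n - t
    offset = float(X.min()) - 1.0
    xp = X - offset
    width = float(r_abs) / int(rsplit)
    ids = np.ceil(xp / width).astype(np.int64)
    n_buckets = int(np.ceil(xp.max() / width))
    first = series.values[:t]
    order = np.lexsort((np.arange(t), first, ids))
    members = order.astype(np.int64)
    sorted_ids = ids[order]
    uids, starts = np.unique(sorted_ids, return_index=True)
    ustart = np.append(starts, t).astype(np.int64)
    return BucketGrid(
        m=m,
        r_abs=float(r_abs),
        rsplit=int(rsplit),
        X=X,
        offset=offset,
        width=width,
        n_buckets=n_buckets,
        span=m * int(rsplit) + 1,
        bucket_ids=ids,
        members=members,
        uids=uids.astype(np.int64),
        ustart=ustart,
    )


@njit(cache=True)
def _count_bucket(x, m, r, members, uids, ustart, span):  # pragma: no cover
    nu = uids.shape[0]
    b = np.int64(0)
    a = np.int64(0)
    comps = np.int64(0)
    for u in range(nu):
        s0 = ustart[u]
        e0 = ustart[u + 1]
        # within-bucket: unordered pairs in first-element sorted order,
        # early exit once the window x_q <= x_p + r is exhausted
        for p in range(s0, e0):
            i = members[p]
            xi = x[i]
            for q in range(p + 1, e0):
                j = members[q]
                comps += 1
                if x[j] - xi > r:
                    break
                ok = True
                for k in range(1, m):
                    comps += 1
                    if abs(x[i + k] - x[j + k]) > r:
                        ok = False
                        break
                if ok:
                    b += 1
                    comps += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        # cross-bucket: occupied buckets with id in [id_u - span, id_u - 1];
        # the upper side is covered when those buckets act as the probe side
        lo_id = uids[u] - span
        v = np.searchsorted(uids, lo_id)
        while v < u:
            s1 = ustart[v]
            e1 = ustart[v + 1]
            for p in range(s0, e0):
                i = members[p]
                xi = x[i]
                # binary search for the first candidate with x_i - x_j <= r;
                # predicates use the same subtraction expression as the
                # verification step so boundary pairs resolve identically
                lo = s1
                hi = e1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if xi - x[members[mid]] > r:
                        lo = mid + 1
                    else:
                        hi = mid
                for q in range(lo, e1):
                    j = members[q]
                    comps += 1
                    if x[j] - xi > r:
                        break
                    ok = True
                    for k in range(1, m):
                        comps += 1
                        if abs(x[i + k] - x[j + k]) > r:
                            ok = False
                            break
                    if ok:
                        b += 1
                        comps += 1
                        if abs(x[i + m] - x[j + m]) <= r:
                            a += 1
            v += 1
    return b, a, comps


def count_matches_bucket(
    series: TimeSeries, m: int, r_abs: float, rsplit: int = 5
) -> MatchCounts:
    """Count similar template pairs with bucket-assisted pruning."""
    x = _validate(series, m, r_abs)
    grid = build_buckets(_integrate(x, m), as_series(series), r_abs, rsplit)
    b, a, comps = _count_bucket(
        x, m, float(r_abs), grid.members, grid.uids, grid.ustart, np.int64(grid.span)
    )
    return MatchCounts(b_pairs=int(b), a_pairs=int(a), element_comparisons=int(comps))
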