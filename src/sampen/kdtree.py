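"""Incremental kd-tree backend: range-search before insert.

Templates are processed in series order.  Each template is first
range-searched against the kd-tree of previously inserted templates (so
every unordered pair is examined exactly once and self-matches can never
occur), and only then inserted.  A node at level ``lv`` discriminates on
coordinate ``lv mod m``; ties descend to the right subtree, and a range
search visits both children whenever the query interval straddles the
node's discriminating value, so the tie rule cannot affect the counts.

The tree is array-backed — three parallel integer arrays holding the
template start index and the left/right child of each node — and both
insertion and search are iterative (the search keeps an explicit stack).
No rebalancing is performed; insertion order is series order, so sorted
inputs degenerate the tree (accepted and documented).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import MatchCounts, TimeSeries, as_series
from .bruteforce import _validate

__all__ = ["KdTree", "count_matches_kdtree"]

_NO_CHILD = -1


@njit(cache=True)
def _kd_insert(x, m, payload, left, right, size, root, t):  # pragma: no cover
    if root < 0:
        payload[0] = t
        return np.int64(1), np.int64(0)
    node = root
    lv = 0
    while True:
        k = lv % m
        if x[t + k] < x[payload[node] + k]:
            if left[node] < 0:
                left[node] = size
                payload[size] = t
                return size + np.int64(1), np.int64(root)
            node = left[node]
        else:
            if right[node] < 0:
                right[node] = size
                payload[size] = t
                return size + np.int64(1), np.int64(root)
            node = right[node]
        lv += 1


@njit(cache=True)
def _kd_range(x, m, r, payload, left, right, root, t, stack):  # pragma: no cover
    tb = np.int64(0)
    ta = np.int64(0)
    visited = np.int64(0)
    comps = np.int64(0)
    if root < 0:
        return tb, ta, visited, comps
    sp = 0
    stack[sp, 0] = root
    stack[sp, 1] = 0
    sp = 1
    while sp > 0:
        sp -= 1
        node = stack[sp, 0]
        lv = stack[sp, 1]
        visited += 1
        j = payload[node]
        ok = True
        for k in range(m):
            comps += 1
            if abs(x[t + k] - x[j + k]) > r:
                ok = False
                break
        if ok:
            tb += 1
            comps += 1
            if abs(x[t + m] - x[j + m]) <= r:
                ta += 1
        # Pruning uses the same subtraction-and-compare expression as the
        # verification step: left-subtree values are < c, and floating-point
        # subtraction is monotone, so q - c > r proves every left descendant
        # fails on this coordinate (symmetrically for the right subtree).
        k = lv % m
        c = x[j + k]
        q = x[t + k]
        child = left[node]
        if child >= 0 and (c >= q or q - c <= r):
            stack[sp, 0] = child
            stack[sp, 1] = lv + 1
            sp += 1
        child = right[node]
        if child >= 0 and (c <= q or c - q <= r):
            stack[sp, 0] = child
            stack[sp, 1] = lv + 1
            sp += 1
    return tb, ta, visited, comps


class KdTree:
    """Array-backed kd-tree over length-``m`` templates of a series.

    Node payloads are template start indices (0-based) into the raw series;
    coordinates are read from the series on demand, so nothing is copied.
    """

    def __init__(self, series: TimeSeries, m: int, capacity: int | None = None):
        series = as_series(series)
        if m < 1:
            raise ValueError("m must be >= 1")
        self.x = series.values
        self.m = int(m)
        cap = int(capacity) if capacity is not None else series.n - m
        if cap < 1:
            raise ValueError("capacity must be positive")
        self.payload = np.full(cap, _NO_CHILD, dtype=np.int64)
        self.left = np.full(cap, _NO_CHILD, dtype=np.int64)
        self.right = np.full(cap, _NO_CHILD, dtype=np.int64)
        self._stack = np.empty((cap + 1, 2), dtype=np.int64)
        self.size = 0
        self.root = _NO_CHILD

    def __len__(self) -> int:
        return self.size

    def insert(self, t: int) -> None:
        """Insert the template starting at 0-based index *t*."""
        if self.size >= self.payload.shape[0]:
            raise ValueError("kd-tree capacity exceeded")
        size, root = _kd_insert(
            self.x, self.m, self.payload, self.left, self.right,
            np.int64(self.size), np.int64(self.root), np.int64(t),
        )
        self.size = int(size)
        self.root = int(root)

    def range_count(self, t: int, r_abs: float):
        """Count stored templates within ``r_abs`` of the query template *t*.

        Returns ``(tb, ta, visited, comps)``: matches at length m, matches at
        length m + 1, candidate nodes visited, and scalar comparisons made.
        The query template must not be in the tree (search-before-insert).
        """
        tb, ta, visited, comps = _kd_range(
            self.x, self.m, float(r_abs), self.payload, self.left, self.right,
            np.int64(self.root), np.int64(t), self._stack,
        )
        return int(tb), int(ta), int(visited), int(comps)


def count_matches_kdtree(series: TimeSeries, m: int, r_abs: float) -> MatchCounts:
    """Count similar template pairs with the incremental kd-tree sweep."""
    x = _validate(series, m, r_abs)
    t_count = x.shape[0] - m
    tree = KdTree(as_series(series), m, capacity=t_count)
    b = a = comps = visited = 0
    for t in range(t_count):
        tb, ta, vis, c = tree.range_count(t, r_abs)
        b += tb
        a += ta
        visited += vis
        comps += c
        tree.insert(t)
    return MatchCounts(
        b_pairs=b, a_pairs=a, element_comparisons=comps, nodes_visited=visited
    )
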