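"""Sample Entropy: definition, parameters, and backend-independent assembly.

Sample Entropy (SampEn) measures the regularity of a univariate time series
``x = x_1, ..., x_N``.  Two length-``m`` templates

    x⃗_i = (x_i, ..., x_{i+m-1})

are *similar* when every pair of corresponding elements differs by at most a
tolerance ``r`` (the maximum / Chebyshev norm).  Let ``B`` be the number of
unordered template pairs similar at length ``m`` and ``A`` the subset of those
pairs that remain similar when both templates are extended by one element.
Then

    SampEn(m, r) = -ln(A / B) = ln(B / A)

with self-matches excluded.  When ``A = 0`` the entropy is infinite.

This module owns the parameter handling, the similarity predicate, and the
assembly of a :class:`SampEnResult` from raw match counts.  The actual pair
counting is delegated to one of four interchangeable backends (brute force,
incremental kd-tree, bucket-assisted, lightweight sorted-series) that are
guaranteed to return identical integer counts and therefore the identical
entropy value.

Conventions shared by every backend:

* exactly ``N - m`` templates are enumerated for both the length-``m`` and
  length-``m+1`` counts, so the one-element extension always exists;
* the similarity inequality is non-strict (``<= r``) in every comparison;
* each unordered pair is counted once;
* reported probabilities ``B^m(r)`` and ``A^m(r)`` are normalised by
  ``(N - m)^2``; any constant normalisation cancels in the ratio, so the
  entropy itself does not depend on this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "INFINITE",
    "BACKENDS",
    "TimeSeries",
    "SampEnParams",
    "MatchCounts",
    "SampEnResult",
    "as_series",
    "resolve_tolerance",
    "templates_similar",
    "sampen_from_counts",
    "compute_sampen",
    "sample_entropy",
]

#: Distinguished value reported when the entropy is undefined (A = 0).
INFINITE = math.inf

#: Identifiers of the four counting backends, in reference order.
BACKENDS = ("bruteforce", "kdtree", "bucket", "lightweight")

_R_MODES = ("absolute", "sd_fraction")


@dataclass(frozen=True)
class TimeSeries:
    """A univariate real-valued series (typically RR intervals in msec).

    The values are coerced to a contiguous float64 array and must all be
    finite.  Any SampEn computation additionally requires ``n >= m + 2`` so
    that at least two templates of length ``m + 1`` exist.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("series must be one-dimensional")
        if v.size == 0:
            raise ValueError("series is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def sample_sd(self) -> float:
        """Sample standard deviation with the (N - 1) denominator."""
        if self.n < 2:
            raise ValueError("sample SD requires at least two values")
        return float(np.std(self.values, ddof=1))


def as_series(x: Union[TimeSeries, Sequence[float], np.ndarray]) -> TimeSeries:
    """Coerce an array-like into a :class:`TimeSeries` (no copy if already one)."""
    return x if isinstance(x, TimeSeries) else TimeSeries(np.asarray(x, dtype=float))


def resolve_tolerance(series: TimeSeries, r_input: float, r_mode: str) -> float:
    """Resolve the tolerance to an absolute value.

    ``absolute`` returns ``r_input`` unchanged; ``sd_fraction`` scales it by
    the sample standard deviation of the series (the HRV convention behind
    the typical choice r = 0.2).
    """
    if r_input <= 0:
        raise ValueError("tolerance must be positive")
    if r_mode == "absolute":
        return float(r_input)
    if r_mode == "sd_fraction":
        sd = as_series(series).sample_sd()
        if sd == 0.0:
            raise ValueError(
                "sd_fraction tolerance is undefined for a constant series "
                "(sample SD is zero); use an absolute tolerance instead"
            )
        return float(r_input) * sd
    raise ValueError(f"unknown tolerance mode {r_mode!r}; expected one of {_R_MODES}")


@dataclass(frozen=True)
class SampEnParams:
    """Resolved SampEn parameters.

    Attributes
    ----------
    m : embedding dimension (template length), typically 1-3 for HRV.
    r_input : the tolerance as given by the caller.
    r_mode : ``"absolute"`` or ``"sd_fraction"``.
    r_abs : the resolved absolute tolerance actually used in comparisons.
    rsplit : bucket split factor (bucket-assisted backend only).  Each
        width-``r`` bucket is subdivided into ``rsplit`` smaller buckets;
        the default of 5 is a robust general-purpose choice.
    """

    m: int
    r_input: float
    r_mode: str
    r_abs: float
    rsplit: int = 5

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_input <= 0 or self.r_abs <= 0:
            raise ValueError("tolerance must be positive")
        if self.r_mode not in _R_MODES:
            raise ValueError(f"unknown tolerance mode {self.r_mode!r}")
        if self.rsplit < 1:
            raise ValueError("rsplit must be >= 1")

    @classmethod
    def create(
        cls,
        series: TimeSeries,
        m: int,
        r: float,
        r_mode: str = "sd_fraction",
        rsplit: int = 5,
    ) -> "SampEnParams":
        """Build parameters for *series*, resolving the tolerance."""
        r_abs = resolve_tolerance(as_series(series), r, r_mode)
        return cls(m=int(m), r_input=float(r), r_mode=r_mode, r_abs=r_abs, rsplit=int(rsplit))


@dataclass(frozen=True)
class MatchCounts:
    """Unordered-pair similarity counters plus instrumentation.

    ``b_pairs`` counts unordered template pairs (i, j), i < j, similar in m
    dimensions; ``a_pairs`` the subset also similar in m + 1 dimensions.
    ``element_comparisons`` tallies every explicit scalar tolerance check
    ``|x_p - x_q| <= r`` a backend performed — the hardware-independent
    measure of work.  Steps of a binary search over a sorted array are not
    tallied (they locate candidates without testing the tolerance predicate
    element-wise).

    ``per_template``, when present, is an (N - m, 2) array of the ordered
    per-template counts (n_i^m, n_i^{m+1}); each unordered pair contributes
    to two templates, so each column sums to twice the pair count.
    ``nodes_visited`` is kd-tree-specific instrumentation (candidate nodes
    examined during range searches).
    """

    b_pairs: int
    a_pairs: int
    element_comparisons: int = 0
    per_template: Optional[np.ndarray] = None
    nodes_visited: Optional[int] = None

    def __post_init__(self) -> None:
        if self.a_pairs < 0 or self.b_pairs < 0 or self.element_comparisons < 0:
            raise ValueError("counts must be non-negative")
        if self.a_pairs > self.b_pairs:
            raise ValueError("a_pairs cannot exceed b_pairs")


@dataclass(frozen=True)
class SampEnResult:
    """The entropy value together with the counts and parameters behind it.

    ``value`` equals ``ln(b_pairs / a_pairs)`` whenever both counts are
    positive, and :data:`INFINITE` otherwise.  ``degenerate_flag`` is
    ``"none"`` for a regular result, ``"a_zero"`` when no template pair
    remained similar after extension, and ``"a_zero,b_zero"`` when no pair
    was similar even at length m (the latter implies the former).
    """

    value: float
    a_norm: float
    b_norm: float
    counts: MatchCounts
    params: SampEnParams
    algorithm: str
    degenerate_flag: str
    n: int

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.value)


def templates_similar(
    series: TimeSeries, i: int, j: int, m: int, r_abs: float
) -> bool:
    """Chebyshev similarity of the length-``m`` templates at 0-based starts i, j.

    True iff ``|x[i+k] - x[j+k]| <= r_abs`` for every ``k = 0..m-1``.  The
    check short-circuits on the first failing coordinate.  Self-comparison
    (``i == j``) is rejected: self-matches are excluded from SampEn.
    """
    series = as_series(series)
    x = series.values
    last = series.n - m
    if not (0 <= i <= last) or not (0 <= j <= last):
        raise IndexError(f"template start out of range (valid 0..{last})")
    if i == j:
        raise ValueError("self-comparison is excluded from Sample Entropy")
    for k in range(m):
        if abs(x[i + k] - x[j + k]) > r_abs:
            return False
    return True


def _degenerate_flag(a_pairs: int, b_pairs: int) -> str:
    if b_pairs == 0:
        return "a_zero,b_zero"
    if a_pairs == 0:
        return "a_zero"
    return "none"


def sampen_from_counts(
    counts: MatchCounts,
    n: int,
    m: int,
    params: Optional[SampEnParams] = None,
    algorithm: str = "",
) -> SampEnResult:
    """Assemble a :class:`SampEnResult` from raw match counts.

    The normalisation constants cancel in the ratio, so the entropy is
    computed directly as ``ln(b_pairs / a_pairs)``; the reported
    probabilities divide both counters by ``(N - m)^2``.
    """
    t = n - m
    if t < 2:
        raise ValueError("series too short: need n >= m + 2")
    denom = float(t) * float(t)
    a_norm = counts.a_pairs / denom
    b_norm = counts.b_pairs / denom
    flag = _degenerate_flag(counts.a_pairs, counts.b_pairs)
    if counts.a_pairs > 0:
        value = math.log(counts.b_pairs / counts.a_pairs)
    else:
        value = INFINITE
    if params is None:
        params = SampEnParams(m=m, r_input=1.0, r_mode="absolute", r_abs=1.0)
    return SampEnResult(
        value=value,
        a_norm=a_norm,
        b_norm=b_norm,
        counts=counts,
        params=params,
        algorithm=algorithm,
        degenerate_flag=flag,
        n=n,
    )


def _count_with_backend(
    name: str, series: TimeSeries, params: SampEnParams
) -> MatchCounts:
    # Imported lazily: the backend modules depend on the types defined here.
    if name == "bruteforce":
        from .bruteforce import count_matches_bruteforce

        return count_matches_bruteforce(series, params.m, params.r_abs)
    if name == "kdtree":
        from .kdtree import count_matches_kdtree

        return count_matches_kdtree(series, params.m, params.r_abs)
    if name == "bucket":
        from .bucket import count_matches_bucket

        return count_matches_bucket(series, params.m, params.r_abs, params.rsplit)
    if name == "lightweight":
        from .lightweight import count_matches_lightweight

        return count_matches_lightweight(series, params.m, params.r_abs)
    raise ValueError(f"unknown backend {name!r}; expected one of {BACKENDS + ('auto',)}")


def compute_sampen(
    series: Union[TimeSeries, Sequence[float], np.ndarray],
    params: SampEnParams,
    algorithm: str = "auto",
) -> SampEnResult:
    """Compute SampEn with the named backend (or an automatic choice).

    ``algorithm="auto"`` applies the selection policy of
    :func:`sampen.bench.select_algorithm`.  Every backend returns identical
    (a_pairs, b_pairs) and hence an identical entropy value; they differ
    only in how many comparisons they avoid.
    """
    series = as_series(series)
    if series.n < params.m + 2:
        raise ValueError(
            f"series too short: n={series.n} but n >= m + 2 = {params.m + 2} required"
        )
    if algorithm == "auto":
        from .bench import select_algorithm

        algorithm = select_algorithm(series.n, params.m)
    counts = _count_with_backend(algorithm, series, params)
    return sampen_from_counts(counts, series.n, params.m, params=params, algorithm=algorithm)


def sample_entropy(
    values: Union[TimeSeries, Sequence[float], np.ndarray],
    m: int = 2,
    r: float = 0.2,
    r_mode: str = "sd_fraction",
    algorithm: str = "auto",
    rsplit: int = 5,
) -> SampEnResult:
    """One-call convenience wrapper around :func:`compute_sampen`."""
    series = as_series(values)
    params = SampEnParams.create(series, m=m, r=r, r_mode=r_mode, rsplit=rsplit)
    return compute_sampen(series, params, algorithm=algorithm)
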