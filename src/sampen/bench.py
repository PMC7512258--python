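"""Algorithm selection policy, cross-backend self-check, benchmark harness.

The selection policy transcribes the empirical findings on RR data: the
lightweight backend wins for m = 1 at any length and for series up to about
3000 beats, while the bucket-assisted backend wins for long series.  The
crossover depends on hardware and signal variability and is therefore a
configurable heuristic, not a guarantee.

Timings reported by the benchmark harness are informational only; the
hardware-independent efficiency signal is the instrumented comparison
count, which every report carries alongside the elapsed time.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    BACKENDS,
    MatchCounts,
    SampEnParams,
    TimeSeries,
    as_series,
    sampen_from_counts,
)
from . import bruteforce, bucket, kdtree, lightweight
from . import synthetic

__all__ = ["select_algorithm", "self_check", "SelfCheckReport", "run_benchmark"]

#: Default series length above which the bucket-assisted backend is chosen.
DEFAULT_CROSSOVER = 3000

BackendFunc = Callable[[TimeSeries, int, float, int], MatchCounts]


def _run_backend(name: str, series: TimeSeries, m: int, r_abs: float, rsplit: int) -> MatchCounts:
    if name == "bruteforce":
        return bruteforce.count_matches_bruteforce(series, m, r_abs)
    if name == "kdtree":
        return kdtree.count_matches_kdtree(series, m, r_abs)
    if name == "bucket":
        return bucket.count_matches_bucket(series, m, r_abs, rsplit)
    if name == "lightweight":
        return lightweight.count_matches_lightweight(series, m, r_abs)
    raise ValueError(f"unknown backend {name!r}")


def select_algorithm(n: int, m: int, crossover: int = DEFAULT_CROSSOVER) -> str:
    """Deterministic backend choice for a series of length *n* at dimension *m*.

    m = 1 -> lightweight (always); otherwise lightweight up to the crossover
    length and bucket-assisted beyond it.
    """
    if m == 1:
        return "lightweight"
    if n <= crossover:
        return "lightweight"
    return "bucket"


@dataclass(frozen=True)
class SelfCheckReport:
    """Outcome of running all backends on one input.

    ``passed`` is true iff every backend produced identical
    (a_pairs, b_pairs).  On failure ``divergence`` localises the problem:
    the shortest series prefix on which a backend's counts differ from the
    exhaustive enumeration, together with the enumerated pairs involving
    the template introduced by that prefix.
    """

    passed: bool
    counts: Dict[str, Tuple[int, int]]
    values: Dict[str, float]
    divergence: Optional[str] = None

    def summary(self) -> str:
        lines = ["self-check: " + ("PASS" if self.passed else "FAIL")]
        for name, (a, b) in self.counts.items():
            lines.append(
                f"  {name:12s} a_pairs={a} b_pairs={b} sampen={self.values[name]}"
            )
        if self.divergence:
            lines.append(self.divergence)
        return "\n".join(lines)


def _oracle_pairs(x: np.ndarray, m: int, r: float):
    """Pure-Python exhaustive enumeration of m-similar unordered pairs."""
    t = x.shape[0] - m
    b_pairs = []
    a = 0
    for i in range(t):
        for j in range(i + 1, t):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b_pairs.append((i, j))
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return b_pairs, a


def _localize(
    series: TimeSeries,
    m: int,
    r_abs: float,
    rsplit: int,
    name: str,
    func: BackendFunc,
) -> str:
    x = series.values
    for length in range(m + 2, series.n + 1):
        prefix = TimeSeries(x[:length].copy())
        pairs, a = _oracle_pairs(prefix.values, m, r_abs)
        got = func(prefix, m, r_abs, rsplit)
        if (got.b_pairs, got.a_pairs) != (len(pairs), a):
            newest = length - m - 1  # template introduced by this prefix
            involved = [p for p in pairs if newest in p]
            return (
                f"  divergence: backend {name!r} first differs on prefix of "
                f"length {length} (expected b={len(pairs)}, a={a}; got "
                f"b={got.b_pairs}, a={got.a_pairs}); enumerated pairs involving "
                f"template {newest}: {involved}"
            )
    return f"  divergence: backend {name!r} differs on the full series only"


def self_check(
    series: TimeSeries,
    m: int,
    r_abs: float,
    rsplit: int = 5,
    backends: Optional[Mapping[str, BackendFunc]] = None,
) -> SelfCheckReport:
    """Run every backend and verify that all counts agree.

    ``backends`` may replace or extend the stock set (used for mutation
    testing); each callable takes (series, m, r_abs, rsplit).  Failure is a
    report, not an exception.
    """
    series = as_series(series)
    if backends is None:
        backends = {
            name: (lambda s, mm, rr, sp, _n=name: _run_backend(_n, s, mm, rr, sp))
            for name in BACKENDS
        }
    counts: Dict[str, Tuple[int, int]] = {}
    values: Dict[str, float] = {}
    results: Dict[str, MatchCounts] = {}
    for name, func in backends.items():
        mc = func(series, m, r_abs, rsplit)
        results[name] = mc
        counts[name] = (mc.a_pairs, mc.b_pairs)
        values[name] = sampen_from_counts(mc, series.n, m).value
    distinct = set(counts.values())
    if len(distinct) == 1:
        return SelfCheckReport(passed=True, counts=counts, values=values)
    # Localise against the exhaustive enumeration.
    pairs, a = _oracle_pairs(series.values, m, r_abs)
    reference = (a, len(pairs))
    messages = []
    for name, func in backends.items():
        if counts[name] != reference:
            messages.append(_localize(series, m, r_abs, rsplit, name, func))
    return SelfCheckReport(
        passed=False,
        counts=counts,
        values=values,
        divergence="\n".join(messages) if messages else None,
    )


def run_benchmark(
    presets: Sequence[str] = ("nsr2f",),
    n_values: Sequence[int] = (1000,),
    mr_pairs: Sequence[Tuple[int, float]] = ((2, 0.2),),
    r_mode: str = "sd_fraction",
    rsplit_values: Sequence[int] = (5,),
    repetitions: int = 3,
    algorithms: Sequence[str] = BACKENDS,
    seed: int = 0,
) -> pd.DataFrame:
    """Time every backend over a grid of synthetic inputs.

    One synthetic series is generated per (preset, n) cell.  The timer
    wraps the counting call only (series generation, parameter resolution
    and result assembly are excluded), each backend gets one untimed
    warm-up call, and the reported elapsed time is the mean over
    ``repetitions`` runs.  ``speedup`` is the straightforward backend's
    mean time divided by the backend's mean time (NaN when the
    straightforward backend is not part of the grid).  Timings are
    hardware-dependent; ``element_comparisons`` is the portable signal.
    """
    rows = []
    for preset_name in presets:
        for n in n_values:
            series = synthetic.generate(synthetic.preset(preset_name, n, seed=seed))
            for m, r in mr_pairs:
                params0 = SampEnParams.create(series, m=m, r=r, r_mode=r_mode)
                for rsplit in rsplit_values:
                    timings: Dict[str, float] = {}
                    for name in algorithms:
                        _run_backend(name, series, m, params0.r_abs, rsplit)  # warm-up
                        elapsed = []
                        mc = None
                        for _ in range(max(1, repetitions)):
                            t0 = time.perf_counter()
                            mc = _run_backend(name, series, m, params0.r_abs, rsplit)
                            elapsed.append(time.perf_counter() - t0)
                        mean_t = float(np.mean(elapsed))
                        timings[name] = mean_t
                        result = sampen_from_counts(mc, series.n, m)
                        rows.append(
                            {
                                "dataset": preset_name,
                                "n": n,
                                "m": m,
                                "r_input": r,
                                "r_mode": r_mode,
                                "rsplit": rsplit,
                                "algorithm": name,
                                "elapsed_s": mean_t,
                                "element_comparisons": mc.element_comparisons,
                                "b_pairs": mc.b_pairs,
                                "a_pairs": mc.a_pairs,
                                "sampen": result.value,
                            }
                        )
                    base = timings.get("bruteforce", float("nan"))
                    for row in rows[-len(algorithms):]:
                        row["speedup"] = base / row["elapsed_s"]
    frame = pd.DataFrame(rows)
    frame.attrs["note"] = (
        "elapsed_s/speedup are hardware-dependent and informational; "
        "element_comparisons is the portable efficiency measure"
    )
    return frame
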