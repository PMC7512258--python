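"""Seeded generators of RR-like series for testing and benchmarking.

Real 24-hour Holter RR series are not redistributable, so the generators
here are statistical surrogates: their contract is the first two moments
(plus seedability), not physiological fidelity.  The four presets mirror the
mean/SD profiles of the healthy (nsr2) and congestive-heart-failure (chf2)
Holter populations commonly used to benchmark SampEn implementations, in
raw and ectopic-filtered (``*f``) variants:

    nsr2   mean 809 ms, SD 204 ms   (with injected ectopic beats)
    chf2   mean 681 ms, SD 369 ms   (with injected ectopic beats)
    nsr2f  mean 807 ms, SD 156 ms
    chf2f  mean 667 ms, SD  45 ms

The base process for the presets is a stationary AR(1) with lag-one
correlation 0.7 — short-range positive autocorrelation being the dominant
feature of RR series that matters for match counting.  Ectopic beats are
emulated by multiplying randomly chosen intervals by a fixed factor; rate
and factor are invented plumbing, documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries

__all__ = ["GeneratorSpec", "generate", "preset", "PRESET_NAMES"]

_KINDS = ("gaussian_iid", "ar1", "constant", "ramp", "mixture")

_PRESETS = {
    # name: (mean ms, sd ms, ectopic_rate, ectopic_scale)
    "nsr2": (809.0, 204.0, 0.01, 1.5),
    "chf2": (681.0, 369.0, 0.03, 1.7),
    "nsr2f": (807.0, 156.0, 0.0, 1.5),
    "chf2f": (667.0, 45.0, 0.0, 1.5),
}

PRESET_NAMES = tuple(_PRESETS)

_SQRT3 = float(np.sqrt(3.0))


@dataclass(frozen=True)
class GeneratorSpec:
    """Fully determined recipe for one synthetic series.

    ``kind`` selects the base process; ``mean``/``sd`` are its target
    marginal moments (msec for RR-like presets).  ``phi`` is the AR(1)
    coefficient (ar1 only).  With probability ``ectopic_rate`` an interval
    is multiplied by ``ectopic_scale`` after the base series is drawn,
    emulating the outliers that inflate the variance of unfiltered HRV
    recordings.  An identical spec (including ``seed``) always produces an
    identical series.
    """

    kind: str
    n: int
    mean: float
    sd: float
    phi: float = 0.0
    ectopic_rate: float = 0.0
    ectopic_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {_KINDS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.kind == "ar1" and not (-1.0 < self.phi < 1.0):
            raise ValueError("AR(1) coefficient phi must lie in (-1, 1)")
        if not (0.0 <= self.ectopic_rate < 1.0):
            raise ValueError("ectopic_rate must lie in [0, 1)")
        if self.ectopic_rate > 0 and self.ectopic_scale <= 1.0:
            raise ValueError("ectopic_scale must exceed 1 when ectopics are injected")


def _base_series(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    n, mean, sd = spec.n, spec.mean, spec.sd
    if spec.kind == "constant":
        return np.full(n, mean, dtype=float)
    if spec.kind == "ramp":
        if n == 1:
            return np.full(1, mean, dtype=float)
        half = _SQRT3 * sd
        return np.linspace(mean - half, mean + half, n)
    if spec.kind == "gaussian_iid":
        return mean + sd * rng.standard_normal(n)
    if spec.kind == "ar1":
        phi = spec.phi
        z = np.empty(n, dtype=float)
        z[0] = sd * rng.standard_normal()
        innov_sd = sd * np.sqrt(1.0 - phi * phi)
        eps = innov_sd * rng.standard_normal(n)
        for t in range(1, n):
            z[t] = phi * z[t - 1] + eps[t]
        return mean + z
    if spec.kind == "mixture":
        # equal-weight two-component normal with marginal SD equal to sd:
        # components at mean +- 0.8 sd with component SD 0.6 sd
        comp = rng.integers(0, 2, size=n)
        centers = mean + (2.0 * comp - 1.0) * 0.8 * sd
        return centers + 0.6 * sd * rng.standard_normal(n)
    raise AssertionError("unreachable")


def generate(spec: GeneratorSpec) -> TimeSeries:
    """Draw the series described by *spec* (deterministic given the seed).

    ``mean`` is the target marginal mean *including* ectopics: scaling a
    fraction q of the intervals by s multiplies the expectation by
    1 + q(s - 1), so the base process is drawn around mean / (1 + q(s - 1)).
    Ectopic injection still adds a few percent of variance on top of the
    base SD, as real unfiltered recordings do.
    """
    rng = np.random.default_rng(spec.seed)
    q, s = spec.ectopic_rate, spec.ectopic_scale
    if q > 0.0:
        base_mean = spec.mean / (1.0 + q * (s - 1.0))
        base = GeneratorSpec(
            kind=spec.kind, n=spec.n, mean=base_mean, sd=spec.sd, phi=spec.phi,
            seed=spec.seed,
        )
        x = _base_series(base, rng).copy()
        mask = rng.random(spec.n) < q
        x[mask] *= s
    else:
        x = _base_series(spec, rng)
    return TimeSeries(x)


def preset(name: str, n: int, seed: int = 0) -> GeneratorSpec:
    """The generator spec for one of the named RR-profile presets.

    Unfiltered presets (nsr2, chf2) carry a nonzero ectopic rate, so that
    :func:`sampen.signal_io.filter_ectopics` meaningfully reduces their SD;
    the filtered presets are ectopic-free.
    """
    try:
        mean, sd, rate, scale = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
        ) from None
    return GeneratorSpec(
        kind="ar1",
        n=n,
        mean=mean,
        sd=sd,
        phi=0.7,
        ectopic_rate=rate,
        ectopic_scale=scale,
        seed=seed,
    )
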