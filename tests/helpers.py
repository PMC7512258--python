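"""Independent pure-Python oracle used to cross-check every backend.

Deliberately naive: exhaustive enumeration straight from the definition,
sharing no code with the package's counting kernels.
"""

from __future__ import annotations

import numpy as np

TOY = [1.0, 2.0, 1.0, 2.0, 1.0, 3.0]


def oracle_counts(x, m, r):
    """Exhaustive (b_pairs, a_pairs) over unordered template pairs."""
    x = [float(v) for v in x]
    t = len(x) - m
    b = a = 0
    for i in range(t):
        for j in range(i + 1, t):
            if all(abs(x[i + k] - x[j + k]) <= r for k in range(m)):
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return b, a


def oracle_pairs(x, m, r):
    """The unordered pairs similar at length m."""
    x = [float(v) for v in x]
    t = len(x) - m
    return [
        (i, j)
        for i in range(t)
        for j in range(i + 1, t)
        if all(abs(x[i + k] - x[j + k]) <= r for k in range(m))
    ]


def ar1_series(rng, n, phi=0.9, mean=0.0, sd=1.0):
    z = np.empty(n)
    z[0] = rng.standard_normal()
    for t in range(1, n):
        z[t] = phi * z[t - 1] + np.sqrt(1 - phi * phi) * rng.standard_normal()
    return mean + sd * z
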