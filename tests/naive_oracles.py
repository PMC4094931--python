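"""Literal loop transcriptions of the defining estimator formulas.

These deliberately naive implementations are the independent oracles the
optimized kernel-matrix code is pinned against; they must stay free of any
import from the production modules.
"""

import math


def naive_kde1(sample, h, q):
    n = len(sample)
    s = 0.0
    for xi in sample:
        s += math.exp(-((q - xi) ** 2) / (2 * h * h))
    return s / (math.sqrt(2 * math.pi) * n * h)


def naive_kde2(x, y, h, qx, qy):
    n = len(x)
    s = 0.0
    for xi, yi in zip(x, y):
        s += math.exp(-((qx - xi) ** 2 + (qy - yi) ** 2) / (2 * h * h))
    return s / (2 * math.pi * n * h * h)


def naive_mi(x, y, h):
    n = len(x)
    total = 0.0
    for j in range(n):
        fxy = naive_kde2(x, y, h, x[j], y[j])
        total += math.log(fxy / (naive_kde1(x, h, x[j]) * naive_kde1(y, h, y[j])))
    return total / n
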