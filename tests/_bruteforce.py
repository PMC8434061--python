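"""Independent brute-force reference implementations for the feature oracles.

Written deliberately in plain Python loops / naive formulas so they share no
code path with the package implementation.
"""

import cmath
import math


def mean(s):
    return sum(s) / len(s)


def pop_std(s):
    m = mean(s)
    return math.sqrt(sum((x - m) ** 2 for x in s) / len(s))


def _median(values):
    v = sorted(values)
    n = len(v)
    mid = n // 2
    return v[mid] if n % 2 else (v[mid - 1] + v[mid]) / 2


def mad(s):
    m = _median(s)
    return _median([abs(x - m) for x in s])


def energy(s):
    return sum(x * x for x in s) / len(s)


def entropy(s):
    a = [abs(x) for x in s]
    total = sum(a)
    if total == 0:
        return 0.0
    out = 0.0
    for x in a:
        c = x / total
        if c > 0:
            out += c * math.log(c)
    return out


def quantile(s, p):
    """Linear interpolation between order statistics at position p*(N-1)."""
    v = sorted(s)
    pos = p * (len(v) - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def iqr(s):
    return quantile(s, 0.75) - quantile(s, 0.25)


def rms(s):
    return math.sqrt(sum(x * x for x in s) / len(s))


def value_range(s):
    return max(s) - min(s)


def skewness(s):
    m = mean(s)
    sd = pop_std(s)
    if sd == 0:
        return 0.0
    return sum(((x - m) / sd) ** 3 for x in s) / len(s)


def kurtosis(s):
    m = mean(s)
    m2 = sum((x - m) ** 2 for x in s) / len(s)
    if m2 == 0:
        return 0.0
    m4 = sum((x - m) ** 4 for x in s) / len(s)
    return m4 / (m2 * m2)


def dft_magnitudes(s):
    """Naive DFT magnitudes of the mean-subtracted signal, bins 1..N/2."""
    n = len(s)
    m = mean(s)
    x = [v - m for v in s]
    out = []
    for k in range(1, n // 2 + 1):
        acc = sum(x[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        out.append(abs(acc))
    return out


def max_freq_ind(bins):
    best = max(bins)
    for i, v in enumerate(bins, start=1):
        if v == best:
            return i


def mean_freq(bins):
    total = sum(bins)
    if total == 0:
        return 0.0
    return sum(i * v for i, v in enumerate(bins, start=1)) / total


def energy_band(bins, a, b):
    return sum(v * v for v in bins[a - 1 : b]) / (b - a + 1)


def majority_with_priority(codes):
    """Most frequent code; ties broken nodding(1) > speaking(2) > other(0)."""
    counts = {}
    for c in codes:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    tied = [c for c, n in counts.items() if n == best]
    for preferred in (1, 2, 0):
        if preferred in tied:
            return preferred
    return min(tied)
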