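"""Independent brute-force stratum-adjusted correlation for cross-checking.

Everything here is computed with explicit loops and textbook formulas:
window means cell by cell, diagonals by index arithmetic, Pearson from raw
sums, average ranks from sorted positions. No code is shared with the
package implementation.
"""

import math

import numpy as np


def brute_smooth(mat: np.ndarray, h: int) -> np.ndarray:
    n = mat.shape[0]
    out = np.zeros_like(mat, dtype=float)
    for i in range(n):
        for j in range(n):
            total, count = 0.0, 0
            for a in range(max(0, i - h), min(n, i + h + 1)):
                for b in range(max(0, j - h), min(n, j + h + 1)):
                    total += mat[a, b]
                    count += 1
            out[i, j] = total / count
    return out


def _pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # ranks are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _variance(values):
    m = sum(values) / len(values)
    return sum((v - m) ** 2 for v in values) / len(values)


def brute_force_scc(mat_a: np.ndarray, mat_b: np.ndarray, h: int, max_k: int) -> float:
    sa = brute_smooth(np.asarray(mat_a, dtype=float), h)
    sb = brute_smooth(np.asarray(mat_b, dtype=float), h)
    n = sa.shape[0]
    num, den = 0.0, 0.0
    for k in range(min(max_k, n - 1) + 1):
        xs = [sa[i, i + k] for i in range(n - k)]
        ys = [sb[i, i + k] for i in range(n - k)]
        if len(xs) < 2 or _variance(xs) == 0 or _variance(ys) == 0:
            continue
        rho = _pearson(xs, ys)
        w = len(xs) * math.sqrt(_variance(_average_ranks(xs)) *
                                _variance(_average_ranks(ys)))
        num += w * rho
        den += w
    if den == 0:
        raise ValueError("no usable stratum")
    return num / den
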