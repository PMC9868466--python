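"""Independent brute-force oracles used only by the tests.

Pure-Python implementations kept deliberately separate from the package's
numpy code paths.
"""

from __future__ import annotations

import math


def pb_slope_enumeration(x, y):
    """Passing-Bablok slope by exhaustive pairwise enumeration.

    Forms every pairwise slope with plain Python loops, drops undefined
    (equal x) and exactly -1 slopes, and returns the median shifted by the
    count of slopes below -1.
    """
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            if dx == 0:
                continue
            s = (y[j] - y[i]) / dx
            if s == -1.0:
                continue
            slopes.append(s)
    if not slopes:
        raise ValueError("no valid slopes")
    slopes.sort()
    big_n = len(slopes)
    k = sum(1 for s in slopes if s < -1.0)
    if big_n % 2 == 1:
        return slopes[(big_n - 1) // 2 + k]
    return (slopes[big_n // 2 - 1 + k] + slopes[big_n // 2 + k]) / 2.0


def ols_closed_form(x, y):
    """Simple-regression slope/intercept/R^2 from the textbook sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    syy = sum((yi - my) ** 2 for yi in y)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = sxy * sxy / (sxx * syy)
    return slope, intercept, r2


def pearson_r(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den
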