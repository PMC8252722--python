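"""Naive pure-Python reference implementations used as independent oracles.

Deliberately primitive: counts via collections.Counter, math.log, brute
force over all ordered pixel pairs for Rao. Never imports the package's
vectorized code paths.
"""

import math
from collections import Counter


def naive_shannon(values):
    n = len(values)
    return -sum(
        (c / n) * math.log(c / n) for c in Counter(values).values()
    )


def naive_renyi(values, alpha):
    n = len(values)
    counts = Counter(values)
    if abs(alpha - 1.0) <= 1e-9:
        return naive_shannon(values)
    if alpha == 0.0:
        return math.log(len(counts))
    s = sum((c / n) ** alpha for c in counts.values())
    return math.log(s) / (1.0 - alpha)


def naive_simpson(values):
    n = len(values)
    return sum((c / n) ** 2 for c in Counter(values).values())


def naive_hill(values, q):
    return math.exp(naive_renyi(values, q))


def naive_rao(values, distance=None):
    """Brute force over all n^2 ordered pixel pairs, times 1/n^2."""
    if distance is None:
        distance = lambda a, b: abs(a - b)
    n = len(values)
    total = 0.0
    for a in values:
        for b in values:
            total += distance(a, b)
    return total / (n * n)


def euclidean(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def naive_window_values(grid, nodata, side, row, col):
    """Clipped-window extraction on a list-of-lists grid; nodata and NaN
    cells are dropped."""
    rows, cols = len(grid), len(grid[0])
    r = side // 2
    out = []
    for rr in range(row - r, row + r + 1):
        for cc in range(col - r, col + r + 1):
            if 0 <= rr < rows and 0 <= cc < cols:
                v = grid[rr][cc]
                if isinstance(v, float) and math.isnan(v):
                    continue
                if nodata is not None and v == nodata:
                    continue
                out.append(v)
    return out


def naive_map(grid, nodata, side, index_fn):
    """Full moving-window map; None marks nodata output cells."""
    rows, cols = len(grid), len(grid[0])
    out = [[None] * cols for _ in range(rows)]
    for row in range(rows):
        for col in range(cols):
            v = grid[row][col]
            focal_bad = (isinstance(v, float) and math.isnan(v)) or (
                nodata is not None and v == nodata
            )
            if focal_bad:
                continue
            out[row][col] = index_fn(naive_window_values(grid, nodata, side, row, col))
    return out
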