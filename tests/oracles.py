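"""Independent brute-force oracles, deliberately written with plain loops
and exact arithmetic so they share no code path with the package."""

import itertools
from fractions import Fraction


def naive_mean(values):
    return sum(values) / len(values)


def naive_two_sample_pvalue(group1, group2):
    """Exhaustive two-sided permutation p-value by explicit enumeration."""
    pooled = list(group1) + list(group2)
    n, n1 = len(pooled), len(group1)
    observed = abs(naive_mean(group1) - naive_mean(group2))
    hits = total = 0
    for chosen in itertools.combinations(range(n), n1):
        chosen = set(chosen)
        a = [pooled[i] for i in range(n) if i in chosen]
        b = [pooled[i] for i in range(n) if i not in chosen]
        total += 1
        if abs(naive_mean(a) - naive_mean(b)) >= observed:
            hits += 1
    return hits / total


def naive_npc_global_pvalue(matrix, n1, combiner="fisher"):
    """Brute-force NPC global p-value.

    ``matrix`` is a list of per-sector observation lists with the n1
    period-1 values first.  Every split of the shared year positions is
    enumerated, partial statistics are ranked into significance levels,
    Fisher-combined per split, and the observed combined value is referred
    to the combined distribution.  Plain loops only.
    """
    import math

    n = len(matrix[0])
    splits = list(itertools.combinations(range(n), n1))
    stats = []
    for chosen in splits:
        chosen = set(chosen)
        row = []
        for series in matrix:
            a = [series[i] for i in range(n) if i in chosen]
            b = [series[i] for i in range(n) if i not in chosen]
            row.append(abs(naive_mean(a) - naive_mean(b)))
        stats.append(row)
    n_splits = len(splits)
    levels = []
    for i in range(n_splits):
        row = []
        for j in range(len(matrix)):
            count = sum(1 for k in range(n_splits) if stats[k][j] >= stats[i][j])
            row.append(count / n_splits)
        levels.append(row)
    if combiner != "fisher":
        raise ValueError("oracle only implements the Fisher combination")
    combined = [-2.0 * sum(math.log(p) for p in row) for row in levels]
    observed = combined[0]  # split (0..n1-1) is the observed assignment
    return sum(1 for c in combined if c >= observed) / n_splits


def naive_median(values):
    """Sort-based median; midpoint average for even lengths."""
    ordered = sorted(values)
    n = len(ordered)
    mid = n // 2
    if n % 2:
        return ordered[mid]
    return (ordered[mid - 1] + ordered[mid]) / 2


def exact_ols_slope(xs, ys):
    """Least-squares slope from the normal equations in exact rationals."""
    xs = [Fraction(x) for x in xs]
    ys = [Fraction(str(y)) for y in ys]
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)
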