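"""Independent loop-based reference implementations used as test oracles.

Everything here is deliberately written with explicit Python loops over
axes and pairs, independent of the vectorized code paths under test.
"""

from __future__ import annotations

import math


def ref_mean(values: list[float]) -> float:
    return sum(values) / len(values)


def ref_pop_std(values: list[float]) -> float:
    m = ref_mean(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / len(values))


def ref_quantile(values: list[float], q: float) -> float:
    """Linear interpolation between order statistics, q at rank q*(N-1)."""
    s = sorted(values)
    rank = q * (len(s) - 1)
    lo = int(math.floor(rank))
    hi = int(math.ceil(rank))
    frac = rank - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def ref_global_stats(matrix: list[list[float]]) -> tuple[float, float, float, float, float]:
    pooled = [v for row in matrix for v in row]
    return (
        ref_mean(pooled),
        ref_pop_std(pooled),
        ref_quantile(pooled, 0.5),
        ref_quantile(pooled, 0.25),
        ref_quantile(pooled, 0.75),
    )


def ref_normalize(matrix: list[list[float]], method: str) -> list[list[float]]:
    mean, std, median, p25, p75 = ref_global_stats(matrix)
    if method == "relative_change":
        return [[v / mean for v in row] for row in matrix]
    if method == "zscore":
        return [[(v - mean) / std for v in row] for row in matrix]
    if method == "zero_center":
        return [[v - mean for v in row] for row in matrix]
    if method == "robust":
        return [[(v - median) / (p75 - p25) for v in row] for row in matrix]
    raise ValueError(method)


def ref_pool(matrix: list[list[float]], method: str) -> list[float]:
    n_rows = len(matrix)
    n_cols = len(matrix[0])
    if method == "rf":
        return [v for row in matrix for v in row]
    if method == "tsd":
        return [ref_pop_std(list(row)) for row in matrix]
    if method == "ssd":
        return [ref_pop_std([matrix[r][t] for r in range(n_rows)]) for t in range(n_cols)]
    if method == "tf":
        return ref_pool(matrix, "tsd") + ref_pool(matrix, "ssd")
    if method == "sf":
        std_t = ref_pool(matrix, "tsd")
        mean_t = [ref_mean(list(row)) for row in matrix]
        std_s = ref_pool(matrix, "ssd")
        mean_s = [ref_mean([matrix[r][t] for r in range(n_rows)]) for t in range(n_cols)]
        return [
            ref_mean(std_t), ref_pop_std(std_t), ref_pop_std(mean_t),
            ref_mean(std_s), ref_pop_std(std_s), ref_pop_std(mean_s),
        ]
    raise ValueError(method)


def ref_auc_pair_counting(scores: list[float], labels: list[int]) -> float:
    """Exhaustive Mann-Whitney pair counting, ties credited one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
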