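"""Independent brute-force oracles used to validate the implementations.

These deliberately use different algorithms from the package: plain
recursion for the edit distance, exhaustive arrangement enumeration for the
runs distribution, and naive formula transcriptions for descriptives. They
are slow and only run on tiny inputs.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache


def recursive_levenshtein(a: tuple, b: tuple) -> int:
    """Top-down recursive edit distance over token suffixes."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(a):
            return len(b) - j
        if j == len(b):
            return len(a) - i
        best = go(i + 1, j + 1) + (a[i] != b[j])
        best = min(best, go(i + 1, j) + 1, go(i, j + 1) + 1)
        return best

    return go(0, 0)


def enumerate_runs_distribution(n_above: int, n_below: int) -> dict[int, float]:
    """Distribution of run counts by brute-force enumeration of arrangements."""
    n = n_above + n_below
    counts: dict[int, int] = {}
    total = 0
    for positions in itertools.combinations(range(n), n_above):
        seq = [0] * n
        for p in positions:
            seq[p] = 1
        runs = 1 + sum(1 for i in range(1, n) if seq[i] != seq[i - 1])
        counts[runs] = counts.get(runs, 0) + 1
        total += 1
    return {r: c / total for r, c in counts.items()}


def naive_describe(values: list[float]) -> dict:
    n = len(values)
    mean = sum(values) / n
    if n > 1:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    else:
        sd = 0.0
    ordered = sorted(values)
    if n % 2:
        median = ordered[n // 2]
    else:
        median = (ordered[n // 2 - 1] + ordered[n // 2]) / 2
    return {
        "mean": mean,
        "sd": sd,
        "median": median,
        "min": min(values),
        "max": max(values),
    }
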