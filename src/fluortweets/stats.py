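"""Quarterly series, descriptives, runs test, chi-square and frequency tables.

The temporal analysis counts posts per calendar quarter and per category,
summarises the quarterly totals, and tests each category's quarterly series
for non-randomness with the one-sample Wald-Wolfowitz runs test about the
median. Gender contrasts use Pearson chi-square on gender x category
contingency tables (records of unknown gender excluded). Term and hashtag
frequency tables back the word-cloud-style summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from ._util import percentage, truncated_mean
from .classify import CATEGORIES, Assignment
from .corpus_io import (
    STUDY_WINDOW,
    QuarterIndex,
    TweetRecord,
    quarter_of,
    quarters_in_window,
)
from .normalize import extract_hashtags, normalize_text

__all__ = [
    "ChiSquareResult",
    "QuarterSeries",
    "RunsTestResult",
    "build_quarter_series",
    "describe_counts",
    "gender_breakdown",
    "gender_chi_square",
    "hashtag_frequencies",
    "runs_test",
    "term_frequencies",
]


@dataclass(frozen=True)
class QuarterSeries:
    """Per-quarter post counts per category over the study window."""

    quarters: list[QuarterIndex]
    counts: dict[str, list[int]]
    totals: list[int]

    def __post_init__(self) -> None:
        for cat, series in self.counts.items():
            if len(series) != len(self.quarters):
                raise ValueError(f"series length mismatch for {cat}")
        expected = [sum(vals) for vals in zip(*(self.counts[c] for c in self.counts))]
        if expected and expected != self.totals:
            raise ValueError("totals must equal per-quarter sums over categories")


@dataclass(frozen=True)
class RunsTestResult:
    """Wald-Wolfowitz runs test about a cutpoint (the median by default)."""

    n_runs: int
    n_above: int
    n_below: int
    p_value: float
    method: str  # "exact" | "normal_approx"

    def __post_init__(self) -> None:
        if self.n_runs > self.n_above + self.n_below:
            raise ValueError("more runs than observations")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square on an observed contingency table."""

    statistic: float
    df: int
    p_value: float
    table: np.ndarray
    expected: np.ndarray
    corrected: bool = False


def build_quarter_series(
    assignments: Sequence[Assignment],
    records: Sequence[TweetRecord],
    window_start: date = STUDY_WINDOW[0],
    window_end: date = STUDY_WINDOW[1],
) -> QuarterSeries:
    """Count assigned posts per calendar quarter and category."""
    quarters = quarters_in_window(window_start, window_end)
    index = {q: i for i, q in enumerate(quarters)}
    by_id = {rec.id: rec for rec in records}
    counts = {c: [0] * len(quarters) for c in CATEGORIES}
    for a in assignments:
        rec = by_id[a.tweet_id]
        q = quarter_of(rec.created_at, window_start, window_end)
        counts[a.category][index[q]] += 1
    totals = [sum(counts[c][i] for c in CATEGORIES) for i in range(len(quarters))]
    return QuarterSeries(quarters=quarters, counts=counts, totals=totals)


def describe_counts(values: Sequence[float]) -> dict:
    """Mean (real and integer-truncated), sample SD, median, min, max.

    SD uses the n-1 denominator; the median uses the midpoint convention for
    even n. The truncated mean is the headline figure for per-quarter post
    volumes (total // n_quarters).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("describe_counts requires a non-empty list")
    return {
        "mean": float(vals.mean()),
        "mean_truncated": truncated_mean(vals.tolist()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        "median": float(np.median(vals)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n": int(vals.size),
    }


def _comb(n: int, k: int) -> int:
    if k < 0 or k > n or n < 0:
        return 0
    return math.comb(n, k)


def runs_pmf(n_above: int, n_below: int) -> dict[int, float]:
    """Exact distribution of the number of runs given group sizes.

    All arrangements of ``n_above`` + ``n_below`` labels are equally likely;
    the count of arrangements with r runs follows the classical
    composition-counting formula.
    """
    n = n_above + n_below
    denom = math.comb(n, n_above)
    pmf: dict[int, float] = {}
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * _comb(n_above - 1, k - 1) * _comb(n_below - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = _comb(n_above - 1, k) * _comb(n_below - 1, k - 1) + _comb(
                n_above - 1, k - 1
            ) * _comb(n_below - 1, k)
        if ways:
            pmf[r] = ways / denom
    return pmf


def two_sided_runs_p(pmf: dict[int, float], observed: int) -> float:
    """Two-sided p as twice the smaller tail (capped at 1)."""
    lower = sum(p for r, p in pmf.items() if r <= observed)
    upper = sum(p for r, p in pmf.items() if r >= observed)
    return min(1.0, 2.0 * min(lower, upper))


def runs_test(values: Sequence[float], cutpoint: float | None = None) -> RunsTestResult:
    """One-sample runs test for randomness about the median.

    Values equal to the cutpoint are dropped; the rest are dichotomised as
    above/below and the number of runs is compared with its distribution
    under exchangeability. Exact two-sided p for up to 30 retained values,
    else a normal approximation with continuity correction.
    """
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValueError("runs test requires at least 2 values")
    cut = float(np.median(vals)) if cutpoint is None else float(cutpoint)
    signs = [v > cut for v in vals if v != cut]
    if len(signs) < 2:
        raise ValueError("fewer than 2 values retained after dropping cutpoint ties")
    n_above = sum(signs)
    n_below = len(signs) - n_above
    n_runs = 1 + sum(1 for i in range(1, len(signs)) if signs[i] != signs[i - 1])
    if n_above == 0 or n_below == 0:
        return RunsTestResult(n_runs, n_above, n_below, 1.0, "exact")
    n = n_above + n_below
    if n <= 30:
        p = two_sided_runs_p(runs_pmf(n_above, n_below), n_runs)
        method = "exact"
    else:
        mu = 1.0 + 2.0 * n_above * n_below / n
        var = 2.0 * n_above * n_below * (2.0 * n_above * n_below - n) / (n * n * (n - 1.0))
        if n_runs < mu:
            z = (n_runs - mu + 0.5) / math.sqrt(var)
        elif n_runs > mu:
            z = (n_runs - mu - 0.5) / math.sqrt(var)
        else:
            z = 0.0
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return RunsTestResult(n_runs, n_above, n_below, p, method)


def _chi_square(table: np.ndarray, correction: bool) -> ChiSquareResult:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    zeros = np.argwhere(expected == 0)
    if zeros.size:
        r, c = zeros[0]
        raise ValueError(f"expected count is zero in cell (row {r}, col {c})")
    stat, p, df, exp = sps.chi2_contingency(table, correction=correction)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        table=table,
        expected=np.asarray(exp),
        corrected=correction,
    )


def gender_chi_square(
    records: Sequence[TweetRecord],
    assignments: Sequence[Assignment],
    mode: str = "omnibus",
    yates_2x2: bool = True,
):
    """Chi-square test(s) of category distribution between genders.

    Records with unknown gender are excluded. ``omnibus`` tests the 2x4
    gender x category table (no continuity correction); ``per_category``
    emits four 2x2 tests (category vs rest; Yates-corrected by default,
    with a Bonferroni-adjusted p alongside the raw one).
    """
    by_id = {rec.id: rec for rec in records}
    cat_of = {a.tweet_id: a.category for a in assignments}
    table = np.zeros((2, len(CATEGORIES)), dtype=float)
    for tid, cat in cat_of.items():
        gender = by_id[tid].gender
        if gender == "unknown":
            continue
        table[0 if gender == "female" else 1, CATEGORIES.index(cat)] += 1
    if mode == "omnibus":
        return _chi_square(table, correction=False)
    if mode != "per_category":
        raise ValueError(f"unknown mode {mode!r}")
    results = {}
    for i, cat in enumerate(CATEGORIES):
        rest = table.sum(axis=1) - table[:, i]
        sub = np.column_stack([table[:, i], rest])
        res = _chi_square(sub, correction=yates_2x2)
        results[cat] = {
            "result": res,
            "p_bonferroni": min(1.0, res.p_value * len(CATEGORIES)),
        }
    return results


def gender_breakdown(
    records: Sequence[TweetRecord], assignments: Sequence[Assignment]
) -> dict:
    """Gender shares with explicit denominators.

    Reports the identified fraction (female+male over all posts, integer
    percent), and per category the female share among gender-identified
    posts of that category.
    """
    by_id = {rec.id: rec for rec in records}
    total = len(assignments)
    known = [a for a in assignments if by_id[a.tweet_id].gender != "unknown"]
    out = {
        "n_total": total,
        "n_identified": len(known),
        "identified_pct": percentage(len(known), total, 0) if total else 0,
        "per_category": {},
    }
    for cat in CATEGORIES:
        cat_known = [a for a in known if a.category == cat]
        n_female = sum(1 for a in cat_known if by_id[a.tweet_id].gender == "female")
        out["per_category"][cat] = {
            "n_identified": len(cat_known),
            "n_female": n_female,
            "female_pct": percentage(n_female, len(cat_known), 0) if cat_known else None,
        }
    return out


def term_frequencies(
    texts_or_tokens: Iterable, top_n: int = 50
) -> list[tuple[str, int]]:
    """Top terms by count, descending, ties broken lexicographically."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    from collections import Counter

    counter: Counter = Counter()
    for item in texts_or_tokens:
        tokens = normalize_text(item) if isinstance(item, str) else tuple(item)
        counter.update(tokens)
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def hashtag_frequencies(texts: Iterable[str], top_n: int = 50) -> list[tuple[str, int]]:
    """Top hashtags by count over raw texts (``#`` retained)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    from collections import Counter

    counter: Counter = Counter()
    for text in texts:
        counter.update(extract_hashtags(text))
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]
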