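"""Seeded nearest-neighbour categorisation and inter-rater agreement.

Two experts independently label a random sample of posts into four content
categories — concern, experience, positive, negative. Posts on which the
raters agree form the consensus *seed set*; agreement quality is summarised
per category (one-vs-rest) by percent agreement and Cohen's kappa. Every
remaining post is then assigned to the category containing its most
syntactically similar seed (maximum normalized word-Levenshtein similarity,
i.e. nearest labelled instance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from ._util import percentage
from .corpus_io import TweetRecord
from .normalize import TokenSeq, normalize_text
from .similarity import (
    TokenProfile,
    bounded_word_levenshtein,
    multiset_upper_bound,
    similarity_upper_bound,
    token_profile,
)

__all__ = [
    "CATEGORIES",
    "AgreementReport",
    "Assignment",
    "SeedSet",
    "assign_category",
    "build_seed_set",
    "classify_corpus",
    "cohens_kappa",
]

#: Canonical category order (A-D in the annotation scheme).
CATEGORIES: tuple[str, ...] = ("concern", "experience", "positive", "negative")


@dataclass(frozen=True)
class SeedSet:
    """Consensus-labelled posts per category: ``members[cat] = [(id, tokens)]``."""

    members: dict[str, list[tuple[str, TokenSeq]]]

    def __post_init__(self) -> None:
        unknown = set(self.members) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in seed set: {sorted(unknown)}")
        ids = [tid for seeds in self.members.values() for tid, _ in seeds]
        if len(ids) != len(set(ids)):
            raise ValueError("a seed tweet appears in more than one category")

    def require_complete(self) -> None:
        empty = [c for c in CATEGORIES if not self.members.get(c)]
        if empty:
            raise ValueError(f"seed set has empty categories: {empty}")

    @property
    def seed_ids(self) -> frozenset:
        return frozenset(tid for seeds in self.members.values() for tid, _ in seeds)

    def category_of(self, tweet_id: str) -> str:
        for cat, seeds in self.members.items():
            if any(tid == tweet_id for tid, _ in seeds):
                return cat
        raise KeyError(tweet_id)


@dataclass(frozen=True)
class AgreementReport:
    """Per-category one-vs-rest agreement between the two raters."""

    per_category: dict[str, dict[str, float]]  # percent_agreement, kappa
    n_rated: int
    n_consensus: int

    def __post_init__(self) -> None:
        if self.n_consensus > self.n_rated:
            raise ValueError("n_consensus cannot exceed n_rated")


@dataclass(frozen=True)
class Assignment:
    """A post's inferred category with its similarity score and margin."""

    tweet_id: str
    category: str
    score: float
    runner_up_margin: float
    low_confidence: bool
    tied: bool = False


def cohens_kappa(table: Sequence[Sequence[float]]) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) for a square table.

    Rows index the first rater's calls, columns the second's; p_o is the
    diagonal fraction and p_e the expected agreement from the marginals.
    """
    import numpy as np

    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    if (t < 0).any():
        raise ValueError("agreement table entries must be non-negative")
    n = t.sum()
    if n <= 0:
        raise ValueError("agreement table must have a positive total")
    p_o = np.trace(t) / n
    p_e = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / (n * n)
    if abs(1.0 - p_e) < 1e-15:
        raise ValueError("degenerate marginals: chance agreement equals 1")
    return float((p_o - p_e) / (1.0 - p_e))


def _validate_labels(labels: pd.DataFrame) -> pd.DataFrame:
    required = {"tweet_id", "rater_id", "category"}
    missing = required - set(labels.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    bad = set(labels["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown category labels: {sorted(bad)}")
    counts = labels.groupby("tweet_id")["rater_id"].agg(["count", "nunique"])
    wrong = counts[(counts["count"] != 2) | (counts["nunique"] != 2)]
    if not wrong.empty:
        raise ValueError(
            "each tweet must be rated exactly once by two distinct raters; "
            f"offending tweet_ids: {sorted(wrong.index)[:10]}"
        )
    return labels


def build_seed_set(
    labels: pd.DataFrame, corpus: Sequence[TweetRecord]
) -> tuple[SeedSet, AgreementReport]:
    """Consensus seed set plus per-category agreement from a two-rater table.

    ``labels`` has one row per (tweet, rater) with columns tweet_id,
    rater_id, category. Tweets where the raters agree enter the seed set
    under the agreed category; disagreements count toward ``n_rated`` only.
    """
    _validate_labels(labels)
    by_id = {rec.id: rec for rec in corpus}
    missing = set(labels["tweet_id"]) - set(by_id)
    if missing:
        raise ValueError(f"labeled tweet_ids absent from corpus: {sorted(missing)[:10]}")

    # deterministic rater order: sort by rater_id within each tweet
    pairs: dict[str, tuple[str, str]] = {}
    for tweet_id, grp in labels.groupby("tweet_id"):
        grp = grp.sort_values("rater_id")
        pairs[tweet_id] = tuple(grp["category"].tolist())

    members: dict[str, list[tuple[str, TokenSeq]]] = {c: [] for c in CATEGORIES}
    n_consensus = 0
    for tweet_id in sorted(pairs):
        c1, c2 = pairs[tweet_id]
        if c1 == c2:
            members[c1].append((tweet_id, normalize_text(by_id[tweet_id].text)))
            n_consensus += 1

    per_category: dict[str, dict[str, float]] = {}
    n_rated = len(pairs)
    for cat in CATEGORIES:
        a = b = c = d = 0
        for c1, c2 in pairs.values():
            r1, r2 = c1 == cat, c2 == cat
            if r1 and r2:
                a += 1
            elif r1:
                b += 1
            elif r2:
                c += 1
            else:
                d += 1
        table = [[a, b], [c, d]]
        try:
            kappa = cohens_kappa(table)
        except ValueError:
            kappa = None  # degenerate marginals: category never (or always) used
        per_category[cat] = {
            "percent_agreement": (a + d) / n_rated,
            "kappa": kappa,
            "n_consensus": a,
        }

    seeds = SeedSet(members)
    report = AgreementReport(per_category=per_category, n_rated=n_rated, n_consensus=n_consensus)
    return seeds, report


def _category_scores(
    prof: TokenProfile,
    seed_profiles: dict[str, list[TokenProfile]],
    aggregation: str,
    top_k: int,
) -> dict[str, float]:
    scores: dict[str, float] = {}
    for cat in CATEGORIES:
        seeds = seed_profiles[cat]
        if aggregation == "max":
            best = 0.0
            for sp in seeds:
                m = max(prof.length, sp.length)
                if m == 0:
                    best = 1.0
                    break
                if similarity_upper_bound(prof, sp) <= best:
                    continue
                if multiset_upper_bound(prof, sp) <= best:
                    continue
                cutoff = int((1.0 - best) * m)
                d = bounded_word_levenshtein(prof.tokens, sp.tokens, cutoff)
                sim = 1.0 - d / m
                if sim > best:
                    best = sim
                    if best == 1.0:
                        break
            scores[cat] = best
        elif aggregation == "mean_top_k":
            sims = sorted((prof.similarity_to(sp) for sp in seeds), reverse=True)
            k = min(top_k, len(sims))
            scores[cat] = sum(sims[:k]) / k
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    return scores


def _mean_similarity(prof: TokenProfile, seeds: list[TokenProfile]) -> float:
    return sum(prof.similarity_to(sp) for sp in seeds) / len(seeds)


def assign_category(
    tokens: Sequence[str],
    seeds: SeedSet,
    confidence_floor: float = 0.1,
    aggregation: str = "max",
    top_k: int = 3,
    _seed_profiles: dict[str, list[TokenProfile]] | None = None,
    tweet_id: str = "",
) -> Assignment:
    """Assign one post to the category with the most syntactic similarity.

    Per-category score is the maximum normalized similarity over that
    category's seeds (nearest labelled instance; ``mean_top_k`` available as
    an alternative aggregation). Score ties are broken by mean similarity
    over the tied categories' seeds, then by canonical category order; an
    all-zero score (no shared tokens with any seed) falls through the tie
    rule and is marked low-confidence.
    """
    seeds.require_complete()
    if _seed_profiles is None:
        _seed_profiles = {
            cat: [token_profile(toks) for _, toks in seeds.members[cat]]
            for cat in CATEGORIES
        }
    prof = token_profile(tokens)
    scores = _category_scores(prof, _seed_profiles, aggregation, top_k)
    best_score = max(scores.values())
    tied = [c for c in CATEGORIES if scores[c] == best_score]
    was_tied = len(tied) > 1
    if was_tied:
        means = {c: _mean_similarity(prof, _seed_profiles[c]) for c in tied}
        best_mean = max(means.values())
        tied = [c for c in tied if means[c] == best_mean]
    category = tied[0]  # canonical order resolves any remaining tie
    others = [scores[c] for c in CATEGORIES if c != category]
    margin = best_score - max(others)
    return Assignment(
        tweet_id=tweet_id,
        category=category,
        score=best_score,
        runner_up_margin=margin,
        low_confidence=best_score < confidence_floor,
        tied=was_tied,
    )


def classify_corpus(
    records: Sequence[TweetRecord],
    seeds: SeedSet,
    confidence_floor: float = 0.1,
    aggregation: str = "max",
    top_k: int = 3,
) -> tuple[list[Assignment], dict]:
    """Assign every record to a category; seeds keep their consensus label.

    Records should already be deduplicated and author-unique. Returns the
    assignments (input order) and a summary with per-category counts and
    percentages (rounded half-up to one decimal of the corpus total). Seed
    tweets are not re-classified — their consensus category stands, with
    score 1.0 by self-match — but count in the totals.
    """
    seeds.require_complete()
    seed_profiles = {
        cat: [token_profile(toks) for _, toks in seeds.members[cat]] for cat in CATEGORIES
    }
    seed_cat = {
        tid: cat for cat, members in seeds.members.items() for tid, _ in members
    }
    assignments: list[Assignment] = []
    for rec in records:
        tokens = normalize_text(rec.text)
        if rec.id in seed_cat:
            cat = seed_cat[rec.id]
            prof = token_profile(tokens)
            scores = _category_scores(prof, seed_profiles, aggregation, top_k)
            others = [scores[c] for c in CATEGORIES if c != cat]
            assignments.append(
                Assignment(
                    tweet_id=rec.id,
                    category=cat,
                    score=scores[cat],
                    runner_up_margin=scores[cat] - max(others),
                    low_confidence=False,
                )
            )
        else:
            assignments.append(
                assign_category(
                    tokens,
                    seeds,
                    confidence_floor=confidence_floor,
                    aggregation=aggregation,
                    top_k=top_k,
                    _seed_profiles=seed_profiles,
                    tweet_id=rec.id,
                )
            )
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    total = len(assignments)
    summary = {
        "total": total,
        "counts": counts,
        "percentages": {
            c: (percentage(counts[c], total, 1) if total else 0.0) for c in CATEGORIES
        },
    }
    return assignments, summary


def assignments_table(assignments: Iterable[Assignment]) -> pd.DataFrame:
    """Tabulate assignments for the standard CSV artifact."""
    return pd.DataFrame(
        [
            {
                "tweet_id": a.tweet_id,
                "category": a.category,
                "score": a.score,
                "margin": a.runner_up_margin,
                "low_confidence": a.low_confidence,
            }
            for a in assignments
        ],
        columns=["tweet_id", "category", "score", "margin", "low_confidence"],
    )
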