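"""Near-duplicate elimination by greedy leader clustering.

Retweets, bot reposts and advertisements appear as clusters of (near-)
identical texts. Records are scanned in chronological order; each joins the
first existing cluster whose leader's normalized syntactic similarity is at
or above the threshold, otherwise it founds a new cluster. Leaders (the
earliest exemplar of each cluster) are retained; members are eliminated.
By construction any two retained leaders are pairwise below the threshold.

Large clusters are characteristic of non-human content (ads, bot retweet
chains) and can be flagged, and optionally removed entirely, with
:func:`flag_nonhuman`. :func:`enforce_unique_authors` then keeps one post
(the earliest) per author so the final corpus has one post per unique user.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import pandas as pd

from .corpus_io import TweetRecord
from .normalize import normalize_text
from .similarity import (
    TokenProfile,
    bounded_word_levenshtein,
    multiset_upper_bound,
    similarity_upper_bound,
    token_profile,
)

__all__ = ["DedupResult", "cluster_report", "enforce_unique_authors", "flag_nonhuman", "leader_cluster"]


@dataclass(frozen=True)
class DedupResult:
    """Outcome of leader clustering over one corpus.

    ``clusters`` maps each leader id to the ids of its eliminated members
    (empty list for singleton clusters); ``similarities`` records each
    eliminated member's similarity to its leader.
    """

    retained: list[TweetRecord]
    clusters: dict[str, list[str]]
    n_eliminated: int
    flagged_nonhuman: frozenset = frozenset()
    similarities: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.8

    @property
    def n_input(self) -> int:
        return len(self.retained) + self.n_eliminated


def leader_cluster(
    records: Sequence[TweetRecord],
    threshold: float = 0.8,
    normalizer: Callable[[str], tuple] = normalize_text,
) -> DedupResult:
    """Greedy one-pass clustering of records by normalized similarity.

    Records are processed by ascending ``created_at`` (ties by id) so that
    originals precede their retweets. Exactness-preserving screens — the
    length bound and the multiset-overlap bound — skip the dynamic program
    only when the pair provably cannot reach the threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: (r.created_at, r.id))

    leaders: list[tuple[TweetRecord, TokenProfile]] = []
    by_leader: dict[str, list[str]] = {}
    sims: dict[str, float] = {}

    for rec in ordered:
        prof = token_profile(normalizer(rec.text))
        joined = False
        for leader, lprof in leaders:
            m = max(prof.length, lprof.length)
            if m == 0:
                sim = 1.0  # both empty after normalization
            else:
                if similarity_upper_bound(prof, lprof) < threshold:
                    continue
                if multiset_upper_bound(prof, lprof) < threshold:
                    continue
                cutoff = int((1.0 - threshold) * m + 1e-9)
                d = bounded_word_levenshtein(prof.tokens, lprof.tokens, cutoff)
                if d > cutoff:
                    continue
                sim = 1.0 - d / m
                if sim < threshold:
                    continue
            by_leader[leader.id].append(rec.id)
            sims[rec.id] = sim
            joined = True
            break
        if not joined:
            leaders.append((rec, prof))
            by_leader[rec.id] = []

    retained = [leader for leader, _ in leaders]
    n_eliminated = sum(len(v) for v in by_leader.values())
    return DedupResult(
        retained=retained,
        clusters=by_leader,
        n_eliminated=n_eliminated,
        similarities=sims,
        threshold=threshold,
    )


def flag_nonhuman(
    result: DedupResult,
    min_cluster_size: int = 3,
    drop_nonhuman_leaders: bool = False,
) -> DedupResult:
    """Flag clusters of ``min_cluster_size``+ records (leader included) as non-human.

    With ``drop_nonhuman_leaders`` the flagged leaders are also removed from
    the retained set (counted as eliminated), so whole ad clusters vanish;
    by default one exemplar per flagged cluster survives.
    """
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    flagged = frozenset(
        leader_id
        for leader_id, members in result.clusters.items()
        if 1 + len(members) >= min_cluster_size
    )
    retained = result.retained
    n_eliminated = result.n_eliminated
    if drop_nonhuman_leaders and flagged:
        retained = [rec for rec in retained if rec.id not in flagged]
        n_eliminated += len(result.retained) - len(retained)
    return replace(
        result, retained=retained, n_eliminated=n_eliminated, flagged_nonhuman=flagged
    )


def enforce_unique_authors(records: Sequence[TweetRecord]) -> list[TweetRecord]:
    """Keep the earliest post (ties by id) per author; output authors are unique."""
    best: dict[str, TweetRecord] = {}
    for rec in records:
        cur = best.get(rec.author_id)
        if cur is None or (rec.created_at, rec.id) < (cur.created_at, cur.id):
            best[rec.author_id] = rec
    return sorted(best.values(), key=lambda r: (r.created_at, r.id))


def cluster_report(result: DedupResult) -> pd.DataFrame:
    """Tabulate clusters as (leader_id, member_id, similarity, flagged) rows."""
    rows = []
    for leader_id in sorted(result.clusters):
        flagged = leader_id in result.flagged_nonhuman
        for member_id in result.clusters[leader_id]:
            rows.append(
                {
                    "leader_id": leader_id,
                    "member_id": member_id,
                    "similarity": result.similarities.get(member_id, float("nan")),
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows, columns=["leader_id", "member_id", "similarity", "flagged"])
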