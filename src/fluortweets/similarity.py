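"""Word-based Levenshtein distance and normalized syntactic similarity.

The distance is the classic Levenshtein edit distance computed over *word
tokens* rather than characters: the minimum number of single-token
insertions, deletions and substitutions (all at unit cost, no transposition)
transforming one token sequence into another, with tokens compared by exact
string equality. The normalized similarity is

    sim(a, b) = 1 - d(a, b) / max(|a|, |b|)

defined as 1 when both sequences are empty. It lies in [0, 1], is symmetric,
and equals 1 exactly when the sequences are equal.

The module also provides cheap upper bounds on the similarity (from sequence
lengths and token-multiset overlap) used by deduplication and classification
to skip the dynamic program when a pair cannot reach a threshold; the bounds
follow from d(a, b) >= |len(a) - len(b)| and from the fact that an alignment
cannot match more tokens than the two multisets share.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "SimilarityParams",
    "TokenProfile",
    "bounded_word_levenshtein",
    "multiset_upper_bound",
    "normalized_similarity",
    "similarity_upper_bound",
    "token_profile",
    "word_levenshtein",
]


@dataclass(frozen=True)
class SimilarityParams:
    """Edit-cost convention: unit insertion/deletion/substitution costs."""

    insertion_cost: int = 1
    deletion_cost: int = 1
    substitution_cost: int = 1

    def __post_init__(self) -> None:
        if not (self.insertion_cost == self.deletion_cost == self.substitution_cost == 1):
            raise ValueError("word-based Levenshtein uses unit edit costs")


def word_levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Minimum token edits (insert/delete/substitute) transforming a into b."""
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    if la < lb:  # iterate over the longer sequence, keep the row short
        a, b, la, lb = b, a, lb, la
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        ta = a[i - 1]
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ta != b[j - 1]),
            )
        prev = cur
    return prev[lb]


def bounded_word_levenshtein(a: Sequence[str], b: Sequence[str], cutoff: int) -> int:
    """Exact distance if it is <= cutoff, else any value > cutoff.

    Abandons the dynamic program as soon as every entry of the current row
    exceeds the cutoff (row minima are non-decreasing), which makes threshold
    checks cheap for clearly dissimilar pairs.
    """
    la, lb = len(a), len(b)
    if abs(la - lb) > cutoff:
        return cutoff + 1
    if la == 0 or lb == 0:
        return max(la, lb)
    if la < lb:
        a, b, la, lb = b, a, lb, la
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        ta = a[i - 1]
        cur = [i] + [0] * lb
        row_min = i
        for j in range(1, lb + 1):
            v = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ta != b[j - 1]),
            )
            cur[j] = v
            if v < row_min:
                row_min = v
        if row_min > cutoff:
            return cutoff + 1
        prev = cur
    return prev[lb] if prev[lb] <= cutoff else cutoff + 1


def normalized_similarity(a: Sequence[str], b: Sequence[str]) -> float:
    """1 - distance / max length; 1.0 for two empty sequences."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - word_levenshtein(a, b) / m


@dataclass(frozen=True)
class TokenProfile:
    """Precomputed per-sequence summaries for fast similarity screening."""

    tokens: tuple[str, ...]
    length: int
    token_set: frozenset
    counts: Counter

    def similarity_to(self, other: "TokenProfile") -> float:
        return normalized_similarity(self.tokens, other.tokens)


def token_profile(tokens: Sequence[str]) -> TokenProfile:
    toks = tuple(tokens)
    return TokenProfile(toks, len(toks), frozenset(toks), Counter(toks))


def similarity_upper_bound(pa: TokenProfile, pb: TokenProfile) -> float:
    """Cheap upper bound on normalized_similarity(pa.tokens, pb.tokens).

    Matched positions in any alignment number at most the shared-token count:
    one per distinct common token plus repeats, which both sides must supply.
    """
    m = max(pa.length, pb.length)
    if m == 0:
        return 1.0
    common = len(pa.token_set & pb.token_set)
    ub = common + min(pa.length - len(pa.token_set), pb.length - len(pb.token_set))
    ub = min(ub, pa.length, pb.length)
    return ub / m


def multiset_upper_bound(pa: TokenProfile, pb: TokenProfile) -> float:
    """Tighter (but costlier) bound via exact multiset intersection size."""
    m = max(pa.length, pb.length)
    if m == 0:
        return 1.0
    small, big = (pa.counts, pb.counts) if pa.length <= pb.length else (pb.counts, pa.counts)
    matched = sum(min(c, big[t]) for t, c in small.items())
    return matched / m
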