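"""Synthetic corpus generator with full ground truth.

Real harvested post corpora can rarely be redistributed, so this module
generates corpora with the statistical structure the analysis assumes: four latent
content categories with separable unigram vocabularies, retweet and
advertisement near-duplicate clusters, per-author post multiplicity, gender
attributes, and per-category quarterly volume trends over the three-year
window. Every generated post carries ground truth (true category, duplicate
parent, ad flag), so each pipeline stage can be scored against a known
answer.

Texts are bag-of-words renderings: each original draws its tokens from its
category's private vocabulary or from a shared pool, embeds one study
keyword phrase (so keyword filtering retains it), and may carry planted
hashtags and a URL. Retweet duplicates are byte-copies prefixed with
``RT @user:``, so after normalization they are token-identical to their
originals; advertisement clusters are near-identical texts posted by
distinct authors. All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .corpus_io import STUDY_WINDOW, TweetRecord, quarters_in_window
from .classify import CATEGORIES

__all__ = ["GeneratorConfig", "GroundTruth", "generate_corpus", "generate_rater_labels"]

#: Study-printed category shares used as default mixture proportions.
DEFAULT_PROPORTIONS = (0.485, 0.07, 0.181, 0.264)

#: Planted hashtag attachment probabilities. Relative sizes follow the
#: study's printed hashtag counts; absolute rates are kept low so that
#: hashtag tokens (shared across categories) do not erode the vocabulary
#: separability the recovery experiments rely on.
DEFAULT_HASHTAG_PROBS = (
    ("#caries", 0.12),
    ("#fluoridevarnish", 0.066),
    ("#toothvarnish", 0.048),
    ("#topicalfluoride", 0.018),
    ("#pediatricdentistry", 0.015),
)

#: Keyword phrases embedded in generated texts (with sampling weights).
_KEYWORD_CHOICES = ("fluoride", "tooth decay", "fluoride varnish", "topical fluoride", "caries risk")
_KEYWORD_WEIGHTS = (0.6, 0.1, 0.1, 0.1, 0.1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults mirror the study conditions.

    ``duplicate_fraction`` is the fraction of all posts that are retweet
    copies of an original; with the default ad clusters it reproduces an
    eliminated fraction near the study's (110,847 of 132,358, i.e. ~84%).
    ``trend_slopes`` give each category's linear quarterly rate multiplier
    across the window (rate_q proportional to 1 + slope * q / (Q - 1)); the
    concern slope 1.75 matches the study's first-to-last-quarter growth of
    the concern series (478 to 1,315). With ``quarter_allocation="expected"``
    (default) each category's posts are spread over quarters by
    largest-remainder quotas, so the planted trend is an exact property of
    the corpus; ``"multinomial"`` draws each post's quarter independently,
    making the trend hold only in expectation.
    """

    n_tweets: int = 2000
    category_proportions: tuple[float, float, float, float] = DEFAULT_PROPORTIONS
    duplicate_fraction: float = 0.80
    ad_clusters: int = 3
    ad_cluster_size: int = 8
    author_repeat_rate: float = 0.05
    gender_probs: tuple[float, float, float] = (0.75, 0.12, 0.13)
    vocab_size_per_category: int = 50
    shared_vocab_size: int = 30
    tweet_length: tuple[int, int] = (8, 16)
    trend_slopes: tuple[float, float, float, float] = (1.75, 0.0, 0.6, 0.3)
    quarter_allocation: str = "expected"
    shared_token_rate: float = 0.15
    hashtag_probs: tuple[tuple[str, float], ...] = DEFAULT_HASHTAG_PROBS
    url_prob: float = 0.1
    window: tuple[date, date] = STUDY_WINDOW
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if abs(sum(self.gender_probs) - 1.0) > 1e-9:
            raise ValueError("gender probabilities must sum to 1")
        if not (0.0 <= self.duplicate_fraction < 1.0):
            raise ValueError("duplicate_fraction must be in [0, 1)")
        if not (0.0 <= self.author_repeat_rate < 1.0):
            raise ValueError("author_repeat_rate must be in [0, 1)")
        if self.tweet_length[0] < 1 or self.tweet_length[0] > self.tweet_length[1]:
            raise ValueError("tweet_length must satisfy 1 <= min <= max")
        if min(self.vocab_size_per_category, self.shared_vocab_size, self.n_tweets) < 1:
            raise ValueError("sizes must be positive")
        if self.ad_clusters < 0 or (self.ad_clusters and self.ad_cluster_size < 2):
            raise ValueError("ad clusters need ad_cluster_size >= 2")
        if self.quarter_allocation not in ("expected", "multinomial"):
            raise ValueError("quarter_allocation must be 'expected' or 'multinomial'")

    @property
    def n_ads(self) -> int:
        return self.ad_clusters * self.ad_cluster_size

    @property
    def n_duplicates(self) -> int:
        return int(round(self.duplicate_fraction * self.n_tweets))

    @property
    def n_originals(self) -> int:
        return self.n_tweets - self.n_duplicates - self.n_ads


@dataclass(frozen=True)
class GroundTruth:
    """Per-post truth plus corpus-level planted parameters."""

    table: pd.DataFrame  # tweet_id, true_category, duplicate_of, is_ad
    proportions: tuple[float, ...]
    trend_slopes: tuple[float, ...]
    duplicate_fraction: float

    def category_of(self) -> dict[str, str]:
        return dict(zip(self.table["tweet_id"], self.table["true_category"]))

    @property
    def original_ids(self) -> list[str]:
        mask = self.table["duplicate_of"].eq("") & ~self.table["is_ad"]
        return self.table.loc[mask, "tweet_id"].tolist()


def _quarter_weights(slope: float, n_quarters: int) -> np.ndarray:
    q = np.arange(n_quarters, dtype=float)
    w = 1.0 + slope * q / (n_quarters - 1)
    w = np.clip(w, 1e-6, None)
    return w / w.sum()


def _random_instant(rng, q_start: datetime, q_end: datetime) -> datetime:
    span = int((q_end - q_start).total_seconds())
    return q_start + timedelta(seconds=int(rng.integers(0, span)))


def generate_corpus(config: GeneratorConfig) -> tuple[list[TweetRecord], GroundTruth]:
    """Generate a corpus and its ground truth; deterministic given the seed.

    Returns records sorted by ``created_at`` (ties by id). Retweet
    duplicates always carry timestamps after their originals.
    """
    cfg = config
    if cfg.n_originals <= 0:
        raise ValueError(
            "infeasible config: duplicates plus ads leave no room for originals"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    quarters = quarters_in_window(*cfg.window)
    nq = len(quarters)
    q_bounds = []
    for q in quarters:
        start = datetime(q.year, 3 * (q.quarter - 1) + 1, 1, tzinfo=timezone.utc)
        if q.quarter == 4:
            end = datetime(q.year + 1, 1, 1, tzinfo=timezone.utc)
        else:
            end = datetime(q.year, 3 * q.quarter + 1, 1, tzinfo=timezone.utc)
        q_bounds.append((start, end))
    window_end = q_bounds[-1][1]

    vocab = {
        cat: [f"{cat}w{i:02d}" for i in range(cfg.vocab_size_per_category)]
        for cat in CATEGORIES
    }
    shared = [f"sharedw{i:02d}" for i in range(cfg.shared_vocab_size)]
    weights = {cat: _quarter_weights(s, nq) for cat, s in zip(CATEGORIES, cfg.trend_slopes)}

    authors: list[str] = []
    author_gender: dict[str, str] = {}

    def new_author() -> str:
        aid = f"u{len(author_gender):05d}"
        author_gender[aid] = ("female", "male", "unknown")[
            int(rng.choice(3, p=cfg.gender_probs))
        ]
        return aid

    def pick_author(repeatable: bool) -> str:
        if repeatable and authors and rng.random() < cfg.author_repeat_rate:
            return authors[int(rng.integers(0, len(authors)))]
        aid = new_author()
        authors.append(aid)
        return aid

    records: list[TweetRecord] = []
    truth_rows: list[dict] = []
    next_id = 0

    def make_id() -> str:
        nonlocal next_id
        tid = f"t{next_id:06d}"
        next_id += 1
        return tid

    def render_text(tokens: list[str]) -> str:
        text = " ".join(tokens)
        for tag, p in cfg.hashtag_probs:
            if rng.random() < p:
                text += f" {tag}"
        if rng.random() < cfg.url_prob:
            suffix = "".join(rng.choice(list("abcdefghij0123456789"), size=8))
            text += f" https://t.co/{suffix}"
        return text

    # 1. originals; category draw is multinomial, quarter placement follows
    # the planted trend either exactly (largest-remainder quotas) or in
    # expectation (independent draws)
    cat_draws = rng.choice(len(CATEGORIES), size=cfg.n_originals, p=cfg.category_proportions)

    def quota_quarters(n_cat: int, w: np.ndarray) -> list[int]:
        exact = n_cat * w
        base = np.floor(exact).astype(int)
        frac_order = np.argsort(-(exact - base), kind="stable")
        for idx in frac_order[: n_cat - int(base.sum())]:
            base[idx] += 1
        out = [q for q, reps in enumerate(base) for _ in range(reps)]
        return [out[i] for i in rng.permutation(len(out))]

    quarter_pool: dict[str, list[int]] = {}
    for i, cat in enumerate(CATEGORIES):
        n_cat = int((cat_draws == i).sum())
        if cfg.quarter_allocation == "expected":
            quarter_pool[cat] = quota_quarters(n_cat, weights[cat])
        else:
            quarter_pool[cat] = [
                int(q) for q in rng.choice(nq, size=n_cat, p=weights[cat])
            ]

    originals: list[TweetRecord] = []
    for ci in cat_draws:
        cat = CATEGORIES[int(ci)]
        length = int(rng.integers(cfg.tweet_length[0], cfg.tweet_length[1] + 1))
        tokens = [
            vocab[cat][int(rng.integers(0, len(vocab[cat])))]
            if rng.random() >= cfg.shared_token_rate
            else shared[int(rng.integers(0, len(shared)))]
            for _ in range(length)
        ]
        phrase = _KEYWORD_CHOICES[int(rng.choice(len(_KEYWORD_CHOICES), p=_KEYWORD_WEIGHTS))]
        pos = int(rng.integers(0, length + 1))
        tokens[pos:pos] = phrase.split()
        qi = quarter_pool[cat].pop()
        ts = _random_instant(rng, *q_bounds[qi])
        author = pick_author(repeatable=True)
        rec = TweetRecord(
            id=make_id(),
            text=render_text(tokens),
            created_at=ts,
            author_id=author,
            gender=author_gender[author],
        )
        originals.append(rec)
        truth_rows.append(
            {"tweet_id": rec.id, "true_category": cat, "duplicate_of": "", "is_ad": False}
        )

    # 2. retweet duplicates of originals
    duplicates: list[TweetRecord] = []
    for _ in range(cfg.n_duplicates):
        src_idx = int(rng.integers(0, len(originals)))
        src = originals[src_idx]
        retweeter = pick_author(repeatable=False)
        delay = timedelta(seconds=int(rng.integers(60, 72 * 3600)))
        ts = min(src.created_at + delay, window_end - timedelta(seconds=1))
        rec = TweetRecord(
            id=make_id(),
            text=f"RT @{src.author_id}: {src.text}",
            created_at=ts,
            author_id=retweeter,
            gender=author_gender[retweeter],
        )
        duplicates.append(rec)
        truth_rows.append(
            {
                "tweet_id": rec.id,
                "true_category": truth_rows[src_idx]["true_category"],
                "duplicate_of": src.id,
                "is_ad": False,
            }
        )

    # 3. advertisement clusters: near-identical promotional texts
    ads: list[TweetRecord] = []
    for k in range(cfg.ad_clusters):
        base_len = max(10, cfg.tweet_length[1])
        base = [shared[int(rng.integers(0, len(shared)))] for _ in range(base_len)]
        base[:0] = ["fluoride", "varnish", "offer", f"ad{k:02d}"]
        base_ts = _random_instant(rng, q_bounds[0][0], q_bounds[-1][1])
        for j in range(cfg.ad_cluster_size):
            tokens = list(base)
            if j > 0:  # one-token variation keeps similarity high but not exact
                tokens[int(rng.integers(4, len(tokens)))] = f"promo{j:02d}"
            ts = min(base_ts + timedelta(hours=int(j)), window_end - timedelta(seconds=1))
            advertiser = pick_author(repeatable=False)
            rec = TweetRecord(
                id=make_id(),
                text=" ".join(tokens),
                created_at=ts,
                author_id=advertiser,
                gender=author_gender[advertiser],
            )
            ads.append(rec)
            truth_rows.append(
                {
                    "tweet_id": rec.id,
                    "true_category": "",
                    "duplicate_of": "",
                    "is_ad": True,
                }
            )

    everything = originals + duplicates + ads
    everything.sort(key=lambda r: (r.created_at, r.id))
    truth = GroundTruth(
        table=pd.DataFrame(truth_rows, columns=["tweet_id", "true_category", "duplicate_of", "is_ad"]),
        proportions=tuple(cfg.category_proportions),
        trend_slopes=tuple(cfg.trend_slopes),
        duplicate_fraction=cfg.duplicate_fraction,
    )
    return everything, truth


def generate_rater_labels(
    truth: GroundTruth,
    sample_size: int,
    rater_error_rates: tuple[float, float] = (0.1, 0.1),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate dual expert annotation of a random sample of originals.

    Each sampled post is labelled independently by two raters who report the
    true category with probability 1 - e and otherwise a uniformly random
    other category. Sampling is without replacement from non-duplicate,
    non-ad posts. Returns the long-format label table (tweet_id, rater_id,
    category).
    """
    for e in rater_error_rates:
        if not (0.0 <= e < 0.5):
            raise ValueError("rater error rates must be in [0, 0.5)")
    pool = truth.original_ids
    if sample_size > len(pool):
        raise ValueError(
            f"sample_size {sample_size} exceeds the {len(pool)} non-duplicate posts"
        )
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(pool), size=sample_size, replace=False)
    cat_of = truth.category_of()
    rows = []
    for idx in sorted(int(i) for i in chosen):
        tid = pool[idx]
        true_cat = cat_of[tid]
        for rater, e in zip(("rater1", "rater2"), rater_error_rates):
            if rng.random() < e:
                others = [c for c in CATEGORIES if c != true_cat]
                label = others[int(rng.integers(0, len(others)))]
            else:
                label = true_cat
            rows.append({"tweet_id": tid, "rater_id": rater, "category": label})
    return pd.DataFrame(rows, columns=["tweet_id", "rater_id", "category"])
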