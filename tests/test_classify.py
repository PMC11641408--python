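from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fluortweets.classify import (
    CATEGORIES,
    SeedSet,
    assign_category,
    build_seed_set,
    classify_corpus,
    cohens_kappa,
)
from fluortweets.normalize import normalize_text
from fluortweets.synthetic import GeneratorConfig, generate_corpus, generate_rater_labels

from conftest import rec


def labels_frame(rows):
    return pd.DataFrame(rows, columns=["tweet_id", "rater_id", "category"])


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([[25, 0], [0, 25]]) == pytest.approx(1.0)

    def test_independence_pattern_is_zero(self):
        assert cohens_kappa([[9, 21], [21, 49]]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        assert cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([[10, 0], [0, 0]])

    def test_matches_sklearn_on_random_tables(self):
        """Agreement with the standard implementation to 1e-12 on 100 tables."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            t = rng.integers(0, 30, size=(2, 2))
            n = t.sum()
            if n == 0:
                continue
            p_e = float((t.sum(1) * t.sum(0)).sum()) / (n * n)
            if abs(1 - p_e) < 1e-12:
                continue
            r1 = [0] * (t[0, 0] + t[0, 1]) + [1] * (t[1, 0] + t[1, 1])
            r2 = [0] * t[0, 0] + [1] * t[0, 1] + [0] * t[1, 0] + [1] * t[1, 1]
            expected = sklearn_metrics.cohen_kappa_score(r1, r2)
            assert cohens_kappa(t) == pytest.approx(expected, abs=1e-12)
            checked += 1


class TestBuildSeedSet:
    def corpus(self):
        return [
            rec("s1", "fluoride lowers iq worry"),
            rec("s2", "dentist visit varnish story"),
            rec("s3", "fluoride prevents cavities great"),
            rec("s4", "fluoride toxic avoid bad"),
        ]

    def test_consensus_enters_seed_set(self):
        labels = labels_frame(
            [("s1", "r1", "concern"), ("s1", "r2", "concern"),
             ("s2", "r1", "experience"), ("s2", "r2", "experience"),
             ("s3", "r1", "positive"), ("s3", "r2", "positive"),
             ("s4", "r1", "negative"), ("s4", "r2", "negative")]
        )
        seeds, report = build_seed_set(labels, self.corpus())
        assert [tid for tid, _ in seeds.members["concern"]] == ["s1"]
        assert report.n_rated == report.n_consensus == 4

    def test_disagreement_excluded_but_counted(self):
        labels = labels_frame(
            [("s1", "r1", "concern"), ("s1", "r2", "negative"),
             ("s2", "r1", "experience"), ("s2", "r2", "experience")]
        )
        seeds, report = build_seed_set(labels, self.corpus())
        assert "s1" not in {tid for m in seeds.members.values() for tid, _ in m}
        assert report.n_rated == 2
        assert report.n_consensus == 1

    def test_wrong_rating_count_rejected(self):
        labels = labels_frame([("s1", "r1", "concern")])
        with pytest.raises(ValueError, match="two distinct raters"):
            build_seed_set(labels, self.corpus())

    def test_unknown_category_rejected(self):
        labels = labels_frame([("s1", "r1", "meh"), ("s1", "r2", "meh")])
        with pytest.raises(ValueError, match="category"):
            build_seed_set(labels, self.corpus())

    def test_agreement_consistent_with_table(self):
        labels = labels_frame(
            [("s1", "r1", "concern"), ("s1", "r2", "concern"),
             ("s2", "r1", "concern"), ("s2", "r2", "negative"),
             ("s3", "r1", "positive"), ("s3", "r2", "positive"),
             ("s4", "r1", "negative"), ("s4", "r2", "negative")]
        )
        _, report = build_seed_set(labels, self.corpus())
        # concern one-vs-rest: a=1, b=1, c=0, d=2 -> agreement 3/4
        assert report.per_category["concern"]["percent_agreement"] == pytest.approx(0.75)


class TestAssignCategory:
    def seeds(self):
        return SeedSet(
            {
                "concern": [("c1", ("fluoride", "lowers", "iq"))],
                "experience": [("e1", ("dentist", "applied", "varnish", "today"))],
                "positive": [("p1", ("fluoride", "prevents", "cavities"))],
                "negative": [("n1", ("fluoride", "toxic", "poison"))],
            }
        )

    def test_exact_match_dominates(self):
        a = assign_category(("fluoride", "prevents", "cavities"), self.seeds())
        assert a.category == "positive"
        assert a.score == 1.0
        assert a.runner_up_margin > 0

    def test_no_shared_tokens_low_confidence_canonical_tiebreak(self):
        a = assign_category(("totally", "unrelated", "words"), self.seeds())
        assert a.score == 0.0
        assert a.low_confidence
        assert a.category == "concern"  # canonical order

    def test_nearest_seed_hand_traced(self):
        # dist to concern seed = 1 (insert), max len 4 -> 0.75
        # dist to positive seed = 3, max len 4 -> 0.25
        a = assign_category(("fluoride", "lowers", "iq", "maybe"), self.seeds())
        assert a.category == "concern"
        assert a.score == pytest.approx(0.75)

    def test_empty_tokens_assigned_by_tie_rule(self):
        a = assign_category((), self.seeds())
        assert a.score == 0.0
        assert a.low_confidence

    def test_incomplete_seed_set_rejected(self):
        seeds = SeedSet({"concern": [("c1", ("a",))]})
        with pytest.raises(ValueError, match="empty categories"):
            assign_category(("a",), seeds)

    def test_mean_top_k_aggregation_available(self):
        a = assign_category(
            ("fluoride", "lowers", "iq"), self.seeds(), aggregation="mean_top_k", top_k=1
        )
        assert a.category == "concern"


class TestClassifyCorpus:
    def test_study_percentages_from_counts(self):
        """Counts (10,428; 1,507; 3,897; 5,679) of 21,511 give the printed
        percentages 48.5 / 7.0 / 18.1 / 26.4."""
        from fluortweets._util import percentage

        counts = dict(zip(CATEGORIES, (10428, 1507, 3897, 5679)))
        assert sum(counts.values()) == 21511
        pcts = {c: percentage(n, 21511, 1) for c, n in counts.items()}
        assert pcts == {"concern": 48.5, "experience": 7.0, "positive": 18.1,
                        "negative": 26.4}

    def test_single_record_corpus_is_hundred_percent(self):
        seeds = SeedSet(
            {
                "concern": [("x", ("bad", "fluoride"))],
                "experience": [("e", ("went", "dentist"))],
                "positive": [("p", ("nice", "teeth"))],
                "negative": [("n", ("avoid", "it"))],
            }
        )
        records = [rec("only", "bad fluoride")]
        _, summary = classify_corpus(records, seeds)
        assert summary["counts"]["concern"] == 1
        assert summary["percentages"]["concern"] == 100.0

    def test_counts_sum_and_percentages_near_100(self):
        cfg = GeneratorConfig(n_tweets=300, duplicate_fraction=0.0, ad_clusters=0,
                              rng_seed=9)
        records, truth = generate_corpus(cfg)
        labels = generate_rater_labels(truth, 80, rater_error_rates=(0.0, 0.0), rng_seed=1)
        seeds, _ = build_seed_set(labels, records)
        assignments, summary = classify_corpus(records, seeds)
        assert sum(summary["counts"].values()) == len(records) == len(assignments)
        assert abs(sum(summary["percentages"].values()) - 100.0) <= 0.2

    def test_seed_tweets_keep_consensus_label_and_self_match(self):
        cfg = GeneratorConfig(n_tweets=200, duplicate_fraction=0.0, ad_clusters=0,
                              rng_seed=10)
        records, truth = generate_corpus(cfg)
        labels = generate_rater_labels(truth, 60, rater_error_rates=(0.0, 0.0), rng_seed=2)
        seeds, _ = build_seed_set(labels, records)
        assignments, _ = classify_corpus(records, seeds)
        by_id = {a.tweet_id: a for a in assignments}
        for cat, members in seeds.members.items():
            for tid, _toks in members:
                assert by_id[tid].category == cat
                assert by_id[tid].score == 1.0  # self-similarity

    def test_deterministic(self):
        cfg = GeneratorConfig(n_tweets=150, duplicate_fraction=0.0, ad_clusters=0,
                              rng_seed=4)
        records, truth = generate_corpus(cfg)
        labels = generate_rater_labels(truth, 40, rng_seed=3)
        seeds, _ = build_seed_set(labels, records)
        a1, s1 = classify_corpus(records, seeds)
        a2, s2 = classify_corpus(records, seeds)
        assert a1 == a2 and s1 == s2


def test_seed_set_rejects_multi_category_membership():
    with pytest.raises(ValueError, match="more than one"):
        SeedSet(
            {
                "concern": [("x", ("a",))],
                "experience": [("x", ("a",))],
                "positive": [],
                "negative": [],
            }
        )
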