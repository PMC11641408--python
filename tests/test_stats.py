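from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from fluortweets._util import percentage, round_half_up, truncated_mean
from fluortweets.classify import CATEGORIES, Assignment
from fluortweets.stats import (
    build_quarter_series,
    describe_counts,
    gender_breakdown,
    gender_chi_square,
    hashtag_frequencies,
    runs_pmf,
    runs_test,
    term_frequencies,
    two_sided_runs_p,
)

from _oracles import enumerate_runs_distribution, naive_describe
from conftest import rec


def assign(tweet_id, category):
    return Assignment(tweet_id=tweet_id, category=category, score=1.0,
                      runner_up_margin=1.0, low_confidence=False)


class TestQuarterSeries:
    def test_empty_corpus_all_zero(self):
        series = build_quarter_series([], [])
        assert len(series.quarters) == 12
        assert all(v == 0 for counts in series.counts.values() for v in counts)
        assert series.totals == [0] * 12

    def test_single_tweet_indexed_correctly(self):
        records = [rec("x", "fluoride", "2018-05-10T12:00:00")]
        series = build_quarter_series([assign("x", "concern")], records)
        expected = [0] * 12
        expected[5] = 1  # 2018-Q2 is the sixth quarter of the window
        assert series.counts["concern"] == expected
        assert series.totals == expected

    def test_totals_conserve_corpus_size(self):
        rng = np.random.default_rng(0)
        records, assignments = [], []
        for i in range(200):
            month = int(rng.integers(1, 13))
            year = int(rng.choice([2017, 2018, 2019]))
            records.append(rec(f"t{i}", "fluoride", f"{year}-{month:02d}-15T00:00:00"))
            assignments.append(assign(f"t{i}", CATEGORIES[int(rng.integers(0, 4))]))
        series = build_quarter_series(assignments, records)
        assert sum(series.totals) == 200
        for i in range(12):
            assert series.totals[i] == sum(series.counts[c][i] for c in CATEGORIES)


class TestDescribeCounts:
    def test_tiny_example(self):
        d = describe_counts([1, 2, 3])
        assert d["mean"] == 2 and d["sd"] == 1 and d["median"] == 2
        assert d["min"] == 1 and d["max"] == 3

    def test_truncated_quarterly_mean_of_study_total(self):
        # 21,511 posts over 12 quarters -> truncated mean 1,792
        per_quarter_total = 21511
        assert truncated_mean([per_quarter_total / 12] * 12) == 1792

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe_counts([])

    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            vals = rng.integers(0, 3000, size=int(rng.integers(2, 20))).tolist()
            d = describe_counts(vals)
            o = naive_describe(vals)
            for key in ("mean", "sd", "median", "min", "max"):
                assert d[key] == pytest.approx(o[key], abs=1e-9)


class TestRunsTest:
    def test_strict_alternation_counts_every_run(self):
        values = [1, 9, 1, 9, 1, 9, 1, 9, 1, 9, 1, 9]  # 6 above, 6 below median
        r = runs_test(values)
        assert r.n_runs == 12 and r.n_above == 6 and r.n_below == 6

    def test_two_blocks_two_runs(self):
        r = runs_test([5, 5, 5, 9, 9, 9], cutpoint=7)
        assert r.n_runs == 2

    def test_median_ties_dropped(self):
        r = runs_test([1, 2, 2, 3])  # median 2; the two 2s are dropped
        assert r.n_above == 1 and r.n_below == 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            runs_test([5])
        with pytest.raises(ValueError):
            runs_test([3, 3, 3], cutpoint=3)

    def test_exact_p_matches_enumeration_for_6_6_2(self):
        pmf = runs_pmf(6, 6)
        oracle = enumerate_runs_distribution(6, 6)
        p = two_sided_runs_p(pmf, 2)
        p_oracle = two_sided_runs_p(oracle, 2)
        assert p == pytest.approx(p_oracle)
        assert p == pytest.approx(4 / 924)  # 2 * P(R <= 2), C(12,6) = 924

    def test_exact_distribution_matches_enumeration_up_to_n12(self):
        """Closed-form run-count pmf equals brute-force enumeration for all
        group sizes with n1 + n2 <= 12."""
        for n1 in range(1, 12):
            for n2 in range(1, 13 - n1):
                pmf = runs_pmf(n1, n2)
                oracle = enumerate_runs_distribution(n1, n2)
                assert set(pmf) == set(oracle)
                for r_count, prob in oracle.items():
                    assert pmf[r_count] == pytest.approx(prob, abs=1e-12)

    def test_normal_approximation_for_long_series(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=40).tolist()
        r = runs_test(values)
        assert r.method == "normal_approx"
        assert 0.0 <= r.p_value <= 1.0

    def test_one_sided_degenerate_returns_p_one(self):
        r = runs_test([1, 2, 3, 4], cutpoint=0)
        assert r.n_runs == 1 and r.p_value == 1.0


class TestGenderChiSquare:
    def _fixture(self, table):
        """Build records/assignments realising a female/male x category table."""
        records, assignments = [], []
        i = 0
        for g_idx, gender in enumerate(("female", "male")):
            for c_idx, cat in enumerate(CATEGORIES):
                for _ in range(int(table[g_idx][c_idx])):
                    records.append(
                        rec(f"x{i}", "fluoride", "2018-01-15T00:00:00",
                            author=f"a{i}", gender=gender)
                    )
                    assignments.append(assign(f"x{i}", cat))
                    i += 1
        return records, assignments

    def test_perfect_independence_statistic_zero(self):
        records, assignments = self._fixture([[10, 10, 10, 10], [10, 10, 10, 10]])
        res = gender_chi_square(records, assignments, mode="omnibus")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2_statistic(self):
        # [[30,10],[10,30]] uncorrected: all expected 20, sum (O-E)^2/E = 20
        obs = np.array([[30, 10], [10, 30]], dtype=float)
        stat, _, _, _ = sps.chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(20.0)
        # concern row (30, 10); rest of categories sum to (10, 30)
        records, assignments = self._fixture([[30, 4, 3, 3], [10, 10, 10, 10]])
        per = gender_chi_square(records, assignments, mode="per_category",
                                yates_2x2=False)
        assert per["concern"]["result"].statistic == pytest.approx(20.0)

    def test_per_category_mode_emits_four_results(self):
        records, assignments = self._fixture([[12, 8, 9, 11], [10, 10, 12, 8]])
        per = gender_chi_square(records, assignments, mode="per_category")
        assert set(per) == set(CATEGORIES)
        for entry in per.values():
            assert entry["p_bonferroni"] >= entry["result"].p_value

    def test_unknown_gender_excluded_from_cells(self):
        records, assignments = self._fixture([[5, 5, 5, 5], [5, 5, 5, 5]])
        records.append(rec("u0", "fluoride", "2018-01-15T00:00:00", gender="unknown"))
        assignments.append(assign("u0", "concern"))
        res = gender_chi_square(records, assignments, mode="omnibus")
        assert res.table.sum() == 40  # the unknown-gender record is not counted

    def test_expected_zero_cell_named(self):
        records, assignments = self._fixture([[5, 0, 5, 5], [5, 0, 5, 5]])
        with pytest.raises(ValueError, match="cell"):
            gender_chi_square(records, assignments, mode="omnibus")

    def test_statistic_invariant_under_permutation(self):
        obs = np.array([[12, 8, 9, 11], [10, 10, 12, 8]], dtype=float)
        stat, _, _, _ = sps.chi2_contingency(obs, correction=False)
        perm = obs[:, [2, 0, 3, 1]][[1, 0], :]
        stat_p, _, _, _ = sps.chi2_contingency(perm, correction=False)
        assert stat == pytest.approx(stat_p)

    def test_matches_scipy_on_random_tables(self):
        """In-module Pearson statistic path agrees with an independent direct
        computation of sum (O-E)^2/E to 1e-12 on 100 random tables."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 100:
            t = rng.integers(1, 40, size=(2, 4)).astype(float)
            row, col = t.sum(1, keepdims=True), t.sum(0, keepdims=True)
            e = row @ col / t.sum()
            direct = float(((t - e) ** 2 / e).sum())
            stat, _, df, _ = sps.chi2_contingency(t, correction=False)
            assert stat == pytest.approx(direct, abs=1e-12)
            assert df == 3
            checked += 1


class TestFrequencies:
    def test_empty_corpus(self):
        assert term_frequencies([], top_n=5) == []

    def test_counting_and_tie_order(self):
        assert term_frequencies(["a a b", "a"], top_n=5) == [("a", 3), ("b", 1)]
        assert term_frequencies(["b a", "a b"], top_n=5) == [("a", 2), ("b", 2)]

    def test_top_n_validation(self):
        with pytest.raises(ValueError):
            term_frequencies(["a"], top_n=0)

    def test_hashtag_ranking(self):
        texts = ["#caries x", "#caries y #varnish", "#varnish z", "#caries q"]
        assert hashtag_frequencies(texts, top_n=2) == [("#caries", 3), ("#varnish", 2)]


class TestGenderBreakdown:
    def test_study_share_arithmetic(self):
        """The printed denominators reproduce: 18,715/21,511 -> 87%,
        6,987/10,428 -> 67%, 874/1,507 -> 58%."""
        assert percentage(18715, 21511, 0) == 87
        assert percentage(6987, 10428, 0) == 67
        assert percentage(874, 1507, 0) == 58

    def test_explicit_denominators(self):
        records = [
            rec("a", "x", gender="female"), rec("b", "x", gender="female"),
            rec("c", "x", gender="male"), rec("d", "x", gender="unknown"),
        ]
        assignments = [assign("a", "concern"), assign("b", "concern"),
                       assign("c", "concern"), assign("d", "negative")]
        out = gender_breakdown(records, assignments)
        assert out["n_total"] == 4 and out["n_identified"] == 3
        assert out["identified_pct"] == 75
        concern = out["per_category"]["concern"]
        assert concern["n_identified"] == 3 and concern["n_female"] == 2
        assert concern["female_pct"] == 67


class TestRounding:
    def test_half_up_one_decimal(self):
        assert round_half_up(26.35, 1) == 26.4
        assert round_half_up(48.477, 1) == 48.5

    def test_integer_percent(self):
        assert round_half_up(86.95, 0) == 87
        assert isinstance(round_half_up(86.95, 0), int)
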