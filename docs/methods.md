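# Methods

This note documents the models, conventions and design choices behind
`fluortweets`, in the order the pipeline applies them, and states what the
synthetic-data experiments do and do not establish.

## Tokenization

Raw post text is reduced to a word-token sequence by a fixed seven-step
pipeline: (1) strip one leading `RT @name:` retweet marker; (2) remove
URLs; (3) remove `@mention` tokens; (4) lowercase; (5) delete `#` so
hashtag words survive as plain words; (6) transliterate non-ASCII letters
via NFKD decomposition (dropping what has no ASCII decomposition) and
replace remaining non-alphanumerics with spaces; (7) split on whitespace.
Output tokens match `[a-z0-9]+` and the map is idempotent on its own
space-joined output.

The marker-stripping rule is load-bearing: it makes a retweet tokenize
identically to its original, which is what lets the downstream edit-distance
deduplication collapse retweet chains onto one exemplar. No stemming,
stop-word removal or lemmatization is applied — the comparison downstream is
deliberately of surface word forms, and adding linguistic normalization
would change what "syntactic similarity" measures.

## Word-based Levenshtein distance and similarity

The core primitive is Levenshtein edit distance computed over word tokens
(unit-cost insertions, deletions, substitutions; no transpositions; tokens
compared by exact equality), via the standard O(|a|·|b|) dynamic program.
The normalized similarity is `1 − d(a,b)/max(|a|,|b|)`, defined as 1 for
two empty sequences; it is symmetric, lies in [0, 1], and equals 1 exactly
on equal sequences. Normalizing by the longer length (rather than the sum
or the shorter length) keeps the score a strict-equality detector while
bounding it, and gives the useful pruning identity
`sim ≤ 1 − |len(a)−len(b)|/max(len)`.

Two exactness-preserving screens avoid the dynamic program for clearly
dissimilar pairs: the length bound above, and a token-multiset bound — an
alignment cannot match more tokens than the two multisets share, so
`sim ≤ shared/max(len)`. A cutoff-banded variant of the DP abandons a pair
once every entry of the current row exceeds the remaining edit budget.
These change running time only, never results; the test suite checks the
DP against a brute-force recursive oracle and against an independent
character-level implementation (edlib) under a token→character encoding.

## Deduplication

Greedy leader clustering in chronological order: each post joins the first
existing leader with similarity ≥ threshold (default 0.8), else founds a
new cluster. Processing in time order keeps the *earliest* exemplar — the
original precedes its retweets — and makes the result deterministic.
Retained leaders are pairwise below threshold by construction; every
eliminated post has similarity ≥ threshold to its leader.

The 0.8 default separates exact/near copies (retweets are similarity 1.0
after tokenization; one-token ad variations sit near 0.9) from mere topical
overlap, which on unigram-rendered synthetic text stays well below 0.8.
Clusters with ≥ 3 members are flagged as non-human (ads, bot chains); by
default one exemplar per flagged cluster survives, and
`drop_nonhuman_leaders` removes whole flagged clusters instead — both
behaviors are reasonable readings of "removing non-human content", so both
are configurable and the flag is always recorded. Finally, one post (the
earliest) per author is kept, so the analysed corpus has one post per
unique user.

## Seeded classification and agreement

Two raters each label a random sample once; a post enters the seed set only
if both chose the same category. Agreement is summarised per category
one-vs-rest: percent agreement `(a+d)/n` and Cohen's kappa
`(p_o − p_e)/(1 − p_e)` from the 2×2 table of "rater 1 said this category"
× "rater 2 said this category". Kappa is reported as undefined (None) when
the marginals are degenerate (a category no rater ever used).

Each unlabelled post's per-category score is the **maximum** normalized
similarity over that category's seeds — nearest labelled instance, the most
literal reading of "most syntactic similarity" (a `mean_top_k` aggregation
is available behind a config knob). Score ties are broken by mean
similarity over the tied categories' seeds, then by the canonical category
order (concern, experience, positive, negative); ties and sub-floor scores
(default floor 0.1) are flagged on the assignment. Seed posts keep their
consensus label and are not re-scored against themselves. Reported
percentages are rounded half-up to one decimal.

## Statistics

*Quarterly series.* Calendar quarters over the window (half-open
[start, end), timestamps UTC); the three-year default window yields exactly
12 quarters. Descriptives of quarterly totals report the sample SD (n−1),
midpoint median, and both the real and the integer-truncated mean — the
truncated value is the headline figure because total//12 is the convention
that reproduces the consistency relation in the reported corpus
(21,511/12 → 1,792).

*Runs test.* One-sample Wald–Wolfowitz about the median; values equal to
the cutpoint are dropped. For n ≤ 30 retained values the two-sided p comes
from the exact run-count distribution (composition-counting formula,
verified against exhaustive enumeration), doubling the smaller tail and
capping at 1; larger n uses the normal approximation with continuity
correction. The test detects non-randomness, not direction, so the package
reports it alongside the raw series rather than asserting "increase" from
the p-value alone.

*Chi-square.* Pearson chi-square on the gender × category table with
unknown-gender posts excluded (gender enters the pipeline as an attribute
supplied upstream, e.g. by an external profile classifier; inferring it is
out of scope). The 2×4 omnibus test is uncorrected; per-category 2×2 tests
(category vs rest) use Yates correction by default (toggleable) and are
reported both raw and Bonferroni-adjusted. A zero expected cell raises an
error naming the cell; the pipeline records the degeneracy in its report
instead of aborting. The computation is delegated to
`scipy.stats.chi2_contingency` behind the module surface.

*Frequencies.* Term and hashtag tables are plain counts, descending with
lexicographic tie-break; hashtags are maximal `#`+alphanumeric runs in the
raw text.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis assumes,
with full per-post ground truth (true category, duplicate parent, ad flag):

- **Mixture.** Original posts draw a category from configurable proportions
  (default 0.485 / 0.07 / 0.181 / 0.264, the shares reported for the
  reference corpus).
- **Text.** Bag-of-words rendering: each token comes from the category's
  private 50-word vocabulary or, with probability 0.15, from a 30-word
  shared pool; one harvest keyword phrase is embedded per post (so keyword
  filtering is lossless on synthetic corpora); topic hashtags are appended
  with small probabilities whose relative sizes mirror the reported hashtag
  ranking; 10% of posts carry a URL. The decoration rates are deliberately
  low: category vocabularies must dominate each post for nearest-seed
  classification to have a well-defined planted truth. Raising the shared
  or hashtag rates degrades separability smoothly and can be used to study
  classifier breakdown.
- **Duplicates.** A configurable fraction (default 0.80, chosen so the
  default corpus reproduces an elimination rate near the reference study's
  ~84%) are byte-copies of an original prefixed `RT @author:`, posted later
  by a different author. Ad clusters are near-identical promotional texts
  (one-token variations) from distinct authors.
- **Timing.** Each category has a linear quarterly rate multiplier
  `1 + slope·q/(Q−1)`; the default concern slope 1.75 reproduces the
  reference first-to-last-quarter growth (478 → 1,315). By default each
  category's posts are spread over quarters by largest-remainder quotas
  (`quarter_allocation="expected"`), making the planted trend an exact
  corpus property; the `"multinomial"` option draws each post's quarter
  independently, in which case the trend holds only in expectation — at
  n = 5,000 the median runs test then detects the default concern slope
  with roughly 77% power, so stochastic-timing experiments need more posts
  or steeper slopes to be reliable.
- **Attributes.** Author gender is planted per author
  (female/male/unknown = 0.75/0.12/0.13) independently of category; a small
  author-repeat rate (0.05) exercises the unique-author rule. All
  randomness flows from one `rng_seed`; corpora are byte-identical across
  runs for a fixed config.

Simulated dual annotation labels a without-replacement sample of originals;
each rater reports the truth with probability 1−e, else a uniform other
category, so the expected raw agreement is `(1−e₁)(1−e₂) + e₁e₂/3` — a
closed form the generator tests verify.

**What passing synthetic tests does not show.** The generator has no
English syntax, no semantics, no paraphrase — near-duplicates are exact
token copies, and categories are separable by construction. Results on it
validate the *mechanics* (dedup recovers planted duplicate fractions to
±0.02; classification recovers planted mixtures to ±0.05 with 50 seeds per
category; planted trends are detected), not classification accuracy on real
tweets, where categories share vocabulary heavily and paraphrased
duplicates would evade a surface edit distance.

## Numerical and interface conventions

- Percentages round half-up (26.35 → 26.4; integer shares for gender),
  matching how statistics packages print them.
- Timestamps are parsed as ISO-8601, naive values assumed UTC; quarter
  intervals are half-open to avoid double counting.
- Duplicate corpus ids are a hard error (corrupted input), never silently
  merged; malformed rows report their line number.
- Keyword matching is case-insensitive contiguous substring on the *raw*
  text, before tokenization, approximating platform advanced-search
  semantics; it is idempotent and order-preserving.
- The pipeline report's stage counts always satisfy
  `keyword_filtered − eliminated_by_dedup − removed_by_unique_author =
  classified`, and re-running a fixed config reproduces the report
  byte-for-byte.

## Problem sizes

The validation experiments run at n = 2,000 posts (mixture and duplicate
recovery, 10 and 1 generator seeds respectively), n = 5,000 (trend
detection, 20 seeds), and n = 6,000 for the end-to-end demonstration — 
sizes at which every recovery band above is comfortably resolvable while a
full suite run stays in the low minutes on one core.

## Known limitations

- Surface edit distance cannot merge paraphrased duplicates or split
  topically distinct posts that share phrasing; that is inherent to the
  method being implemented, not a defect of this implementation.
- Nearest-instance classification with few seeds in a category (e.g. a 7%
  category in a small annotation sample) is noisy, and an annotation sample
  can fail to produce any consensus seed for a rare category, in which case
  classification refuses to run rather than silently guess.
- The exact runs test requires a series that is not constant about its
  median; exactly-linear quota-allocated series with flat slopes can be
  degenerate, which callers must handle (the pipeline records it).
- Live platform harvesting, account-level bot detection and gender
  inference are out of scope by design; gender is consumed as an input
  attribute.
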