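"""Generate a synthetic post corpus with known ground truth.

The generator emulates a three-year harvest of short public posts about
topical fluoride: four latent content categories with separable
vocabularies, retweet copies, advertisement clusters, author multiplicity,
gender attributes and a rising "concern" trend across quarters.
"""

from collections import Counter

from fluortweets import GeneratorConfig, generate_corpus

config = GeneratorConfig(n_tweets=1000, rng_seed=42)
records, truth = generate_corpus(config)

n_dups = int((truth.table["duplicate_of"] != "").sum())
n_ads = int(truth.table["is_ad"].sum())
print(f"generated {len(records)} posts "
      f"({len(truth.original_ids)} originals, {n_dups} retweet copies, {n_ads} ad posts)")
print("true category mix of originals:",
      dict(Counter(truth.table.loc[truth.table['duplicate_of'].eq('')
                                   & ~truth.table['is_ad'], 'true_category'])))
print("first post:", records[0].text[:80], "...")

# Every post embeds at least one harvest keyword, so a keyword filter
# retains the whole corpus; the duplicate fraction (default 0.80) mirrors
# the elimination rate the deduplication stage is expected to reproduce.
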