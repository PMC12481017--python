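"""The three enrichment statistics on small constructed inputs.

1. Location-shuffling permutation enrichment of regions in an annotation
   (overlap measured in base pairs against 1000 length-preserving
   relocations within the universe).
2. Two-sided chi-squared on the proportion of query CpGs overlapping
   binding sites versus the background CpG set.
3. One-sided Fisher overrepresentation of a gene list in a gene set.
"""

import numpy as np

from tmrcall.enrichment import (
    cpg_proportion_chisq,
    fisher_overrepresentation,
    shuffle_enrichment,
)
from tmrcall.intervals import GenomicInterval

rng = np.random.default_rng(0)

# 1. query regions deliberately placed inside the annotation
universe = [GenomicInterval("chr1", 0, 1_000_000)]
annotation = [GenomicInterval("chr1", i * 100_000, i * 100_000 + 10_000) for i in range(10)]
query = [GenomicInterval("chr1", i * 100_000 + 2_000, i * 100_000 + 2_400) for i in range(10)]
res = shuffle_enrichment(query, annotation, universe, n_perm=1000, rng=1)
print(f"shuffle enrichment: observed {res.observed_overlap_bp:.0f} bp, "
      f"expected {res.expected_mean:.0f} bp, ratio {res.enrichment_ratio:.1f}, "
      f"empirical p = {res.empirical_p:.4f}")
print("  ratio >> 1 with small p: the regions sit in the annotation far more")
print("  than random relocations of the same lengths would.")

# 2. CpG-proportion chi-squared: 60% of query CpGs vs 10% of background in sites
sites = [GenomicInterval("chr1", 0, 1_000)]
query_cpgs = [("chr1", i) for i in range(60)] + [("chr1", 5_000 + i) for i in range(40)]
background = [("chr1", 100 + i) for i in range(100)] + [("chr1", 9_000 + i) for i in range(900)]
chi2, p, direction = cpg_proportion_chisq(query_cpgs, background, sites)
print(f"\nCpG proportion chi-squared: chi2 = {chi2:.1f}, p = {p:.2e}, {direction}")

# 3. Fisher: 8 of 10 query genes in a 10-gene set, background of 100
bg = [f"g{i}" for i in range(100)]
odds, p = fisher_overrepresentation(bg[:10], bg[:8] + bg[50:52], bg)
print(f"\nFisher overrepresentation: odds ratio = {odds:.1f}, one-sided p = {p:.2e}")
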