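"""Recompute the published FDR tiers from the shipped summary tables.

The package ships the chromosome-wise significant SNPs reported by a
Canchim growth-trait GWAS together with the number of SNPs tested per
autosome.  Running the step-up on those p-values reproduces every printed
tier and the per-trait significant counts.
"""

from gqlsgwas import bh_significant, fdr_tier, summarize_regions
from gqlsgwas.datasets import load_chromosome_counts, load_reported_hits

hits = load_reported_hits()
counts = load_chromosome_counts()
m = dict(zip(counts["chromosome"], counts["n_snps_evaluated"]))

for trait, grp in hits.groupby("trait", sort=False):
    n_sig = sum(
        int(bh_significant(cg["p_value"].tolist(), m[chrom], 0.10).sum())
        for chrom, cg in grp.groupby("chromosome")
    )
    print(f"{trait}: {n_sig} SNPs significant at chromosome-wise FDR 10%")

# tier of the birth-weight hit on BTA4 (p = 1.39e-6 among m = 32,187 tests)
tiers = fdr_tier({4: [1.39e-6]}, {4: m[4]})
print("BW rs43421095 tier:", tiers[4][0])
print("region tally:", summarize_regions(hits["region"]))
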