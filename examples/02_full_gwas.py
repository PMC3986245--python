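"""Full association scan on a synthetic study.

QC -> pedigree relationship matrix -> per-SNP GQLS score test against the
EBVs -> chromosome-wise FDR tiers -> allele-substitution effects and LD for
the significant SNPs.  A SNP's tier is the smallest FDR level (1/5/10%) at
which the chromosome-wise Benjamini-Hochberg step-up declares it.
"""

from gqlsgwas import SimulationConfig, make_study, run_pipeline

cfg = SimulationConfig(seed=7, n_snps=500, n_causal=2)
bundle = make_study(cfg)

result = run_pipeline(bundle.genotypes, bundle.pedigree, bundle.ebv,
                      traits=["BW", "WW", "LYW"])

sig = result.assoc[result.assoc.fdr_tier != "NS"]
print(f"tested {result.geno_qc.n_variants} SNPs on "
      f"{result.geno_qc.n_animals} animals; {len(sig)} significant")
cols = ["trait", "snp_id", "chromosome", "maf", "p_value", "fdr_tier", "effect"]
print(sig[cols].to_string(index=False))
# 'effect' is the allele-substitution regression slope: kg of EBV per copy
# of the B allele.  Compare the top hits with the simulated truth:
for trait, tt in bundle.truth.per_trait.items():
    print(trait, "truth:", {k: round(v, 3) for k, v in tt.causal_effects.items()})
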