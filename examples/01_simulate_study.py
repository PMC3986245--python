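"""Generate a synthetic study: pedigree, gene-dropped genotypes, EBVs.

The defaults emulate a commercial beef-cattle design: ~400 genotyped
animals, offspring of a small sire pool and a large dam pool, mean pedigree
inbreeding near 0.02, and EBVs for three weight traits at realistic scales.
"""

import numpy as np

from gqlsgwas import SimulationConfig, build_a_matrix, make_study

cfg = SimulationConfig(seed=1, n_snps=500)
bundle = make_study(cfg, "example_study")

rel = build_a_matrix(bundle.pedigree, bundle.genotypes.animal_ids)
print(f"pedigree animals:   {len(bundle.pedigree)}")
print(f"genotyped cohort:   {bundle.genotypes.n_animals} animals x "
      f"{bundle.genotypes.n_variants} SNPs")
print(f"mean inbreeding F:  {rel.f.mean():.4f}")
for trait in bundle.ebv.traits:
    v = bundle.ebv.frame[trait]
    print(f"{trait} EBV: mean {v.mean():+.2f} kg, sd {v.std():.2f} kg")
# The truth record lists the simulated causal SNPs per trait, for power checks.
print("causal SNPs (BW):", bundle.truth.per_trait["BW"].causal_effects)
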