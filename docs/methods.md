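# Methods

## Model and statistic

The association test treats the genotype, not the phenotype, as the
response.  For a single SNP, animal *i*'s genotype is its B-allele count
*gᵢ ∈ {0,1,2}*, summarised as the allele proportion *yᵢ = gᵢ/2*.  The EBV
*xᵢ* (kg) is the covariate of a logistic quasi-model

    logit E[y_i] = beta0 + beta1 x_i,        Cov(y) = phi A,

with **A** the pedigree numerator relationship matrix.  The covariance
assumption is exact for a neutral locus segregating through a pedigree: the
covariance of allele proportions between relatives is p(1−p)/2 times their
additive relationship.  The quasi-score test of β₁ = 0 needs only the null
model.  The null allele frequency is the GLS mean
p̂ = (1ᵀA⁻¹y)/(1ᵀA⁻¹1) (the solution of the quasi-score equation for a
constant mean), and the statistic is

    U      = x' A^-1 (y - p_hat 1)
    Var(U) = phi_hat [ x' A^-1 x - (x' A^-1 1)^2 / (1' A^-1 1) ]
    W_G    = U^2 / Var(U),   phi_hat = p_hat (1 - p_hat) / 2,

referred to χ²₁.  Because p̂ makes 1ᵀA⁻¹(y − p̂1) = 0, W_G is exactly
invariant to affine maps of x and to allele relabelling y → 1 − y; both are
enforced by tests, along with equality (to 1e-10) with an independent
Cholesky-whitening computation of the same statistic.  The score test
estimates no SNP effect; effect sizes come from a separate single-locus OLS
of EBV on allele count, reported in kg per B-allele copy.  The sign of the
reported effect follows the package's B-allele convention (below); only
magnitudes are comparable across conventions.

Missing genotypes are handled per SNP by complete-case restriction.  The
A-submatrix Cholesky factor is cached per distinct missingness pattern
(keyed on the row subset), since a scan re-solves against the same pattern
for thousands of SNPs.  No matrix inverse is ever formed explicitly.

Degenerate cases return NA rather than an inflated statistic: p̂ outside
(0,1), fewer than 3 called animals, or Var(U) ≤ 1e-12 (monomorphic-in-effect
columns).  A constant covariate raises an error, since the test is
undefined rather than null.

## Relationship matrix

A is built by the tabular method over a topological ordering (Kahn's
algorithm, ties broken by input order): a(i,j) = ½[a(sire,j) + a(dam,j)],
a(i,i) = 1 + ½ a(sire,dam), unknown parents contributing zero.  It is
always computed over the full ancestor closure of the requested animals and
then restricted, so relationships transmitted through ungenotyped ancestors
are preserved; the statistic itself uses the submatrix over the analysed
animals, which carries the same information for the score equation and
avoids singular padding.  Inbreeding is F = diag(A) − 1.  Correctness is
checked against Wright's path-counting values on toy pedigrees and against
Monte-Carlo gene-dropping kinship (10⁵ drops, agreement within 0.01).

## Quality control

Animals with call rate < 90 % are removed first; SNP rules are then
evaluated jointly on statistics computed once from the surviving animals:
call rate < 90 %, MAF < 5 % (strict inequality: a SNP at exactly 5 % is
kept), Hardy–Weinberg χ²₁ p < 1e-5 (no continuity correction; monomorphic
SNPs are conventionally assigned p = 1), and heterozygote excess
Ho − He > 0.15 with He = 2p̂q̂.  "Heterozygote excess" is read as the
difference of observed and expected heterozygosity, the only dimensionless
reading compatible with a fixed 15 % figure.  Joint evaluation makes QC
idempotent and order-independent across the SNP rules; at these thresholds
sequential application would differ negligibly.  Non-autosomal (outside
Bos taurus 1–29) or unpositioned variants are rejected at the format
boundary, so QC never sees them.

## Multiple testing

FDR control is chromosome-wise: the family for the BH step-up is the set of
SNPs tested on one chromosome after QC (per trait).  The step-up finds the
largest rank i with p(i) ≤ q·i/m and declares all p-values up to p(i)
significant — the step-up (rather than per-rank thresholding) is essential:
in the shipped worked examples a p-value that fails q·1/m is still
significant because rank 3 passes.  A SNP's tier is the smallest
q ∈ {1 %, 5 %, 10 %} at which it is declared; labels are serialized exactly
as "1%", "5%", "10%", "NS".  Equal p-values are kept in input order
(stable sort), so ties share a fate.  Callers may pass only the k smallest
p-values of a chromosome with the full m, which is valid precisely when the
omitted p-values are all larger — the assumption made for the shipped
summary table, which lists only the significant SNPs.

## Post-hoc analyses

LD is the composite genotypic r²: the squared Pearson correlation of
unphased dosages after joint complete-case restriction.  Genotypes here are
unphased, so the haplotype-based r² is not computable without imputation;
the composite version is its standard unphased analogue and is invariant to
allele relabelling.  The gene survey returns all genes overlapping a closed
±250 kb window (a gene at exactly 250,000 bp distance is included), nearest
first, ties broken by gene start.  Region labels are "genic" (a gene spans
the position), "upstream" (within 5 kb 5′ of a transcription start,
strand-aware) or "intergenic"; finer intron/exon classification would
require exon-level annotation and is out of scope.

## File conventions

Internal coordinates are 1-based inclusive; BED input (0-based half-open)
is converted at the boundary.  In the PLINK-style text dialect the B allele
of each SNP is the lexicographically later of its observed alleles — a
deterministic convention that needs no chip manifest; dosage files are
taken as already B-coded, with a sibling `.map` file supplying positions.
Upstream genotype-calling quality (e.g. low calling scores on intensity
platforms) is represented as missing genotypes in the input.

## Synthetic data

The generator emulates the study conditions the pipeline targets:

* **Pedigree** — discrete generations; each non-founder draws a sire from a
  small pool (default fraction 0.12 of the cohort size, i.e. ~48 sires per
  400 offspring) and a dam from a large pool (0.89, ~355 dams), reproducing
  the strong paternal half-sib skew of beef-cattle designs.  Defaults (100
  founders, 7 generations, 400 per generation → 2,500 animals with 400
  genotyped) give a mean pedigree inbreeding of ≈ 0.019 in the genotyped
  cohort, matching the ≈ 0.02 typical of such populations.
* **Genotypes** — gene dropping: founder alleles are Bernoulli draws at
  per-SNP frequencies from U(0.05, 0.5); each non-founder inherits one
  uniformly chosen allele per parent, independently per SNP.  SNPs are
  unlinked by default (sufficient for testing the score test and FDR); an
  optional Markov-copying mode (`ld_rho`) correlates adjacent founder
  alleles purely to exercise the LD analyses.  Default 2,900 SNPs across 29
  autosomes — the analyses are per-SNP, so desk-scale marker counts test
  the same code paths as a full chip.
* **EBVs** — true breeding value = causal-SNP part + polygenic part drawn
  as N(0, σ²A) via the Cholesky factor of A; the two parts are empirically
  scaled so the causal share is 1 − `polygenic_h2`.  EBV = TBV + noise with
  the noise sized so corr(EBV, TBV) = `ebv_accuracy`; the trait SDs
  describe the EBV scale (defaults 1.34 / 5.67 / 8.98 kg for BW / WW / LYW,
  means 0.20 / 1.24 / 0.95 kg).  The truth record retains causal SNP ids,
  realized effects and TBVs for power analyses.

What the generator does *not* emulate: linkage maps and realistic LD decay,
selection and assortative mating, admixture (multi-breed composites),
genotyping-platform error structure, and EBV shrinkage correlated with
family size.  Passing tests therefore demonstrate the statistical
machinery — calibration under relatedness, power, invariances — not
robustness to those real-data features.

## Verified operating characteristics

The test suite (fixed seeds, desk scale) verifies: type-I error at
α = 0.05 inside the 99 % binomial CI and KS-uniform p-values on 2,000 null
SNPs × 200 animals under strong half-sib relatedness; ≥ 95 % detection (at
chromosome-wise FDR 10 %) of a causal SNP explaining ~24 % of EBV variance
at n = 400 across 50 replicates, with < 10 % average relative bias of the
allele-substitution estimate; and exact reproduction of the shipped
published worked examples (26 FDR tiers, 4/12/10 significant counts,
18/7/1 region tally).

## Numerical choices

Cholesky factorization with a positive-definiteness error that points at
pedigree contradictions; Var(U) floor 1e-12; p-values rendered in
scientific notation with 3 significant digits on output; one global seed
per simulation with all draws taken from derived streams (seed, seed+1,
seed+2 for pedigree / genotypes / EBVs) so stages are individually
reproducible.
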