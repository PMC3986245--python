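"""Follow-up analyses for significant SNPs.

* allele-substitution effect: OLS slope of EBV on B-allele count, with the
  usual t-test on the slope;
* LD r-squared: squared Pearson correlation of unphased dosages (the
  composite genotypic r2);
* gene survey: genes overlapping a +/- 250 kb window around a SNP, ordered
  by distance, with a genic / upstream / intergenic region label;
* region tally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import MISSING, AnnotationSet, GeneRecord, VariantMeta

DEFAULT_GENE_WINDOW_BP = 250_000
UPSTREAM_WINDOW_BP = 5_000


@dataclass(frozen=True)
class EffectResult:
    snp_id: str
    mu: float  # intercept, kg
    b: float  # allele substitution effect, kg per B-allele copy
    slope_p_value: float


def allele_substitution(
    ebv: np.ndarray, counts: np.ndarray, snp_id: str = ""
) -> EffectResult:
    """OLS fit of EBV = mu + b * counts + e; pairs with a missing count are
    dropped.  The sign of b refers to the B allele; the reported magnitude is
    the average change in breeding value per allele copy."""
    ebv = np.asarray(ebv, dtype=float)
    counts = np.asarray(counts)
    ok = (counts != MISSING) & np.isfinite(ebv)
    ebv, counts = ebv[ok], counts[ok].astype(float)
    if len(ebv) < 3:
        raise ValueError("need at least 3 complete (ebv, count) pairs")
    if np.ptp(counts) == 0:
        raise ValueError("genotype counts are constant; effect undefined")
    fit = stats.linregress(counts, ebv)
    return EffectResult(snp_id, float(fit.intercept), float(fit.slope), float(fit.pvalue))


def ld_r2(calls_1: np.ndarray, calls_2: np.ndarray) -> float:
    """Composite (dosage) r2 between two SNPs: squared Pearson correlation of
    the genotype counts after joint complete-case restriction.  Invariant to
    allele relabelling of either SNP.  NaN if a column is monomorphic after
    restriction or fewer than 3 complete pairs remain."""
    c1 = np.asarray(calls_1)
    c2 = np.asarray(calls_2)
    ok = (c1 != MISSING) & (c2 != MISSING)
    c1, c2 = c1[ok].astype(float), c2[ok].astype(float)
    if len(c1) < 3 or np.ptp(c1) == 0 or np.ptp(c2) == 0:
        return float("nan")
    r = np.corrcoef(c1, c2)[0, 1]
    return float(r * r)


def _distance(gene: GeneRecord, position_bp: int) -> int:
    if gene.start_bp <= position_bp <= gene.end_bp:
        return 0
    return min(abs(gene.start_bp - position_bp), abs(gene.end_bp - position_bp))


def survey_genes(
    variant: VariantMeta,
    ann: AnnotationSet,
    window_bp: int = DEFAULT_GENE_WINDOW_BP,
) -> tuple[list[GeneRecord], str]:
    """Genes whose span overlaps [pos - window, pos + window], nearest first
    (distance 0 = containing; ties broken by gene start).

    Region label: "genic" when some gene contains the position; otherwise
    "upstream" when the position lies within 5 kb 5' of a transcription
    start (strand-aware); otherwise "intergenic".  The window is closed: a
    gene at exactly ``window_bp`` distance is included.
    """
    pos = variant.position_bp
    lo, hi = pos - window_bp, pos + window_bp
    hits = [
        g
        for g in ann.on_chromosome(variant.chromosome)
        if g.end_bp >= lo and g.start_bp <= hi
    ]
    hits.sort(key=lambda g: (_distance(g, pos), g.start_bp))
    if any(_distance(g, pos) == 0 for g in hits):
        label = "genic"
    elif any(_is_upstream(g, pos) for g in hits):
        label = "upstream"
    else:
        label = "intergenic"
    return hits, label


def _is_upstream(gene: GeneRecord, pos: int) -> bool:
    if gene.strand == "-":
        return gene.end_bp < pos <= gene.end_bp + UPSTREAM_WINDOW_BP
    return gene.start_bp - UPSTREAM_WINDOW_BP <= pos < gene.start_bp


def summarize_regions(labels) -> dict[str, int]:
    """Tally of region labels, deterministic (first-seen) order."""
    tally: dict[str, int] = {}
    for label in labels:
        label = str(label)
        tally[label] = tally.get(label, 0) + 1
    return tally
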