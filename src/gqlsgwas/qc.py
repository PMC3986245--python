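"""Genotype quality control.

Animals are filtered first (call rate), then SNPs; the four SNP rules are
evaluated jointly on statistics computed once from the surviving animals'
non-missing calls:

* call rate < 90%
* minor allele frequency < 5% (strict: MAF exactly at the threshold is kept)
* Hardy-Weinberg chi-square p < 1e-5 (1 df, no continuity correction)
* heterozygote excess: observed minus expected heterozygosity (Ho - He) > 0.15

Non-autosomal or unpositioned variants never reach this module — the readers
reject them — so the autosome rule is enforced at the format boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QCThresholds:
    hwe_p_min: float = 1e-5
    het_excess_max: float = 0.15
    maf_min: float = 0.05
    snp_call_rate_min: float = 0.90
    animal_call_rate_min: float = 0.90

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QCReport:
    """Exclusion counts per rule plus surviving dimensions."""

    n_animals_in: int = 0
    n_variants_in: int = 0
    animals_removed_call_rate: list[str] = field(default_factory=list)
    snps_removed: dict[str, list[str]] = field(default_factory=dict)
    n_animals_out: int = 0
    n_variants_out: int = 0

    def summary_lines(self) -> list[str]:
        lines = [
            f"animals: {self.n_animals_in} in, {self.n_animals_out} kept, "
            f"{len(self.animals_removed_call_rate)} removed by call rate",
            f"snps: {self.n_variants_in} in, {self.n_variants_out} kept",
        ]
        for rule, ids in self.snps_removed.items():
            lines.append(f"  removed by {rule}: {len(ids)}")
        return lines

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("axis\trule\tid\n")
            for aid in self.animals_removed_call_rate:
                fh.write(f"animal\tcall_rate\t{aid}\n")
            for rule, ids in self.snps_removed.items():
                for sid in ids:
                    fh.write(f"snp\t{rule}\t{sid}\n")


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square goodness-of-fit p-value for Hardy-Weinberg proportions.

    Expected genotype counts come from the sample allele frequency; 1 df, no
    continuity correction.  A monomorphic sample carries no information about
    HWE, so it returns p = 1.
    """
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("all genotype counts are zero")
    p_b = (n_ab + 2 * n_bb) / (2 * n)
    if p_b in (0.0, 1.0):
        return 1.0
    expected = np.array(
        [n * (1 - p_b) ** 2, n * 2 * p_b * (1 - p_b), n * p_b**2]
    )
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=1))


def _genotype_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        (calls == 0).sum(axis=0),
        (calls == 1).sum(axis=0),
        (calls == 2).sum(axis=0),
    )


def variant_statistics(geno: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Per-variant call rate, B-allele frequency, MAF, Ho, He, HWE p."""
    calls = geno.calls
    n_aa, n_ab, n_bb = _genotype_counts(calls)
    n_called = n_aa + n_ab + n_bb
    call_rate = n_called / geno.n_animals
    with np.errstate(invalid="ignore", divide="ignore"):
        p_b = np.where(n_called > 0, (n_ab + 2 * n_bb) / (2 * np.maximum(n_called, 1)), np.nan)
    maf = np.minimum(p_b, 1 - p_b)
    ho = np.where(n_called > 0, n_ab / np.maximum(n_called, 1), np.nan)
    he = 2 * p_b * (1 - p_b)
    hwe_p = np.array(
        [
            hwe_test(int(a), int(b), int(c)) if (a + b + c) > 0 else 1.0
            for a, b, c in zip(n_aa, n_ab, n_bb)
        ]
    )
    return {
        "call_rate": call_rate,
        "p_b": p_b,
        "maf": maf,
        "ho": ho,
        "he": he,
        "hwe_p": hwe_p,
    }


def animal_qc(
    geno: GenotypeMatrix, th: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop animals whose non-missing call fraction is below the threshold."""
    if geno.n_animals == 0 or geno.n_variants == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(n_animals_in=geno.n_animals, n_variants_in=geno.n_variants)
    call_rate = 1.0 - geno.missing_fraction_per_animal()
    keep = call_rate >= th.animal_call_rate_min
    report.animals_removed_call_rate = [
        a for a, k in zip(geno.animal_ids, keep) if not k
    ]
    if not keep.any():
        raise ValueError("animal QC removed every animal")
    kept_ids = [a for a, k in zip(geno.animal_ids, keep) if k]
    out = geno.subset_animals(kept_ids)
    report.n_animals_out = out.n_animals
    report.n_variants_out = out.n_variants
    return out, report


def snp_qc(
    geno: GenotypeMatrix, th: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the four SNP rules jointly on pre-filter statistics."""
    if geno.n_variants == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(n_animals_in=geno.n_animals, n_variants_in=geno.n_variants)
    s = variant_statistics(geno)
    fail = {
        "call_rate": s["call_rate"] < th.snp_call_rate_min,
        "maf": s["maf"] < th.maf_min,
        "hwe": s["hwe_p"] < th.hwe_p_min,
        "het_excess": (s["ho"] - s["he"]) > th.het_excess_max,
    }
    snp_ids = np.array([v.snp_id for v in geno.variants])
    keep = np.ones(geno.n_variants, dtype=bool)
    for rule, mask in fail.items():
        mask = np.asarray(mask) & ~np.isnan(s["call_rate"])
        report.snps_removed[rule] = list(snp_ids[mask])
        keep &= ~mask
    if not keep.any():
        raise ValueError("SNP QC removed every variant")
    out = geno.subset_variants(keep)
    report.n_animals_out = out.n_animals
    report.n_variants_out = out.n_variants
    return out, report


def apply_qc(
    geno: GenotypeMatrix, th: QCThresholds = QCThresholds()
) -> tuple[GenotypeMatrix, QCReport, QCReport]:
    """Animal filter first, then SNP filters (order of application)."""
    after_animals, animal_report = animal_qc(geno, th)
    after_snps, snp_report = snp_qc(after_animals, th)
    return after_snps, animal_report, snp_report
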