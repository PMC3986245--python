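"""End-to-end orchestration: QC -> A matrix -> GQLS scan -> chromosome-wise
FDR -> allele-substitution effects, LD and gene survey for significant SNPs.

This is the library behind the command-line interface; every stage is also
usable on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .fdr import FdrConfig, annotate_tiers
from .gqls import run_gwas
from .pedigree import build_a_matrix
from .posthoc import (
    DEFAULT_GENE_WINDOW_BP,
    allele_substitution,
    ld_r2,
    survey_genes,
)
from .qc import QCReport, QCThresholds, apply_qc
from .types import MISSING, AnnotationSet, EBVTable, GenotypeMatrix, Pedigree

log = logging.getLogger("gqlsgwas")


@dataclass
class PipelineResult:
    assoc: pd.DataFrame  # all traits stacked, association-table schema
    qc_animal_report: QCReport
    qc_snp_report: QCReport
    m_by_chrom: dict[int, int]  # post-QC tested SNPs per chromosome
    ld: pd.DataFrame  # pairwise r2 among significant SNPs, per trait/chrom
    geno_qc: GenotypeMatrix


def run_pipeline(
    geno: GenotypeMatrix,
    ped: Pedigree,
    ebv: EBVTable,
    traits: list[str],
    annotation: AnnotationSet | None = None,
    thresholds: QCThresholds = QCThresholds(),
    fdr_cfg: FdrConfig = FdrConfig(),
    window_bp: int = DEFAULT_GENE_WINDOW_BP,
) -> PipelineResult:
    if not traits:
        raise ValueError("no traits requested")
    geno_qc, animal_rep, snp_rep = apply_qc(geno, thresholds)
    for line in animal_rep.summary_lines() + snp_rep.summary_lines():
        log.info("qc: %s", line)
    m_by_chrom: dict[int, int] = {}
    for v in geno_qc.variants:
        m_by_chrom[v.chromosome] = m_by_chrom.get(v.chromosome, 0) + 1
    for chrom in sorted(m_by_chrom):
        log.info("fdr family: chromosome %d, m = %d SNPs tested", chrom, m_by_chrom[chrom])
    rel = build_a_matrix(ped, geno_qc.animal_ids)
    tables = []
    for trait in traits:
        table = run_gwas(geno_qc, ebv, trait, rel)
        table = annotate_tiers(table, m_by_chrom, fdr_cfg)
        tables.append(table)
    assoc = pd.concat(tables, ignore_index=True)

    sig = assoc["fdr_tier"] != "NS"
    snp_col = {v.snp_id: j for j, v in enumerate(geno_qc.variants)}
    # allele-substitution effects for significant SNPs only (single-locus OLS)
    for i in assoc.index[sig]:
        snp_id, trait = assoc.at[i, "snp_id"], assoc.at[i, "trait"]
        counts = geno_qc.calls[:, snp_col[snp_id]]
        x = ebv.values_for(trait, geno_qc.animal_ids)
        try:
            eff = allele_substitution(x, counts, snp_id)
            assoc.at[i, "effect"] = eff.b
        except ValueError:
            pass
    # gene survey
    if annotation is not None:
        meta = {v.snp_id: v for v in geno_qc.variants}
        for i in assoc.index[sig]:
            variant = meta[assoc.at[i, "snp_id"]]
            genes, label = survey_genes(variant, annotation, window_bp)
            assoc.at[i, "genes"] = ";".join(g.name for g in genes)
            assoc.at[i, "region"] = label
    # pairwise LD among significant SNPs within trait and chromosome
    ld_rows = []
    for (trait, chrom), grp in assoc[sig].groupby(["trait", "chromosome"], sort=False):
        ids = list(dict.fromkeys(grp["snp_id"]))
        for a_i in range(len(ids)):
            for b_i in range(a_i + 1, len(ids)):
                r2 = ld_r2(
                    geno_qc.calls[:, snp_col[ids[a_i]]],
                    geno_qc.calls[:, snp_col[ids[b_i]]],
                )
                ld_rows.append(
                    {"trait": trait, "chromosome": chrom,
                     "snp_1": ids[a_i], "snp_2": ids[b_i], "r2": r2}
                )
    ld = pd.DataFrame(ld_rows, columns=["trait", "chromosome", "snp_1", "snp_2", "r2"])
    return PipelineResult(assoc, animal_rep, snp_rep, m_by_chrom, ld, geno_qc)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the association, Manhattan, QC, m-per-chromosome and LD tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for trait, grp in result.assoc.groupby("trait", sort=False):
        p = out / f"assoc_{trait}.tsv"
        _io.write_assoc_table(grp.reset_index(drop=True), p)
        paths[f"assoc_{trait}"] = p
        p = out / f"manhattan_{trait}.tsv"
        _io.write_manhattan_table(grp, p)
        paths[f"manhattan_{trait}"] = p
    paths["qc_report"] = out / "qc_report.tsv"
    with open(paths["qc_report"], "w") as fh:
        fh.write("axis\trule\tid\n")
        for aid in result.qc_animal_report.animals_removed_call_rate:
            fh.write(f"animal\tcall_rate\t{aid}\n")
        for rule, ids in result.qc_snp_report.snps_removed.items():
            for sid in ids:
                fh.write(f"snp\t{rule}\t{sid}\n")
    paths["m_by_chrom"] = out / "snps_per_chromosome.tsv"
    with open(paths["m_by_chrom"], "w") as fh:
        fh.write("chromosome\tn_snps_tested\n")
        for chrom in sorted(result.m_by_chrom):
            fh.write(f"{chrom}\t{result.m_by_chrom[chrom]}\n")
    paths["ld"] = out / "ld_significant.tsv"
    result.ld.to_csv(paths["ld"], sep="\t", index=False, float_format="%.6g")
    return paths
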