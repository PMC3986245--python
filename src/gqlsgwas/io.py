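"""Readers and writers for every external format the pipeline touches.

Formats
-------
* pedigree: whitespace- or comma-delimited, 3+ columns (animal, sire, dam),
  ``0`` or empty field = unknown parent.
* genotypes: either a PLINK-style text ``.ped``/``.map`` pair (``ped_map``
  dialect) or a dosage TSV with a header of SNP ids and one animal per row
  (``dosage_tsv`` dialect, values in {0,1,2,NA}).  Both dialects take variant
  positions from a ``.map`` file with the same stem.
* EBVs: long TSV ``animal_id  trait  value``.
* gene annotation: BED4 (0-based half-open, converted to 1-based inclusive
  on read) or GFF3 ``gene`` features.
* association and Manhattan tables: TSV with a fixed column order.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ASSOC_COLUMNS,
    MISSING,
    UNKNOWN,
    AnnotationSet,
    EBVTable,
    GeneRecord,
    GenotypeMatrix,
    Pedigree,
    PedigreeRecord,
    VariantMeta,
    empty_assoc_table,
)

# ---------------------------------------------------------------------------
# pedigree


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3+ column parentage table; extra columns are ignored."""
    records = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in (line.split(",") if "," in line else line.split())]
            if len(fields) < 3:
                raise ValueError(f"pedigree line needs >= 3 columns: {line!r}")
            animal, sire, dam = fields[0], fields[1] or UNKNOWN, fields[2] or UNKNOWN
            records.append(PedigreeRecord(animal, sire, dam))
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in ped.records:
            fh.write(f"{rec.animal_id}\t{rec.sire_id}\t{rec.dam_id}\n")


# ---------------------------------------------------------------------------
# genotypes


def _read_map(path: Path) -> list[tuple[int, str, int]]:
    """PLINK .map: chrom, snp_id, cM, bp per line."""
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            chrom, snp_id, _cm, bp = line.split()[:4]
            out.append((int(chrom), snp_id, int(bp)))
    return out


def read_genotypes(path: str | Path, dialect: str = "dosage_tsv") -> GenotypeMatrix:
    """Read genotypes as B-allele counts.

    ``ped_map``: PLINK text .ped (allele pairs A/C/G/T, 0 = missing) plus a
    sibling .map.  The B allele of each SNP is the lexicographically later of
    the alleles observed there, so the coding is deterministic without a chip
    manifest; a SNP with three observed alleles is an error.

    ``dosage_tsv``: tab-separated, header ``animal_id`` then SNP ids, cells in
    {0, 1, 2, NA}; dosages are taken as already B-coded.  A sibling .map file
    supplies chromosome/position (the dosage header has no position channel).
    """
    path = Path(path)
    if dialect == "ped_map":
        return _read_ped_map(path)
    if dialect == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_ped_map(path: Path) -> GenotypeMatrix:
    variants_meta = _read_map(path.with_suffix(".map"))
    n_var = len(variants_meta)
    animal_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_var:
                raise ValueError(
                    f".ped row for {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields)} fields, expected {6 + 2 * n_var}"
                )
            animal_ids.append(fields[1])
            pairs = [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(n_var)]
            allele_rows.append(pairs)
    calls = np.full((len(animal_ids), n_var), MISSING, dtype=np.int8)
    variants = []
    for j, (chrom, snp_id, bp) in enumerate(variants_meta):
        observed = sorted(
            {a for row in allele_rows for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise ValueError(f"{snp_id}: more than two alleles observed: {observed}")
        if not observed:
            observed = ["A"]
        allele_b = observed[-1]
        allele_a = observed[0] if len(observed) == 2 else allele_b
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == allele_b) + (a2 == allele_b)
        variants.append(VariantMeta(chrom, bp, snp_id, allele_a, allele_b))
    return GenotypeMatrix(animal_ids, variants, calls)


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    variants_meta = _read_map(path.with_suffix(".map"))
    by_id = {snp_id: (chrom, bp) for chrom, snp_id, bp in variants_meta}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        snp_ids = header[1:]
        animal_ids: list[str] = []
        rows: list[list[int]] = []
        for fields in reader:
            if not fields:
                continue
            animal_ids.append(fields[0])
            row = []
            for snp_id, cell in zip(snp_ids, fields[1:]):
                if cell in ("NA", "", "."):
                    row.append(MISSING)
                    continue
                try:
                    value = int(cell)
                except ValueError:
                    raise ValueError(
                        f"non-integer dosage {cell!r} for {snp_id}"
                    ) from None
                row.append(value)
            rows.append(row)
    variants = []
    for snp_id in snp_ids:
        if snp_id not in by_id:
            raise ValueError(f"{snp_id} missing from sibling .map file")
        chrom, bp = by_id[snp_id]
        variants.append(VariantMeta(chrom, bp, snp_id))
    return GenotypeMatrix(animal_ids, variants, np.array(rows, dtype=np.int8))


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage TSV plus its sibling .map file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("animal_id\t" + "\t".join(v.snp_id for v in geno.variants) + "\n")
        for i, animal in enumerate(geno.animal_ids):
            cells = [
                "NA" if c == MISSING else str(int(c)) for c in geno.calls[i]
            ]
            fh.write(animal + "\t" + "\t".join(cells) + "\n")
    with open(path.with_suffix(".map"), "w") as fh:
        for v in geno.variants:
            fh.write(f"{v.chromosome}\t{v.snp_id}\t0\t{v.position_bp}\n")


# ---------------------------------------------------------------------------
# EBVs


def read_ebv(path: str | Path) -> EBVTable:
    """Long TSV: animal_id, trait, value (kg); header optional."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if list(df.columns[:3]) != ["animal_id", "trait", "value"]:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["animal_id", "trait", "value"],
            dtype={0: str},
        )
    dup = df.duplicated(subset=["animal_id", "trait"])
    if dup.any():
        raise ValueError("duplicate (animal, trait) EBV entries")
    wide = df.pivot(index="animal_id", columns="trait", values="value")
    wide.columns.name = None
    return EBVTable(wide)


def write_ebv(ebv: EBVTable, path: str | Path) -> None:
    long = (
        ebv.frame.reset_index()
        .melt(id_vars=ebv.frame.index.name or "index", var_name="trait", value_name="value")
    )
    long.columns = ["animal_id", "trait", "value"]
    long = long.sort_values(["animal_id", "trait"], kind="stable")
    long.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read gene intervals from BED4 or GFF3 (by extension).

    BED is 0-based half-open and converted to 1-based inclusive here; GFF3 is
    already 1-based inclusive.  Only ``gene`` features of a GFF3 are kept.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    return _read_bed(path)


def _read_bed(path: Path) -> AnnotationSet:
    genes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                fields = line.split()
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ValueError(f"malformed BED interval {name}: start {start} >= end {end}")
            strand = fields[5] if len(fields) > 5 else "+"
            genes.append(GeneRecord(name, int(chrom), start + 1, end, strand))
    return AnnotationSet(genes)


def _read_gff3(path: Path) -> AnnotationSet:
    genes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields[:9]
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attr.get("Name") or attr.get("ID") or attr.get("gene_id") or "?"
            feature_class = attr.get("biotype")
            genes.append(
                GeneRecord(name, int(chrom), int(start), int(end),
                           strand if strand in "+-" else "+", feature_class)
            )
    return AnnotationSet(genes)


def write_annotation_bed(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in ann.genes:
            fh.write(
                f"{g.chromosome}\t{g.start_bp - 1}\t{g.end_bp}\t{g.name}\t0\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# association / Manhattan tables


def write_assoc_table(results: pd.DataFrame, path: str | Path) -> None:
    """Deterministic column order; p-values in scientific notation with
    three significant digits."""
    df = results.copy() if len(results) else empty_assoc_table()
    for col in ASSOC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[ASSOC_COLUMNS]
    out = df.copy()
    for col in ("p_value",):
        out[col] = [
            "NA" if (isinstance(v, float) and math.isnan(v)) else f"{float(v):.3E}"
            for v in df[col]
        ]
    for col in ("maf", "p_hat", "w_g", "effect"):
        out[col] = [
            "NA" if (isinstance(v, float) and math.isnan(v)) else f"{float(v):.6g}"
            for v in df[col]
        ]
    out.to_csv(path, sep="\t", index=False)


def read_assoc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"snp_id": str})
    return df


def write_manhattan_table(results: pd.DataFrame, path: str | Path) -> None:
    """Plot-ready table: chromosome, position in Mbp, -log10 p-value."""
    rows = []
    for _, r in results.iterrows():
        p = r["p_value"]
        rows.append(
            {
                "chromosome": int(r["chromosome"]),
                "position_mbp": r["position_bp"] / 1e6,
                "neg_log10_p": -math.log10(p) if p == p and p > 0 else float("nan"),
                "fdr_tier": r.get("fdr_tier", "NS"),
            }
        )
    pd.DataFrame(rows, columns=["chromosome", "position_mbp", "neg_log10_p", "fdr_tier"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
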