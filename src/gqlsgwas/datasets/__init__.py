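"""Worked-example data shipped with the package.

Summary statistics published by a genome-wide association study of growth
traits (birth, weaning and long-yearling weight) in Canchim beef cattle:
the table of chromosome-wise significant SNPs (p-values, FDR tiers, MAF,
allele-substitution effects, gene and region annotations) and the number of
SNPs evaluated per Bos taurus autosome after quality control.  These power
the multiple-testing worked examples and the acceptance checks; the
underlying genotype data are not public.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reported_hits", "load_chromosome_counts"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reported_hits() -> pd.DataFrame:
    """26 chromosome-wise significant SNPs for BW / WW / LYW as published."""
    df = _read("canchim_reported_hits.tsv")
    df["snp_id"] = df["snp_id"].astype(str)
    return df


def load_chromosome_counts() -> pd.DataFrame:
    """SNPs evaluated per autosome (the per-chromosome FDR family sizes m)."""
    return _read("canchim_chromosome_counts.tsv")
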