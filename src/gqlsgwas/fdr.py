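"""Chromosome-wise Benjamini-Hochberg FDR with 1% / 5% / 10% tier labels.

The step-up procedure sorts the m p-values of one chromosome in ascending
order, finds the largest rank i with p(i) <= q * i / m, and declares that
p-value and all smaller ones significant.  Step-up matters: a small p-value
that misses its own per-rank threshold is still rescued when a larger rank
passes, which is exactly the behaviour the 10%-tier worked examples require.

Callers may pass only the k smallest p-values of a chromosome together with
the full test count m >= k; ranks are then still 1..k, which is valid as
long as the omitted p-values really are larger than every one supplied.

A SNP's tier is the smallest q level at which it is declared significant
within its chromosome; "NS" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

DEFAULT_Q_LEVELS = (0.01, 0.05, 0.10)


@dataclass(frozen=True)
class FdrConfig:
    q_levels: tuple[float, ...] = DEFAULT_Q_LEVELS

    def __post_init__(self):
        qs = self.q_levels
        if not qs or any(not 0 < q < 1 for q in qs) or list(qs) != sorted(set(qs)):
            raise ValueError("q_levels must be strictly increasing, in (0, 1)")

    def tier_label(self, q: float) -> str:
        return f"{q * 100:g}%"


def bh_significant(p_values: Sequence[float], m: int, q: float) -> np.ndarray:
    """Boolean significance flags (input order) of the BH step-up at level q.

    ``m`` is the total number of tests in the family (all SNPs tested on the
    chromosome); it may exceed ``len(p_values)`` when only the smallest
    p-values are supplied.
    """
    p = np.asarray(p_values, dtype=float)
    if m < len(p):
        raise ValueError(f"m = {m} < number of p-values = {len(p)}")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if len(p) == 0:
        return np.zeros(0, dtype=bool)
    # stable sort: equal p-values keep input order
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1)
    passed = p[order] <= q * ranks / m
    flags = np.zeros(len(p), dtype=bool)
    if passed.any():
        cutoff = np.max(np.flatnonzero(passed))
        flags[order[: cutoff + 1]] = True
    return flags


def fdr_tier(
    p_values_by_chrom: Mapping[int, Sequence[float]],
    m_by_chrom: Mapping[int, int],
    cfg: FdrConfig = FdrConfig(),
) -> dict[int, list[str]]:
    """Tier per SNP (input order within chromosome): smallest passing q level."""
    tiers: dict[int, list[str]] = {}
    for chrom, p_values in p_values_by_chrom.items():
        m = m_by_chrom[chrom]
        labels = ["NS"] * len(p_values)
        for q in sorted(cfg.q_levels, reverse=True):
            flags = bh_significant(p_values, m, q)
            for i, flagged in enumerate(flags):
                if flagged:
                    labels[i] = cfg.tier_label(q)
        tiers[chrom] = labels
    return tiers


def annotate_tiers(assoc, m_by_chrom: Mapping[int, int], cfg: FdrConfig = FdrConfig()):
    """Fill the ``fdr_tier`` column of an association table, per trait and
    chromosome, ignoring NA p-values (they stay "NS")."""
    assoc = assoc.copy()
    assoc["fdr_tier"] = "NS"
    for (_trait, chrom), grp in assoc.groupby(["trait", "chromosome"], sort=False):
        valid = grp["p_value"].notna()
        if not valid.any():
            continue
        p = grp.loc[valid, "p_value"].tolist()
        labels = fdr_tier({chrom: p}, {chrom: m_by_chrom[chrom]}, cfg)[chrom]
        assoc.loc[grp.index[valid], "fdr_tier"] = labels
    return assoc
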