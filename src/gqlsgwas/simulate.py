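"""Synthetic study generator: pedigree, gene-dropped genotypes, EBVs.

The generator emulates the structure of a commercial beef-cattle design: a
few hundred genotyped animals in the youngest generation, the offspring of
few sires and many dams (strong paternal half-sib structure), embedded in a
larger multi-generation pedigree; dense unlinked autosomal SNPs obtained by
gene dropping founder alleles; and EBVs for three correlated weight traits
built from a causal-SNP part plus a pedigree-polygenic part, observed with
configurable accuracy.  Defaults give 400 genotyped animals and trait scales
of roughly 1.3 / 5.7 / 9.0 kg EBV standard deviations for birth, weaning and
long-yearling weight, the magnitudes typical of Canchim growth evaluations.

All randomness flows from the single ``seed`` in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .pedigree import build_a_matrix
from .types import EBVTable, GenotypeMatrix, Pedigree, PedigreeRecord, VariantMeta
from . import io as _io

import pandas as pd


@dataclass(frozen=True)
class SimulationConfig:
    n_founders: int = 100
    n_per_generation: int = 400
    n_generations: int = 7  # founder generation included; deep enough for mean F near 0.02
    sire_fraction: float = 0.12  # sire-pool size / offspring count (49:400 skew)
    dam_fraction: float = 0.89  # dam-pool size / offspring count (355:400)
    n_snps: int = 2900
    n_chromosomes: int = 29
    chromosome_length_bp: int = 100_000_000
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.50
    ld_rho: float = 0.0  # Markov copying prob between adjacent founder alleles
    n_causal: int = 5
    causal_effect_sd: float = 1.0
    polygenic_h2: float = 0.80  # share of true-breeding-value variance that is polygenic
    ebv_accuracy: float = 0.70
    traits: tuple[str, ...] = ("BW", "WW", "LYW")
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: {"BW": 0.20, "WW": 1.24, "LYW": 0.95}
    )
    trait_sds: Mapping[str, float] = field(
        default_factory=lambda: {"BW": 1.34, "WW": 5.67, "LYW": 8.98}
    )
    seed: int = 0

    def __post_init__(self):
        if min(self.n_founders, self.n_per_generation, self.n_generations, self.n_snps) < 1:
            raise ValueError("counts must be positive")
        if self.n_chromosomes < 1 or self.n_chromosomes > 29:
            raise ValueError("n_chromosomes must be in 1..29")
        for frac in (self.sire_fraction, self.dam_fraction, self.ebv_accuracy):
            if not 0 < frac <= 1:
                raise ValueError("fractions must be in (0, 1]")
        if not 0 <= self.polygenic_h2 < 1 or not 0 <= self.ld_rho < 1:
            raise ValueError("polygenic_h2 and ld_rho must be in [0, 1)")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal exceeds n_snps")


@dataclass
class TraitTruth:
    causal_effects: dict[str, float]  # snp_id -> kg per B-allele copy
    tbv: pd.Series  # true breeding values, indexed by animal id


@dataclass
class Truth:
    per_trait: dict[str, TraitTruth]


def _sexes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.random(n) < 0.5  # True = male


def simulate_pedigree(cfg: SimulationConfig) -> tuple[Pedigree, list[str]]:
    """Discrete-generation pedigree; returns it plus the youngest-generation
    ids (the genotyped cohort).  Non-founders draw a sire from a small sire
    pool and a dam from a large dam pool of the previous generation."""
    rng = np.random.default_rng(cfg.seed)
    records: list[PedigreeRecord] = []
    prev_ids = [f"G0_{i:05d}" for i in range(cfg.n_founders)]
    prev_male = _sexes(rng, cfg.n_founders)
    records.extend(PedigreeRecord(a) for a in prev_ids)
    latest = prev_ids
    for g in range(1, cfg.n_generations):
        males = [a for a, m in zip(prev_ids, prev_male) if m]
        females = [a for a, m in zip(prev_ids, prev_male) if not m]
        if not males or not females:
            raise ValueError("sire or dam pool is empty; increase n_founders")
        n_off = cfg.n_per_generation
        n_sires = max(1, min(len(males), round(cfg.sire_fraction * n_off)))
        n_dams = max(1, min(len(females), round(cfg.dam_fraction * n_off)))
        sire_pool = list(rng.choice(males, size=n_sires, replace=False))
        dam_pool = list(rng.choice(females, size=n_dams, replace=False))
        ids = [f"G{g}_{i:05d}" for i in range(n_off)]
        sires = rng.choice(sire_pool, size=n_off)
        dams = rng.choice(dam_pool, size=n_off)
        records.extend(
            PedigreeRecord(a, s, d) for a, s, d in zip(ids, sires, dams)
        )
        prev_ids, prev_male, latest = ids, _sexes(rng, n_off), ids
    return Pedigree(records), latest


def _variant_grid(cfg: SimulationConfig) -> list[VariantMeta]:
    variants = []
    base = cfg.n_snps // cfg.n_chromosomes
    extra = cfg.n_snps % cfg.n_chromosomes
    for chrom in range(1, cfg.n_chromosomes + 1):
        k = base + (1 if chrom <= extra else 0)
        if k == 0:
            continue
        spacing = cfg.chromosome_length_bp // (k + 1)
        for i in range(k):
            variants.append(
                VariantMeta(chrom, spacing * (i + 1), f"snp_c{chrom}_{i:05d}", "A", "B")
            )
    return variants


def drop_genotypes(ped: Pedigree, cfg: SimulationConfig) -> GenotypeMatrix:
    """Gene dropping over the whole pedigree.

    Founder haplotype alleles are Bernoulli draws at per-SNP frequencies from
    U(founder_maf_low, founder_maf_high); with ``ld_rho`` > 0 adjacent
    founder alleles on a chromosome are Markov copies of their neighbour with
    that probability, giving non-trivial LD for the r2 analyses.  Every
    non-founder inherits one uniformly chosen allele per parent, independently
    per SNP (unlinked transmission).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    variants = _variant_grid(cfg)
    n_snps = len(variants)
    order = ped.topological_order
    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    freqs = rng.uniform(cfg.founder_maf_low, cfg.founder_maf_high, size=n_snps)
    hap1 = np.zeros((n, n_snps), dtype=np.int8)
    hap2 = np.zeros((n, n_snps), dtype=np.int8)
    founders = [a for a in order if ped.record(a).is_founder]
    f_idx = np.array([pos[a] for a in founders])
    chrom_of = np.array([v.chromosome for v in variants])
    new_chrom = np.ones(n_snps, dtype=bool)
    new_chrom[1:] = chrom_of[1:] != chrom_of[:-1]
    for hap in (hap1, hap2):
        base = (rng.random((len(founders), n_snps)) < freqs).astype(np.int8)
        if cfg.ld_rho > 0:
            copy = rng.random((len(founders), n_snps)) < cfg.ld_rho
            copy[:, new_chrom] = False
            out = base.copy()
            for j in range(1, n_snps):
                out[:, j] = np.where(copy[:, j], out[:, j - 1], base[:, j])
            base = out
        hap[f_idx] = base
    for aid in order:
        rec = ped.record(aid)
        if rec.is_founder:
            continue
        i = pos[aid]
        si, di = pos[rec.sire_id], pos[rec.dam_id]
        pick_s = rng.integers(0, 2, size=n_snps)
        pick_d = rng.integers(0, 2, size=n_snps)
        hap1[i] = np.where(pick_s == 0, hap1[si], hap2[si])
        hap2[i] = np.where(pick_d == 0, hap1[di], hap2[di])
    calls = (hap1 + hap2).astype(np.int8)
    return GenotypeMatrix(order, variants, calls)


def simulate_ebv(
    geno: GenotypeMatrix, ped: Pedigree, cfg: SimulationConfig
) -> tuple[EBVTable, Truth]:
    """EBVs per trait for the animals of ``geno``.

    True breeding value = causal-SNP part (empirically scaled to a
    ``1 - polygenic_h2`` share of the trait's genetic variance) + polygenic
    part drawn as N(0, sigma2 * A).  EBV = TBV + estimation noise sized so
    corr(EBV, TBV) = ebv_accuracy in expectation, then shifted to the trait
    mean.  The truth record keeps the realized causal effects and TBVs for
    power analyses.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    rel = build_a_matrix(ped, geno.animal_ids)
    chol = np.linalg.cholesky(rel.a)
    n = geno.n_animals
    dosages = geno.calls.astype(float)
    frame = {}
    per_trait: dict[str, TraitTruth] = {}
    for trait in cfg.traits:
        # trait_sds describe the EBV scale; with EBV = TBV + noise and
        # corr(EBV, TBV) = r, a TBV sd of r * sd_target yields an EBV sd
        # of sd_target.
        sd_target = float(cfg.trait_sds.get(trait, 1.0)) * cfg.ebv_accuracy
        mean_target = float(cfg.trait_means.get(trait, 0.0))
        var_causal_target = (1.0 - cfg.polygenic_h2) * sd_target**2
        var_poly_target = cfg.polygenic_h2 * sd_target**2
        causal = np.zeros(n)
        effects: dict[str, float] = {}
        if cfg.n_causal > 0:
            idx = rng.choice(geno.n_variants, size=cfg.n_causal, replace=False)
            raw = rng.normal(0.0, cfg.causal_effect_sd, size=cfg.n_causal)
            part = dosages[:, idx] @ raw
            sv = part.std()
            scale = np.sqrt(var_causal_target) / sv if sv > 0 else 0.0
            causal = part * scale
            effects = {
                geno.variants[j].snp_id: float(raw[k] * scale)
                for k, j in enumerate(idx)
            }
        poly = chol @ rng.normal(size=n)
        sv = poly.std()
        poly = poly * (np.sqrt(var_poly_target) / sv if sv > 0 else 0.0)
        tbv = causal + poly
        r = cfg.ebv_accuracy
        noise_sd = tbv.std() * np.sqrt(max(1.0 / r**2 - 1.0, 0.0))
        ebv = tbv + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else tbv.copy()
        frame[trait] = ebv + mean_target
        per_trait[trait] = TraitTruth(effects, pd.Series(tbv, index=geno.animal_ids))
    table = EBVTable(pd.DataFrame(frame, index=geno.animal_ids))
    return table, Truth(per_trait)


@dataclass
class StudyBundle:
    pedigree: Pedigree
    genotypes: GenotypeMatrix  # genotyped cohort only
    ebv: EBVTable
    truth: Truth
    paths: dict[str, Path]


def make_study(cfg: SimulationConfig, out_dir: str | Path | None = None) -> StudyBundle:
    """Simulate a full study and (optionally) write it in the pipeline's file
    formats: pedigree TSV, dosage TSV + .map, EBV TSV, truth TSV."""
    ped, genotyped = simulate_pedigree(cfg)
    geno_all = drop_genotypes(ped, cfg)
    geno = geno_all.subset_animals(genotyped)
    ebv, truth = simulate_ebv(geno, ped, cfg)
    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": out / "pedigree.tsv",
            "genotypes": out / "genotypes.tsv",
            "ebv": out / "ebv.tsv",
            "truth": out / "truth.tsv",
        }
        _io.write_pedigree(ped, paths["pedigree"])
        _io.write_genotypes(geno, paths["genotypes"])
        _io.write_ebv(ebv, paths["ebv"])
        with open(paths["truth"], "w") as fh:
            fh.write("snp_id\ttrait\teffect\n")
            for trait, tt in truth.per_trait.items():
                for snp_id, eff in tt.causal_effects.items():
                    fh.write(f"{snp_id}\t{trait}\t{eff:.6g}\n")
    return StudyBundle(ped, geno, ebv, truth, paths)
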