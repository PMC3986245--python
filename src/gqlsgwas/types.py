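"""Domain types shared across the pipeline.

Conventions used throughout:

* Genotype calls are B-allele counts in ``{0, 1, 2}``; missing calls are
  stored as :data:`MISSING` (``-1``) in an ``int8`` matrix.
* Chromosomes are the Bos taurus autosomes, integers 1-29.
* Base-pair positions are 1-based inclusive; BED input is converted at the
  reading boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
UNKNOWN: str = "0"

N_AUTOSOMES: int = 29

FDR_TIER_LABELS = ("1%", "5%", "10%", "NS")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates)."""


@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: str
    sire_id: str = UNKNOWN
    dam_id: str = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.sire_id == UNKNOWN and self.dam_id == UNKNOWN


class Pedigree:
    """Parentage records: (animal, sire, dam), ``"0"`` = unknown parent.

    Parents named but lacking their own record are auto-promoted to founder
    records on construction.  The graph must be acyclic; a cycle (e.g. an
    animal listed as its own ancestor) raises :class:`PedigreeError` naming
    one animal on the cycle.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        records = list(records)
        seen: dict[str, PedigreeRecord] = {}
        for rec in records:
            if rec.animal_id in seen:
                raise PedigreeError(f"duplicate animal id {rec.animal_id!r}")
            if rec.animal_id == UNKNOWN:
                raise PedigreeError("animal id '0' is reserved for unknown parents")
            seen[rec.animal_id] = rec
        # founder promotion: named parents without their own record
        promoted: list[PedigreeRecord] = []
        for rec in records:
            for parent in (rec.sire_id, rec.dam_id):
                if parent != UNKNOWN and parent not in seen:
                    founder = PedigreeRecord(parent)
                    seen[parent] = founder
                    promoted.append(founder)
        self.records: list[PedigreeRecord] = promoted + records
        self._index = {rec.animal_id: i for i, rec in enumerate(self.records)}
        self._topological_order()  # raises on cycle

    @property
    def ids(self) -> list[str]:
        return [rec.animal_id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._index

    def record(self, animal_id: str) -> PedigreeRecord:
        return self.records[self._index[animal_id]]

    def parents(self, animal_id: str) -> tuple[str, str]:
        rec = self.record(animal_id)
        return rec.sire_id, rec.dam_id

    def _topological_order(self) -> list[str]:
        """Kahn's algorithm, parents before offspring; ties broken by input
        order.  Raises :class:`PedigreeError` naming an animal on a cycle."""
        n = len(self.records)
        children: dict[str, list[str]] = {rec.animal_id: [] for rec in self.records}
        indeg = {rec.animal_id: 0 for rec in self.records}
        for rec in self.records:
            for parent in (rec.sire_id, rec.dam_id):
                if parent != UNKNOWN:
                    children[parent].append(rec.animal_id)
                    indeg[rec.animal_id] += 1
        order: list[str] = []
        # queue keeps input order; scan positions once (stable Kahn)
        from collections import deque

        queue = deque(rec.animal_id for rec in self.records if indeg[rec.animal_id] == 0)
        while queue:
            aid = queue.popleft()
            order.append(aid)
            for child in children[aid]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if len(order) != n:
            on_cycle = next(a for a, d in indeg.items() if d > 0)
            raise PedigreeError(
                f"pedigree contains a cycle involving animal {on_cycle!r}"
            )
        return order

    @property
    def topological_order(self) -> list[str]:
        return self._topological_order()


@dataclass(frozen=True, order=True)
class VariantMeta:
    """SNP metadata; chromosome restricted to autosomes 1-29, position 1-based."""

    chromosome: int
    position_bp: int
    snp_id: str = field(compare=False)
    allele_a: str = field(default="A", compare=False)
    allele_b: str = field(default="B", compare=False)

    def __post_init__(self):
        if not 1 <= self.chromosome <= N_AUTOSOMES:
            raise ValueError(
                f"{self.snp_id}: chromosome {self.chromosome} outside autosomes 1-{N_AUTOSOMES}"
            )
        if self.position_bp < 1:
            raise ValueError(f"{self.snp_id}: position {self.position_bp} < 1")


class GenotypeMatrix:
    """Animals x variants matrix of B-allele counts with missing values.

    ``calls`` is ``int8``; entries are 0/1/2 or :data:`MISSING`.  Variants are
    kept sorted by (chromosome, position).
    """

    def __init__(
        self,
        animal_ids: Sequence[str],
        variants: Sequence[VariantMeta],
        calls: np.ndarray,
    ):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(animal_ids), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(animal_ids)}, {len(variants)})"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be 0, 1, 2 or MISSING (-1)")
        order = sorted(
            range(len(variants)),
            key=lambda j: (variants[j].chromosome, variants[j].position_bp),
        )
        self.animal_ids: list[str] = list(animal_ids)
        self.variants: list[VariantMeta] = [variants[j] for j in order]
        self.calls: np.ndarray = np.ascontiguousarray(calls[:, order])
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("duplicate animal ids in genotype matrix")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_animals(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [idx[a] for a in keep]
        return GenotypeMatrix(list(keep), self.variants, self.calls[rows, :])

    def subset_variants(self, keep_mask: np.ndarray) -> "GenotypeMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        variants = [v for v, k in zip(self.variants, keep_mask) if k]
        return GenotypeMatrix(self.animal_ids, variants, self.calls[:, keep_mask])

    def missing_fraction_per_animal(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def call_rate_per_variant(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)


class EBVTable:
    """Per-animal estimated breeding values per trait (kg)."""

    def __init__(self, frame: pd.DataFrame):
        """``frame``: index = animal_id, one column per trait."""
        if frame.index.has_duplicates:
            raise ValueError("duplicate animal ids in EBV table")
        if any(not str(c) for c in frame.columns):
            raise ValueError("empty trait name")
        self.frame = frame.astype(float)

    @property
    def animal_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def traits(self) -> list[str]:
        return list(self.frame.columns)

    def values_for(self, trait: str, animal_ids: Sequence[str]) -> np.ndarray:
        if trait not in self.frame.columns:
            raise KeyError(f"unknown trait {trait!r}; have {self.traits}")
        sub = self.frame.loc[list(animal_ids), trait]
        if sub.isna().any():
            missing = sub.index[sub.isna()].tolist()[:5]
            raise ValueError(f"animals without {trait} EBV: {missing} ...")
        return sub.to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneRecord:
    name: str
    chromosome: int
    start_bp: int  # 1-based inclusive
    end_bp: int  # 1-based inclusive
    strand: str = "+"
    feature_class: str | None = None

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"gene {self.name}: start {self.start_bp} > end {self.end_bp}"
            )


class AnnotationSet:
    """Gene intervals, sorted by (chromosome, start)."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes: list[GeneRecord] = sorted(
            genes, key=lambda g: (g.chromosome, g.start_bp)
        )

    def __len__(self) -> int:
        return len(self.genes)

    def on_chromosome(self, chromosome: int) -> list[GeneRecord]:
        return [g for g in self.genes if g.chromosome == chromosome]


#: Column order of the association result table (mirrors the reported
#: summary-table schema: trait, SNP, chromosome, position, alleles, genes,
#: region, MAF, p-value, FDR tier, allele substitution effect).
ASSOC_COLUMNS = [
    "trait",
    "snp_id",
    "chromosome",
    "position_bp",
    "alleles",
    "genes",
    "region",
    "n_used",
    "maf",
    "p_hat",
    "w_g",
    "p_value",
    "fdr_tier",
    "effect",
]


def empty_assoc_table() -> pd.DataFrame:
    return pd.DataFrame(columns=ASSOC_COLUMNS)
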