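import numpy as np
import pytest

from gqlsgwas import (
    GenotypeMatrix,
    Pedigree,
    PedigreeRecord,
    RelationshipMatrix,
    SimulationConfig,
    VariantMeta,
    build_a_matrix,
    make_study,
)


@pytest.fixture
def trio_pedigree():
    return Pedigree(
        [PedigreeRecord("A"), PedigreeRecord("B"), PedigreeRecord("C", "A", "B")]
    )


@pytest.fixture
def half_sib_pedigree():
    """Sire S with two dams -> half-sibs H1, H2; their offspring X has F = 1/8."""
    return Pedigree(
        [
            PedigreeRecord("S"),
            PedigreeRecord("D1"),
            PedigreeRecord("D2"),
            PedigreeRecord("H1", "S", "D1"),
            PedigreeRecord("H2", "S", "D2"),
            PedigreeRecord("X", "H1", "H2"),
        ]
    )


@pytest.fixture
def full_sib_mating_pedigree():
    """Full sibs B1 x B2 -> offspring X with F = 1/4."""
    return Pedigree(
        [
            PedigreeRecord("S"),
            PedigreeRecord("D"),
            PedigreeRecord("B1", "S", "D"),
            PedigreeRecord("B2", "S", "D"),
            PedigreeRecord("X", "B1", "B2"),
        ]
    )


@pytest.fixture
def six_animal_rel(half_sib_pedigree):
    return build_a_matrix(half_sib_pedigree)


@pytest.fixture
def identity_rel():
    def make(n):
        return RelationshipMatrix([f"a{i}" for i in range(n)], np.eye(n))

    return make


@pytest.fixture(scope="session")
def small_study():
    """One shared synthetic study: 200 genotyped animals, 300 SNPs, 2 causal."""
    cfg = SimulationConfig(
        seed=42, n_founders=80, n_per_generation=200, n_generations=3,
        n_snps=300, n_chromosomes=10, n_causal=2,
    )
    return make_study(cfg)


def random_pedigree(rng: np.random.Generator, n_founders=4, n_extra=8) -> Pedigree:
    """Random acyclic pedigree: each non-founder picks parents among earlier
    animals (or unknown)."""
    records = [PedigreeRecord(f"f{i}") for i in range(n_founders)]
    ids = [r.animal_id for r in records]
    for k in range(n_extra):
        sire = ids[rng.integers(0, len(ids))] if rng.random() < 0.9 else "0"
        dam = ids[rng.integers(0, len(ids))] if rng.random() < 0.9 else "0"
        if sire == dam:
            dam = "0"
        aid = f"x{k}"
        records.append(PedigreeRecord(aid, sire, dam))
        ids.append(aid)
    return Pedigree(records)


def toy_genotypes(rng: np.random.Generator, n_animals=6, n_snps=4) -> GenotypeMatrix:
    variants = [
        VariantMeta(1 + j % 2, 1000 * (j + 1), f"s{j}", "A", "C") for j in range(n_snps)
    ]
    calls = rng.integers(0, 3, size=(n_animals, n_snps)).astype(np.int8)
    return GenotypeMatrix([f"a{i}" for i in range(n_animals)], variants, calls)
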