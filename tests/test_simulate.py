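import numpy as np
import pytest

from gqlsgwas import (
    MISSING,
    SimulationConfig,
    build_a_matrix,
    drop_genotypes,
    make_study,
    simulate_ebv,
    simulate_pedigree,
)


def small_cfg(**kw):
    base = dict(
        seed=0, n_founders=40, n_per_generation=60, n_generations=3,
        n_snps=50, n_chromosomes=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulatePedigree:
    def test_deterministic_per_seed(self):
        p1, g1 = simulate_pedigree(small_cfg())
        p2, g2 = simulate_pedigree(small_cfg())
        assert [r for r in p1.records] == [r for r in p2.records]
        assert g1 == g2

    def test_single_generation_all_founders(self):
        ped, latest = simulate_pedigree(small_cfg(n_generations=1))
        assert all(r.is_founder for r in ped.records)
        assert latest == ped.ids

    def test_sire_skew(self):
        ped, latest = simulate_pedigree(small_cfg(n_per_generation=200, sire_fraction=0.1))
        sires = {ped.record(a).sire_id for a in latest}
        dams = {ped.record(a).dam_id for a in latest}
        assert len(sires) <= 20
        assert len(dams) > len(sires)

    def test_inbreeding_rises_with_generations(self):
        """With few sires, mean pedigree inbreeding of the youngest cohort
        grows with depth (checked in expectation over seeds)."""
        def mean_f(n_generations, seed):
            cfg = small_cfg(seed=seed, n_generations=n_generations, sire_fraction=0.08)
            ped, latest = simulate_pedigree(cfg)
            return build_a_matrix(ped, latest).f.mean()

        shallow = np.mean([mean_f(2, s) for s in range(10)])
        deep = np.mean([mean_f(5, s) for s in range(10)])
        assert deep > shallow


class TestDropGenotypes:
    def test_mendelian_consistency_for_all_trios(self):
        cfg = small_cfg(seed=1)
        ped, _ = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        idx = {a: i for i, a in enumerate(geno.animal_ids)}
        for rec in ped.records:
            if rec.is_founder:
                continue
            child = geno.calls[idx[rec.animal_id]]
            sire = geno.calls[idx[rec.sire_id]]
            dam = geno.calls[idx[rec.dam_id]]
            # child B-count must be attainable from one allele per parent:
            # floor contributions: parent call 0 -> contributes 0, 2 -> 1,
            # 1 -> either
            lo = (sire == 2).astype(int) + (dam == 2).astype(int)
            hi = (sire >= 1).astype(int) + (dam >= 1).astype(int)
            assert np.all(child >= lo) and np.all(child <= hi)

    def test_founder_frequency_within_binomial_ci(self):
        cfg = small_cfg(seed=2, n_founders=200, n_generations=1, n_snps=30)
        ped, _ = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        rng = np.random.default_rng(cfg.seed + 1)  # same stream as generator
        freqs = rng.uniform(cfg.founder_maf_low, cfg.founder_maf_high, size=30)
        observed = geno.calls.mean(axis=0) / 2.0
        # 4-sigma band per SNP at 2N = 400 draws
        se = np.sqrt(freqs * (1 - freqs) / (2 * 200))
        assert np.all(np.abs(observed - freqs) < 4 * se + 1e-9)

    def test_same_seed_identical_matrix(self):
        cfg = small_cfg(seed=3)
        ped, _ = simulate_pedigree(cfg)
        g1 = drop_genotypes(ped, cfg)
        g2 = drop_genotypes(ped, cfg)
        np.testing.assert_array_equal(g1.calls, g2.calls)

    def test_ld_mode_produces_adjacent_correlation(self):
        cfg_no = small_cfg(seed=4, n_snps=40, n_chromosomes=1, n_founders=150,
                           n_generations=1)
        cfg_ld = small_cfg(seed=4, n_snps=40, n_chromosomes=1, n_founders=150,
                           n_generations=1, ld_rho=0.9)
        from gqlsgwas.posthoc import ld_r2

        def mean_adjacent_r2(cfg):
            ped, _ = simulate_pedigree(cfg)
            geno = drop_genotypes(ped, cfg)
            vals = [
                ld_r2(geno.calls[:, j], geno.calls[:, j + 1])
                for j in range(geno.n_variants - 1)
            ]
            return np.nanmean(vals)

        assert mean_adjacent_r2(cfg_ld) > mean_adjacent_r2(cfg_no) + 0.2


class TestSimulateEbv:
    def test_perfect_accuracy_gives_tbv_plus_mean(self):
        cfg = small_cfg(seed=5, ebv_accuracy=1.0, traits=("BW",))
        ped, latest = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg).subset_animals(latest)
        ebv, truth = simulate_ebv(geno, ped, cfg)
        np.testing.assert_allclose(
            ebv.values_for("BW", latest) - cfg.trait_means["BW"],
            truth.per_trait["BW"].tbv.loc[latest].to_numpy(),
            atol=1e-10,
        )

    def test_empirical_accuracy_near_configured(self):
        cfg = SimulationConfig(
            seed=6, n_founders=150, n_per_generation=400, n_generations=3,
            n_snps=60, n_chromosomes=3, ebv_accuracy=0.7, traits=("WW",),
        )
        ped, latest = simulate_pedigree(cfg)
        geno = drop_genotypes(ped, cfg).subset_animals(latest)
        ebv, truth = simulate_ebv(geno, ped, cfg)
        r = np.corrcoef(
            ebv.values_for("WW", latest), truth.per_trait["WW"].tbv.loc[latest]
        )[0, 1]
        assert abs(r - 0.7) < 0.05

    def test_too_many_causal_snps(self):
        with pytest.raises(ValueError, match="n_causal"):
            small_cfg(n_causal=51)


class TestMakeStudy:
    def test_default_config_echo(self):
        cfg = SimulationConfig(seed=0, n_snps=30)
        bundle = make_study(cfg)
        assert bundle.genotypes.n_animals == 400
        assert list(bundle.ebv.traits) == ["BW", "WW", "LYW"]

    def test_same_seed_identical_files(self, tmp_path):
        cfg = small_cfg(seed=7, n_causal=2)
        b1 = make_study(cfg, tmp_path / "one")
        b2 = make_study(cfg, tmp_path / "two")
        for key in b1.paths:
            assert b1.paths[key].read_bytes() == b2.paths[key].read_bytes()

    def test_pedigree_a_tracks_genotypic_relatedness(self, small_study):
        """Tabular A entries correlate positively with realized allele
        sharing (centred dosage correlation) among genotyped animals."""
        geno = small_study.genotypes
        rel = build_a_matrix(small_study.pedigree, geno.animal_ids)
        d = geno.calls.astype(float)
        d -= d.mean(axis=0)
        denom = d.std(axis=0)
        d = d[:, denom > 0] / denom[denom > 0]
        grm = d @ d.T / d.shape[1]
        iu = np.triu_indices(geno.n_animals, k=1)
        corr = np.corrcoef(rel.a[iu], grm[iu])[0, 1]
        assert corr > 0.3
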