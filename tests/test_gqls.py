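import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gqlsgwas import (
    MISSING,
    GenotypeMatrix,
    VariantMeta,
    build_a_matrix,
    gqls_statistic,
    null_allele_freq,
    run_gwas,
)
from gqlsgwas.types import EBVTable

from conftest import random_pedigree
from oracles import classical_score_stat, gls_null_freq_dense, score_stat_whitened


def random_instance(rng, rel):
    n = len(rel.ids)
    y = rng.integers(0, 3, size=n) / 2.0
    x = rng.normal(size=n)
    return y, x


class TestNullAlleleFreq:
    def test_identity_reduces_to_mean(self, identity_rel):
        rel = identity_rel(4)
        assert null_allele_freq(np.array([0, 0.5, 0.5, 1.0]), rel) == pytest.approx(0.5)

    def test_degenerate_all_ones(self, identity_rel):
        rel = identity_rel(4)
        assert null_allele_freq(np.ones(4), rel) == pytest.approx(1.0)
        out = gqls_statistic(np.ones(4), np.arange(4.0), rel)
        assert np.isnan(out.p_value) and out.p_hat == pytest.approx(1.0)

    def test_matches_dense_inverse_on_pedigree(self, six_animal_rel):
        rng = np.random.default_rng(2)
        y, _ = random_instance(rng, six_animal_rel)
        expected = gls_null_freq_dense(y, six_animal_rel.a)
        assert null_allele_freq(y, six_animal_rel) == pytest.approx(expected, abs=1e-12)


class TestStatistic:
    def test_constant_y_gives_zero_statistic(self, six_animal_rel):
        out = gqls_statistic(np.full(6, 0.5), np.arange(6.0), six_animal_rel)
        assert out.score == pytest.approx(0.0, abs=1e-12)
        assert out.w_g == pytest.approx(0.0, abs=1e-12)
        assert out.p_value == pytest.approx(1.0)

    def test_frozen_hand_computed_example(self, identity_rel):
        # GLS score test by hand: p = 0.5, U = 2, Var = 0.125 * 4 = 0.5,
        # W = 8, p = P(chi2_1 > 8) = 4.6777e-3
        out = gqls_statistic(
            np.array([0.0, 0, 1, 1]), np.array([-1.0, -1, 1, 1]), identity_rel(4)
        )
        assert out.w_g == pytest.approx(8.0)
        assert out.p_value == pytest.approx(4.6777e-3, rel=1e-4)

    def test_constant_covariate_errors(self, identity_rel):
        with pytest.raises(ValueError, match="constant"):
            gqls_statistic(np.array([0, 0.5, 1.0]), np.ones(3), identity_rel(3))

    def test_whitening_oracle_on_pedigree(self, six_animal_rel):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y, x = random_instance(rng, six_animal_rel)
            if len(set(y)) == 1:
                continue
            out = gqls_statistic(y, x, six_animal_rel)
            if np.isnan(out.w_g):
                continue
            w_oracle, p_oracle = score_stat_whitened(y, x, six_animal_rel.a)
            assert out.w_g == pytest.approx(w_oracle, abs=1e-10)
            assert out.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_identity_matches_classical_score_test(self, identity_rel):
        rng = np.random.default_rng(4)
        hits = 0
        while hits < 50:
            n = int(rng.integers(4, 13))
            rel = identity_rel(n)
            y, x = random_instance(rng, rel)
            if not 0 < y.mean() < 1:
                continue
            out = gqls_statistic(y, x, rel)
            assert out.w_g == pytest.approx(classical_score_stat(y, x), abs=1e-10)
            hits += 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-10, 10),
    )
    def test_affine_and_flip_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng, n_founders=4, n_extra=6)
        rel = build_a_matrix(ped)
        y, x = random_instance(rng, rel)
        out = gqls_statistic(y, x, rel)
        if np.isnan(out.w_g):
            return
        affine = gqls_statistic(y, a * x + b, rel)
        flipped = gqls_statistic(1.0 - y, x, rel)
        assert affine.w_g == pytest.approx(out.w_g, rel=1e-9)
        assert flipped.w_g == pytest.approx(out.w_g, rel=1e-9)
        assert flipped.p_hat == pytest.approx(1.0 - out.p_hat, abs=1e-12)


class TestRunGwas:
    @pytest.fixture
    def small_inputs(self, half_sib_pedigree):
        ids = half_sib_pedigree.topological_order
        rel = build_a_matrix(half_sib_pedigree)
        rng = np.random.default_rng(7)
        variants = [VariantMeta(1, 1000 * (j + 1), f"s{j}") for j in range(4)]
        calls = rng.integers(0, 3, size=(len(ids), 4)).astype(np.int8)
        geno = GenotypeMatrix(ids, variants, calls)
        ebv = EBVTable(pd.DataFrame({"BW": rng.normal(size=len(ids))}, index=ids))
        return geno, ebv, rel

    def test_all_missing_snp_gets_na_row(self, small_inputs):
        geno, ebv, rel = small_inputs
        geno.calls[:, 2] = MISSING
        table = run_gwas(geno, ebv, "BW", rel)
        row = table[table.snp_id == "s2"].iloc[0]
        assert row.n_used == 0 and np.isnan(row.p_value)
        assert len(table) == geno.n_variants  # skipped SNP still reported

    def test_duplicated_snp_identical_statistics(self, small_inputs):
        geno, ebv, rel = small_inputs
        variants = geno.variants + [VariantMeta(1, 99_000, "dup_of_s0")]
        calls = np.column_stack([geno.calls, geno.calls[:, 0]])
        geno2 = GenotypeMatrix(geno.animal_ids, variants, calls)
        table = run_gwas(geno2, ebv, "BW", rel)
        a = table[table.snp_id == "s0"].iloc[0]
        b = table[table.snp_id == "dup_of_s0"].iloc[0]
        assert a.w_g == b.w_g and a.p_value == b.p_value and a.p_hat == b.p_hat

    def test_missing_trait_errors(self, small_inputs):
        geno, ebv, rel = small_inputs
        with pytest.raises(KeyError, match="unknown trait"):
            run_gwas(geno, ebv, "LYW", rel)

    def test_complete_case_matches_manual_restriction(self, small_inputs):
        geno, ebv, rel = small_inputs
        geno.calls[0, 1] = MISSING
        table = run_gwas(geno, ebv, "BW", rel)
        row = table[table.snp_id == "s1"].iloc[0]
        called = geno.calls[:, 1] != MISSING
        sub_ids = [a for a, c in zip(geno.animal_ids, called) if c]
        sub_rel = rel.restrict(sub_ids)
        y = geno.calls[called, 1] / 2.0
        x = ebv.values_for("BW", sub_ids)
        expected = gqls_statistic(y, x, sub_rel)
        assert row.w_g == pytest.approx(expected.w_g, abs=1e-12)
        assert row.n_used == called.sum()
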