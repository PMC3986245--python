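"""Generalized quasi-likelihood score (GQLS) association test.

Model
-----
For a single SNP, each animal's genotype is summarised as an allele
proportion ``y_i`` in {0, 1/2, 1} (half the B-allele count).  The EBV ``x_i``
enters a logistic quasi-model

    logit E[y_i] = beta0 + beta1 * x_i,      Cov(y) = phi * A,

where ``A`` is the pedigree numerator relationship matrix, which both
corrects for family structure and supplies the quasi-likelihood weights.
Under the null hypothesis beta1 = 0 the mean is a constant allele frequency
``p`` and the quasi-score equation yields the GLS estimate

    p_hat = (1' A^-1 y) / (1' A^-1 1).

The score for beta1 evaluated at the null is

    U      = x' A^-1 (y - p_hat 1)
    Var(U) = phi_hat * [ x' A^-1 x - (x' A^-1 1)^2 / (1' A^-1 1) ]
    W_G    = U^2 / Var(U),        phi_hat = p_hat (1 - p_hat) / 2,

and W_G is referred to a chi-square distribution with one degree of freedom.
``phi_hat`` is the binomial(2) variance of an allele proportion at the null
frequency.  W_G is exactly invariant to affine maps of x (the centring term
makes 1' A^-1 (y - p_hat 1) = 0) and to allele relabelling y -> 1 - y.

The test provides no estimate of the SNP effect; allele-substitution effects
come from the separate single-locus regression in :mod:`gqlsgwas.posthoc`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import RelationshipMatrix
from .types import ASSOC_COLUMNS, MISSING, EBVTable, GenotypeMatrix

#: Var(U) below this is treated as degenerate (NA result, never an inflated W).
VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class GqlsOutput:
    p_hat: float
    score: float
    variance: float
    w_g: float
    p_value: float

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.w_g)


_NA_OUTPUT = GqlsOutput(np.nan, np.nan, np.nan, np.nan, np.nan)


def null_allele_freq(
    y: np.ndarray, rel: RelationshipMatrix, subset: np.ndarray | None = None
) -> float:
    """GLS-weighted mean allele frequency p_hat = (1'A^-1 y)/(1'A^-1 1).

    With A = I this is the arithmetic mean of y.  Returns the estimate even
    when it is degenerate (0 or 1); callers decide how to flag it.
    """
    y = np.asarray(y, dtype=float)
    ones = np.ones(len(y))
    ainv_y = rel.solve(y, subset)
    ainv_1 = rel.solve(ones, subset)
    return float(ones @ ainv_y) / float(ones @ ainv_1)


def gqls_statistic(
    y: np.ndarray,
    x: np.ndarray,
    rel: RelationshipMatrix,
    subset: np.ndarray | None = None,
) -> GqlsOutput:
    """Score test of one SNP; returns an NA output for degenerate inputs.

    ``y``: allele proportions in {0, 1/2, 1}; ``x``: EBVs; ``rel``: A over
    the same animals (or a superset, with ``subset`` giving row indices).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have the same length")
    if len(y) < 3:
        return _NA_OUTPUT
    if np.ptp(x) == 0:
        raise ValueError("covariate x is constant; the score test is undefined")
    ones = np.ones(len(y))
    ainv_y = rel.solve(y, subset)
    ainv_1 = rel.solve(ones, subset)
    ainv_x = rel.solve(x, subset)
    s11 = float(ones @ ainv_1)
    p_hat = float(ones @ ainv_y) / s11
    if not 0.0 < p_hat < 1.0:
        return GqlsOutput(p_hat, np.nan, np.nan, np.nan, np.nan)
    phi = p_hat * (1.0 - p_hat) / 2.0
    u = float(x @ ainv_y) - p_hat * float(x @ ainv_1)
    var_u = phi * (float(x @ ainv_x) - float(x @ ainv_1) ** 2 / s11)
    if var_u <= VAR_FLOOR:
        return GqlsOutput(p_hat, u, var_u, np.nan, np.nan)
    w_g = u * u / var_u
    p_value = float(stats.chi2.sf(w_g, df=1))
    return GqlsOutput(p_hat, u, var_u, w_g, p_value)


def run_gwas(
    geno: GenotypeMatrix,
    ebv: EBVTable,
    trait: str,
    rel: RelationshipMatrix,
) -> pd.DataFrame:
    """Single-SNP GQLS scan of every variant against one trait's EBVs.

    Missing genotypes are handled per SNP by complete-case restriction; the
    A-submatrix factorization is cached per distinct missingness pattern
    (``rel.solve`` keys its Cholesky cache on the row subset).  Returns a
    data frame in the association-table schema; SNPs with a degenerate null
    frequency or fewer than 3 called animals get NA statistics.
    """
    x_full = ebv.values_for(trait, geno.animal_ids)
    rel_idx = rel.index_of(geno.animal_ids)
    rows = []
    calls = geno.calls
    for j, variant in enumerate(geno.variants):
        col = calls[:, j]
        called = col != MISSING
        n_used = int(called.sum())
        y = col[called] / 2.0
        x = x_full[called]
        subset = rel_idx[called]
        p_b = float(y.mean()) if n_used else np.nan
        maf = min(p_b, 1 - p_b) if n_used else np.nan
        out = _NA_OUTPUT if n_used < 3 else gqls_statistic(y, x, rel, subset)
        rows.append(
            {
                "trait": trait,
                "snp_id": variant.snp_id,
                "chromosome": variant.chromosome,
                "position_bp": variant.position_bp,
                "alleles": f"{variant.allele_a},{variant.allele_b}",
                "genes": "",
                "region": "",
                "n_used": n_used,
                "maf": maf,
                "p_hat": out.p_hat,
                "w_g": out.w_g,
                "p_value": out.p_value,
                "fdr_tier": "NS",
                "effect": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)
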