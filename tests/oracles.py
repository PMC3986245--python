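"""Independent oracles used by the tests.

These deliberately take different computational routes from the package:
explicit matrix inverses, Cholesky whitening, brute-force enumeration and
Monte-Carlo gene dropping, so that agreement is informative.
"""

import numpy as np
from scipy import stats


def gls_null_freq_dense(y, a):
    """p_hat via an explicit dense inverse (the package never forms one)."""
    ainv = np.linalg.inv(a)
    ones = np.ones(len(y))
    return float(ones @ ainv @ y) / float(ones @ ainv @ ones)


def score_stat_whitened(y, x, a):
    """GQLS statistic computed on Cholesky-whitened data.

    With A = L L', z = L^-1 y, w = L^-1 x and u = L^-1 1, the correlated
    problem becomes an ordinary (identity-covariance) weighted score test.
    """
    l = np.linalg.cholesky(a)
    z = np.linalg.solve(l, y)
    w = np.linalg.solve(l, x)
    u = np.linalg.solve(l, np.ones(len(y)))
    p_hat = float(u @ z) / float(u @ u)
    phi = p_hat * (1 - p_hat) / 2
    score = float(w @ (z - p_hat * u))
    var = phi * (float(w @ w) - float(w @ u) ** 2 / float(u @ u))
    w_g = score**2 / var
    return w_g, float(stats.chi2.sf(w_g, df=1))


def classical_score_stat(y, x):
    """Textbook score test of beta1 = 0 in the quasi-binomial logistic model
    with independent observations (A = I): U = sum x (y - ybar),
    Var = phi * sum (x - xbar)^2."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    p = y.mean()
    phi = p * (1 - p) / 2
    u = float(x @ (y - p))
    var = phi * float(((x - x.mean()) ** 2).sum())
    return u * u / var


def bh_brute_force(p_values, m, q):
    """Check every rank explicitly: significant iff p <= max over i of
    {p(i) : p(i) <= q i / m}."""
    p = np.asarray(p_values, float)
    order = np.argsort(p, kind="stable")
    best = None
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            best = p[idx]
    if best is None:
        return np.zeros(len(p), dtype=bool)
    return p <= best


def gene_drop_kinship(ped, id_a, id_b, n_drops, rng):
    """Monte-Carlo 2x-kinship between two animals at a single neutral locus:
    drop unique founder alleles, estimate the probability that a random
    allele from each is identical by descent; additive relationship = 2 phi.
    """
    order = ped.topological_order
    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    h1 = np.zeros((n_drops, n), dtype=np.int32)
    h2 = np.zeros((n_drops, n), dtype=np.int32)
    label = 0
    for aid in order:
        i = pos[aid]
        rec = ped.record(aid)
        if rec.is_founder:
            h1[:, i] = label
            h2[:, i] = label + 1
            label += 2
        else:
            si, di = pos[rec.sire_id], pos[rec.dam_id]
            pick = rng.integers(0, 2, size=n_drops)
            h1[:, i] = np.where(pick == 0, h1[:, si], h2[:, si])
            pick = rng.integers(0, 2, size=n_drops)
            h2[:, i] = np.where(pick == 0, h1[:, di], h2[:, di])
    ia, ib = pos[id_a], pos[id_b]
    ibd = (
        (h1[:, ia] == h1[:, ib]).astype(float)
        + (h1[:, ia] == h2[:, ib])
        + (h2[:, ia] == h1[:, ib])
        + (h2[:, ia] == h2[:, ib])
    ) / 4.0
    return 2.0 * ibd.mean()


def wright_path_inbreeding_half_sib():
    """Wright's path-counting F for the offspring of two half sibs sharing
    one non-inbred common ancestor: one path of length n_s + n_d + 1 = 3
    segments -> F = (1/2)^3 = 0.125."""
    return 0.5**3


def wright_path_inbreeding_full_sib():
    """Two common ancestors, each path (1/2)^3 -> F = 0.25."""
    return 2 * 0.5**3
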