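"""Additive numerator relationship matrix (A) and inbreeding from a pedigree.

The tabular method processes animals in a topological order (parents first):

    a(i, j) = 0.5 * (a(sire_i, j) + a(dam_i, j))      for j before i
    a(i, i) = 1 + 0.5 * a(sire_i, dam_i)

with unknown parents contributing 0.  The inbreeding coefficient is
F_i = a(i, i) - 1 = 0.5 * a(sire_i, dam_i).

A is always computed over the full ancestor closure and only then restricted
to the animals of interest, so relationships transmitted through ungenotyped
ancestors are preserved.  No explicit inverse is ever formed; the
:class:`RelationshipMatrix` exposes factorize-and-solve instead, caching the
Cholesky factor per row subset (the association scan re-solves against the
same complete-case subsets many times).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .types import Pedigree, UNKNOWN


class RelationshipMatrix:
    """Symmetric additive relationship matrix over an ordered id list."""

    def __init__(self, ids: Sequence[str], a: np.ndarray):
        a = np.asarray(a, dtype=float)
        if a.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match id list")
        self.ids: list[str] = list(ids)
        self.a: np.ndarray = a
        self._index = {aid: i for i, aid in enumerate(self.ids)}
        self._factor_cache: dict[bytes, tuple] = {}

    @property
    def f(self) -> np.ndarray:
        """Per-animal inbreeding coefficients, diag(A) - 1."""
        return np.diag(self.a) - 1.0

    def index_of(self, animal_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._index[a] for a in animal_ids], dtype=int)

    def restrict(self, animal_ids: Sequence[str]) -> "RelationshipMatrix":
        idx = self.index_of(animal_ids)
        return RelationshipMatrix(list(animal_ids), self.a[np.ix_(idx, idx)])

    def solve(self, rhs: np.ndarray, subset: np.ndarray | None = None) -> np.ndarray:
        """Solve A[subset, subset] @ x = rhs via cached Cholesky.

        ``subset`` is an integer or boolean index over rows; ``None`` means
        the full matrix.  Raises a ``ValueError`` with a pedigree-oriented
        hint if the principal submatrix is not positive definite.
        """
        if subset is None:
            subset = np.arange(len(self.ids))
        subset = np.asarray(subset)
        if subset.dtype == bool:
            subset = np.flatnonzero(subset)
        key = subset.astype(np.int64).tobytes()
        factor = self._factor_cache.get(key)
        if factor is None:
            sub = self.a[np.ix_(subset, subset)]
            try:
                factor = cho_factor(sub, lower=True)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    "relationship submatrix is not positive definite; check the "
                    "pedigree for duplicate or contradictory parentage entries"
                ) from exc
            self._factor_cache[key] = factor
        return cho_solve(factor, np.asarray(rhs, dtype=float))


def _closure_order(ped: Pedigree, keep_ids: Sequence[str]) -> list[str]:
    """Topological order of keep_ids plus all their ancestors."""
    needed: set[str] = set()
    stack = list(keep_ids)
    while stack:
        aid = stack.pop()
        if aid in needed or aid == UNKNOWN:
            continue
        needed.add(aid)
        sire, dam = ped.parents(aid)
        stack.extend(p for p in (sire, dam) if p != UNKNOWN)
    return [aid for aid in ped.topological_order if aid in needed]


def build_a_matrix(ped: Pedigree, keep_ids: Sequence[str] | None = None) -> RelationshipMatrix:
    """Tabular A over the ancestor closure, restricted to ``keep_ids``.

    ``keep_ids=None`` returns A over the whole pedigree in topological order.
    """
    if keep_ids is None:
        keep_ids = ped.topological_order
    keep_ids = list(keep_ids)
    if not keep_ids:
        raise ValueError("keep_ids is empty")
    missing = [a for a in keep_ids if a not in ped]
    if missing:
        raise KeyError(f"ids not in pedigree: {missing[:5]}")
    order = _closure_order(ped, keep_ids)
    pos = {aid: i for i, aid in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for i, aid in enumerate(order):
        sire, dam = ped.parents(aid)
        si = pos.get(sire, -1)
        di = pos.get(dam, -1)
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * a[si, :i]
        if di >= 0:
            row += 0.5 * a[di, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[si, di] if (si >= 0 and di >= 0) else 0.0)
    keep_idx = np.array([pos[aid] for aid in keep_ids])
    return RelationshipMatrix(keep_ids, a[np.ix_(keep_idx, keep_idx)])


def inbreeding(ped: Pedigree) -> dict[str, float]:
    """Wright's inbreeding coefficient per animal: F_i = 0.5 * a(sire, dam)."""
    rel = build_a_matrix(ped)
    return dict(zip(rel.ids, rel.f))


def solve_a(
    rel: RelationshipMatrix, rhs: np.ndarray, subset: np.ndarray | None = None
) -> np.ndarray:
    """Module-level alias for :meth:`RelationshipMatrix.solve`."""
    return rel.solve(rhs, subset)


def write_a_matrix(rel: RelationshipMatrix, path) -> None:
    """Dense TSV dump of A with ids as header, for debugging."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(rel.ids) + "\n")
        for aid, row in zip(rel.ids, rel.a):
            fh.write(aid + "\t" + "\t".join(f"{v:.8g}" for v in row) + "\n")
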