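"""Pedigrees and the additive (numerator) relationship matrix.

A pedigree is the list of (animal, sire, dam) triples that defines how
additive genetic covariance is shared among relatives.  This module builds
the numerator relationship matrix ``A`` by the tabular method, its sparse
inverse by Henderson's rules with inbreeding, and supports pruning a
pedigree to the ancestor closure of the phenotyped animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: Sentinel for an unknown parent in pedigree files and arrays.
UNKNOWN = 0


class PedigreeError(ValueError):
    """Raised when a pedigree violates ordering or referential integrity."""


@dataclass
class Pedigree:
    """Ordered pedigree: parents precede offspring; ``0`` marks unknown parents.

    Parameters
    ----------
    animal, sire, dam
        Integer arrays of equal length.  Animal ids are positive and unique;
        sire/dam are either :data:`UNKNOWN` or an id appearing *earlier* in
        ``animal``.
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (len(self.animal) == len(self.sire) == len(self.dam)):
            raise PedigreeError("animal, sire and dam columns differ in length")
        if np.any(self.animal <= 0):
            raise PedigreeError("animal ids must be positive integers")
        self._index = {int(a): i for i, a in enumerate(self.animal)}
        if len(self._index) != len(self.animal):
            raise PedigreeError("duplicate animal ids in pedigree")
        for name, parents in (("sire", self.sire), ("dam", self.dam)):
            for i, p in enumerate(parents):
                if p == UNKNOWN:
                    continue
                j = self._index.get(int(p))
                if j is None:
                    raise PedigreeError(
                        f"{name} {int(p)} of animal {int(self.animal[i])} "
                        "is not listed as an animal"
                    )
                if j >= i:
                    raise PedigreeError(
                        f"{name} {int(p)} does not precede its offspring "
                        f"{int(self.animal[i])}: pedigree must be in "
                        "generation order"
                    )
                if p == self.animal[i]:
                    raise PedigreeError(f"animal {int(p)} is its own {name}")

    def __len__(self) -> int:
        return len(self.animal)

    def index_of(self, animal_id: int) -> int:
        """Positional index of ``animal_id`` in the pedigree ordering."""
        try:
            return self._index[int(animal_id)]
        except KeyError:
            raise PedigreeError(f"animal {animal_id} not in pedigree") from None

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Positional sire/dam indices, ``-1`` for unknown."""
        sire_ix = np.array(
            [self._index[int(p)] if p != UNKNOWN else -1 for p in self.sire],
            dtype=np.int64,
        )
        dam_ix = np.array(
            [self._index[int(p)] if p != UNKNOWN else -1 for p in self.dam],
            dtype=np.int64,
        )
        return sire_ix, dam_ix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal, "sire": self.sire, "dam": self.dam}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        return cls(
            frame["animal"].to_numpy(),
            frame["sire"].to_numpy(),
            frame["dam"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix with its animal ordering.

    Attributes
    ----------
    animal : array of animal ids defining row/column order.
    A : dense symmetric matrix of additive relationships, diagonal
        ``1 + F_i`` with ``F_i`` the inbreeding coefficient.
    inbreeding : per-animal inbreeding coefficients ``F_i``.
    """

    animal: np.ndarray
    A: np.ndarray
    inbreeding: np.ndarray

    def to_coordinate_frame(self, tol: float = 0.0) -> pd.DataFrame:
        """Lower-triangle (row, col, value) dump in coordinate text format."""
        rows, cols = np.tril_indices(len(self.animal))
        vals = self.A[rows, cols]
        keep = np.abs(vals) > tol
        return pd.DataFrame(
            {
                "row": self.animal[rows[keep]],
                "col": self.animal[cols[keep]],
                "value": vals[keep],
            }
        )


def prune(pedigree: Pedigree, keep_ids) -> Pedigree:
    """Restrict a pedigree to ``keep_ids`` and all of their ancestors.

    The result keeps the original (valid) ordering.  Unknown ids raise
    :class:`PedigreeError`.
    """
    keep_ids = [int(k) for k in keep_ids]
    sire_ix, dam_ix = pedigree.parent_indices()
    keep = np.zeros(len(pedigree), dtype=bool)
    stack = [pedigree.index_of(k) for k in keep_ids]
    while stack:
        i = stack.pop()
        if keep[i]:
            continue
        keep[i] = True
        if sire_ix[i] >= 0:
            stack.append(int(sire_ix[i]))
        if dam_ix[i] >= 0:
            stack.append(int(dam_ix[i]))
    kept = np.flatnonzero(keep)
    kept_ids = set(pedigree.animal[kept].tolist())
    sire = np.where(np.isin(pedigree.sire[kept], list(kept_ids)), pedigree.sire[kept], UNKNOWN)
    dam = np.where(np.isin(pedigree.dam[kept], list(kept_ids)), pedigree.dam[kept], UNKNOWN)
    # ancestors of a kept animal are kept, so parents are never dropped;
    # the np.where is belt-and-braces for founders with UNKNOWN already
    return Pedigree(pedigree.animal[kept], sire, dam)


def relationship_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method.

    Recursion over animals in pedigree order: for animal ``i`` with parents
    ``s, d`` (unknown parents contribute zero),

    * ``a_ij = 0.5 (a_js + a_jd)`` for every earlier ``j``;
    * ``a_ii = 1 + 0.5 a_sd``.
    """
    n = len(pedigree)
    sire_ix, dam_ix = pedigree.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_ix[i], dam_ix[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(
        animal=pedigree.animal.copy(), A=A, inbreeding=np.diag(A) - 1.0
    )


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients ``F_i`` (diagonal of A minus one)."""
    return relationship_matrix(pedigree).inbreeding


def mendelian_sampling_variances(
    pedigree: Pedigree, inbreeding: np.ndarray | None = None
) -> np.ndarray:
    """Within-family (Mendelian sampling) variance ``d_i`` for each animal.

    ``d_i = 0.5 - 0.25 (F_s + F_d)`` with both parents known,
    ``0.75 - 0.25 F_p`` with one parent known, and ``1`` for founders.
    These are the diagonal of ``D`` in the decomposition ``A = T D T'``,
    so ``log|A| = sum(log d_i)``.
    """
    if inbreeding is None:
        inbreeding = inbreeding_coefficients(pedigree)
    sire_ix, dam_ix = pedigree.parent_indices()
    d = np.ones(len(pedigree))
    for i in range(len(pedigree)):
        s, dm = sire_ix[i], dam_ix[i]
        if s >= 0 and dm >= 0:
            d[i] = 0.5 - 0.25 * (inbreeding[s] + inbreeding[dm])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * inbreeding[s]
        elif dm >= 0:
            d[i] = 0.75 - 0.25 * inbreeding[dm]
    return d


def a_inverse(pedigree: Pedigree) -> tuple[sparse.csr_matrix, float]:
    """Sparse inverse of the relationship matrix by Henderson's rules.

    Accounts for inbreeding through the Mendelian sampling variances.
    Returns the CSR inverse and ``log|A|``.
    """
    n = len(pedigree)
    sire_ix, dam_ix = pedigree.parent_indices()
    d = mendelian_sampling_variances(pedigree)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (sire_ix[i], dam_ix[i]) if p >= 0]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * alpha)
    Ainv = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n, n), dtype=np.float64
    )
    Ainv.sum_duplicates()
    logdet_A = float(np.sum(np.log(d)))
    return Ainv, logdet_A


def gene_drop_relationships(
    pedigree: Pedigree, n_replicates: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo estimate of A by gene dropping (identity-by-descent sampling).

    Two independent founder alleles per founder; offspring inherit one allele
    from each parent uniformly at random.  The additive relationship between
    ``i`` and ``j`` is ``2 * P(random allele of i IBD to random allele of j)``,
    estimated over replicates.  Intended as a small-pedigree oracle.
    """
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    sire_ix, dam_ix = pedigree.parent_indices()
    # allele labels: founders get fresh labels, offspring sample from parents
    est = np.zeros((n, n))
    next_label = 0
    alleles = np.zeros((n_replicates, n, 2), dtype=np.int32)
    for i in range(n):
        for slot, p in enumerate((sire_ix[i], dam_ix[i])):
            if p < 0:
                alleles[:, i, slot] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_replicates)
                alleles[:, i, slot] = alleles[np.arange(n_replicates), p, pick]
    for i in range(n):
        for j in range(i + 1):
            ibd = np.zeros(n_replicates)
            for s in range(2):
                for t in range(2):
                    ibd += alleles[:, i, s] == alleles[:, j, t]
            est[i, j] = est[j, i] = 0.5 * float(ibd.mean())
    return est
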