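"""Pedigree, genomic and combined (single-step) relationship matrices.

The single-step machinery rests on three kernels:

* the numerator relationship matrix ``A`` built from the pedigree by the
  tabular method (with inbreeding),
* the genomic relationship matrix ``G = Z D Z' q`` built from
  allele-frequency-centred gene content (VanRaden method 1, with optional
  per-marker weights ``D``), and
* the combined inverse ``H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]]`` that
  joins genotyped and non-genotyped animals, where ``A22`` is the pedigree
  relationship restricted to the genotyped animals.

All animals are referenced by their position in the pedigree; genotyped
animals carry an index vector into that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, unknown ids, duplicates)."""


@dataclass
class Pedigree:
    """Ordered pedigree: parents precede offspring.

    Parameters
    ----------
    ids : list of str
        Animal identifiers, unique, in an order where every parent appears
        before any of its offspring.
    sire, dam : ndarray of int
        Positional index of each animal's sire/dam, ``-1`` when unknown.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate animal ids in pedigree")
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise PedigreeError("parent index arrays must match id count")
        for p in (self.sire, self.dam):
            if np.any(p >= np.arange(n)):
                raise PedigreeError(
                    "pedigree not ordered parents-first (or an animal is its "
                    "own ancestor); reorder with Pedigree.from_records"
                )
            if np.any(p < -1):
                raise PedigreeError("parent indices must be >= -1")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_ids) -> np.ndarray:
        """Positional indices of the given animal ids (error on unknown)."""
        try:
            return np.array([self._index[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from exc

    @classmethod
    def from_records(cls, records, reorder: bool = True) -> "Pedigree":
        """Build a pedigree from (animal, sire, dam) triples.

        ``None``, ``"0"``, ``""`` and ``"NA"`` denote unknown parents.  Every
        named parent must itself appear as an animal.  When ``reorder`` is
        true, records listed before their parents are sorted into a valid
        parents-first order (a cycle raises :class:`PedigreeError`).
        """
        missing = (None, "0", "", "NA", 0)
        rows = [(str(a), None if s in missing else str(s),
                 None if d in missing else str(d)) for a, s, d in records]
        known = {a for a, _, _ in rows}
        for a, s, d in rows:
            for p in (s, d):
                if p is not None and p not in known:
                    raise PedigreeError(
                        f"parent {p!r} of {a!r} does not appear as an animal"
                    )
        if len(known) != len(rows):
            raise PedigreeError("duplicate animal ids in pedigree")
        if reorder:
            rows = _topo_sort(rows)
        ids = [a for a, _, _ in rows]
        pos = {a: i for i, a in enumerate(ids)}
        sire = np.array([pos[s] if s is not None else -1 for _, s, _ in rows])
        dam = np.array([pos[d] if d is not None else -1 for _, _, d in rows])
        return cls(ids, sire, dam)

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F = diag(A) - 1."""
        return np.diag(build_A(self)) - 1.0


def _topo_sort(rows):
    """Stable parents-first ordering; no-op on valid input, cycles raise."""
    seen: set[str] = set()
    valid = True
    for a, s, d in rows:
        if any(p is not None and p not in seen for p in (s, d)):
            valid = False
            break
        seen.add(a)
    if valid:
        return rows
    import heapq

    pos = {a: i for i, (a, _, _) in enumerate(rows)}
    parents = {a: [p for p in (s, d) if p is not None] for a, s, d in rows}
    children: dict[str, list[str]] = {a: [] for a in parents}
    indeg = {a: 0 for a in parents}
    for a, ps in parents.items():
        for p in ps:
            children[p].append(a)
            indeg[a] += 1
    heap = [pos[a] for a in indeg if indeg[a] == 0]
    heapq.heapify(heap)
    byid = {a: (a, s, d) for a, s, d in rows}
    ids = [a for a, _, _ in rows]
    order = []
    while heap:
        a = ids[heapq.heappop(heap)]
        order.append(a)
        for ch in children[a]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                heapq.heappush(heap, pos[ch])
    if len(order) != len(rows):
        raise PedigreeError("cycle in pedigree (an animal is its own ancestor)")
    return [byid[a] for a in order]


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``a_ii = 1 + 0.5 a_{sire,dam}`` (inbreeding from the parents' mutual
    relationship) and ``a_ij = 0.5 (a_{j,sire(i)} + a_{j,dam(i)})`` for
    ``j`` preceding ``i``; unknown parents contribute nothing.
    """
    n = pedigree.n
    s, d = pedigree.sire, pedigree.dam
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            row = 0.5 * (A[si, :i] + A[di, :i])
            aii = 1.0 + 0.5 * A[si, di]
        elif si >= 0:
            row = 0.5 * A[si, :i]
            aii = 1.0
        elif di >= 0:
            row = 0.5 * A[di, :i]
            aii = 1.0
        else:
            row = np.zeros(i)
            aii = 1.0
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = aii
    return A


def build_A_inverse(pedigree: Pedigree, as_sparse: bool = True):
    """Inverse of A by Henderson's rules, accounting for inbreeding.

    Each animal contributes ``(e_i - 0.5 e_s - 0.5 e_d)(...)'/ m_i`` where
    ``m_i`` is its Mendelian-sampling variance: ``0.5 - 0.25 (F_s + F_d)``
    with both parents known, ``0.75 - 0.25 F_p`` with one, 1 with none.
    """
    n = pedigree.n
    s, d = pedigree.sire, pedigree.dam
    F = pedigree.inbreeding()
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            m = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            m = 0.75 - 0.25 * F[si if si >= 0 else di]
        else:
            m = 1.0
        b = 1.0 / m
        members = [(i, 1.0)] + [(p, -0.5) for p in (si, di) if p >= 0]
        for (r, cr) in members:
            for (c, cc) in members:
                rows.append(r)
                cols.append(c)
                vals.append(b * cr * cc)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv if as_sparse else Ainv.toarray()


@dataclass
class GenotypeMatrix:
    """Allele dosages (animals x markers) with a marker map.

    ``dosages`` counts copies of the tracked allele (0/1/2; NaN allowed only
    before quality control).  ``marker_map`` is a DataFrame-like with columns
    ``marker``, ``chrom``, ``bp`` sorted by (chrom, bp).  Allele frequencies
    are those of the tracked allele, computed from the genotyped sample
    unless supplied.
    """

    dosages: np.ndarray
    animal_ids: list[str]
    marker_map: "pandas.DataFrame"  # noqa: F821 - avoid hard import at type time
    allele_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (animals x markers)")
        if self.dosages.shape[0] != len(self.animal_ids):
            raise ValueError("animal_ids length must match dosage rows")
        if self.dosages.shape[1] != len(self.marker_map):
            raise ValueError("marker_map length must match dosage columns")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(
                self.dosages, initial=0
            ) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        if self.allele_freqs is None:
            self.allele_freqs = np.nanmean(self.dosages, axis=0) / 2.0
        else:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def centred(self) -> np.ndarray:
        """Gene-content matrix Z: dosage minus twice the allele frequency."""
        return self.dosages - 2.0 * self.allele_freqs

    def subset(self, animal_ids) -> "GenotypeMatrix":
        """Restrict to the given animals, recomputing allele frequencies."""
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = [pos[a] for a in animal_ids]
        return GenotypeMatrix(
            dosages=self.dosages[idx], animal_ids=list(animal_ids),
            marker_map=self.marker_map,
        )


def build_G(
    genotypes: GenotypeMatrix,
    weights: np.ndarray | None = None,
    target_mean_diag: float | None = None,
) -> tuple[np.ndarray, float]:
    """Genomic relationship matrix ``G = Z D Z' q`` (VanRaden method 1).

    ``q`` scales the raw ``Z D Z'`` so that its mean diagonal equals
    ``target_mean_diag`` (typically ``mean(diag(A22))``); when no target is
    given the raw mean diagonal is kept, i.e. ``q = 1``.

    Returns
    -------
    (G, q)
    """
    Z = genotypes.centred()
    if Z.shape[1] == 0:
        raise ValueError("empty marker set")
    if np.isnan(Z).any():
        raise ValueError("missing dosages: run QC / imputation before build_G")
    var = Z.var(axis=0)
    if np.any(var == 0):
        bad = int(np.flatnonzero(var == 0)[0])
        raise ValueError(f"monomorphic marker at column {bad}: zero variance")
    if weights is None:
        weights = np.ones(Z.shape[1])
    weights = np.asarray(weights, dtype=float)
    ZD = Z * weights
    G_raw = ZD @ Z.T
    raw_mean = float(np.mean(np.diag(G_raw)))
    if target_mean_diag is None:
        q = 1.0
    else:
        q = float(target_mean_diag) / raw_mean
    G = G_raw * q
    return 0.5 * (G + G.T), q


def blend_G(G: np.ndarray, A22: np.ndarray, eps: float = 0.05) -> np.ndarray:
    """Stabilise G toward its pedigree counterpart: (1-eps) G + eps A22.

    With ``eps = 0`` the genomic matrix is returned untouched (the pure
    VanRaden form); a small positive ``eps`` guarantees invertibility when
    the marker count does not support full rank.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError("blending epsilon must lie in [0, 1)")
    if eps == 0.0:
        return G
    return (1.0 - eps) * G + eps * A22


def build_H_inverse(
    A_inv,
    A22_inv: np.ndarray,
    G_inv: np.ndarray,
    genotyped_index: np.ndarray,
) -> sp.csr_matrix:
    """Single-step inverse ``H^-1 = A^-1 + [[0,0],[0, G^-1 - A22^-1]]``.

    The ``G^-1 - A22^-1`` block is added at the genotyped animals'
    positions; with no genotyped animals H^-1 is exactly A^-1.
    """
    A_inv = sp.csr_matrix(A_inv)
    idx = np.asarray(genotyped_index, dtype=np.int64)
    if idx.size == 0:
        return A_inv.copy()
    diffblock = np.asarray(G_inv) - np.asarray(A22_inv)
    r = np.repeat(idx, idx.size)
    c = np.tile(idx, idx.size)
    add = sp.coo_matrix((diffblock.ravel(), (r, c)), shape=A_inv.shape)
    return (A_inv + add.tocsr()).tocsr()


@dataclass
class RelationshipSet:
    """All relationship kernels for one analysis.

    Holds A, A^-1, the genotyped subset A22 (and inverse), the genomic G
    (and inverse, after optional blending), the combined H^-1, the
    genotyped-animal index into the pedigree ordering, and the G scaling
    factor q.
    """

    A: np.ndarray
    A_inv: sp.csr_matrix
    genotyped_index: np.ndarray
    A22: np.ndarray | None = None
    A22_inv: np.ndarray | None = None
    G: np.ndarray | None = None
    G_inv: np.ndarray | None = None
    H_inv: sp.csr_matrix | None = None
    q: float = 1.0

    @classmethod
    def from_pedigree(
        cls,
        pedigree: Pedigree,
        genotypes: GenotypeMatrix | None = None,
        weights: np.ndarray | None = None,
        eps: float = 0.05,
    ) -> "RelationshipSet":
        """Build every kernel from a pedigree and (optionally) genotypes.

        ``eps`` blends G toward A22 before inversion (0 disables blending,
        at the cost of requiring a full-rank marker panel).
        """
        A = build_A(pedigree)
        A_inv = build_A_inverse(pedigree)
        if genotypes is None:
            return cls(A=A, A_inv=A_inv, genotyped_index=np.empty(0, np.int64),
                       H_inv=A_inv.copy())
        idx = pedigree.index_of(genotypes.animal_ids)
        A22 = A[np.ix_(idx, idx)]
        G, q = build_G(genotypes, weights=weights,
                       target_mean_diag=float(np.mean(np.diag(A22))))
        Gb = blend_G(G, A22, eps=eps)
        try:
            G_inv = np.linalg.inv(Gb)
            A22_inv = np.linalg.inv(A22)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular genomic matrix: increase the blending epsilon "
                "(RelationshipSet.from_pedigree(..., eps=...)) or supply "
                "more markers"
            ) from exc
        H_inv = build_H_inverse(A_inv, A22_inv, G_inv, idx)
        return cls(A=A, A_inv=A_inv, genotyped_index=idx, A22=A22,
                   A22_inv=A22_inv, G=G, G_inv=G_inv, H_inv=H_inv, q=q)
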