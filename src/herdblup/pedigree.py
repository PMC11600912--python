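"""Pedigree container and numerator-relationship machinery.

Implements the recursive tabular method for A, Henderson's rules for the
sparse inverse A⁻¹ with exact inbreeding (Meuwissen & Luo's algorithm),
extraction of the genotyped block A22, and unknown-parent genetic groups by
the extended-pedigree (phantom-parent) device.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1

__all__ = [
    "Pedigree",
    "GeneticGroupMap",
    "compute_inbreeding",
    "compute_A_tabular",
    "compute_A_inverse",
    "extract_A22",
    "make_group_map",
    "restrict_to_generations",
]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    Attributes
    ----------
    ids : list of str
        Animal identifiers in processing order.
    sire, dam : int arrays
        Index of the parent in ``ids``; ``-1`` for unknown.
    sex : array of 'M'/'F'.
    birth_year : int array.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    birth_year: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=object)
        self.birth_year = np.asarray(self.birth_year, dtype=np.int64)
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}
        self._check_order()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame, strict_years: bool = False) -> "Pedigree":
        """Build a pedigree from a frame with columns id,sire,dam,sex,birth_year.

        Rows may be in any order; a topological sort is applied.  Unknown
        parents are coded 0, empty or NA.  Cycles raise ``PedigreeError``.
        """
        df = df.copy()
        df["id"] = df["id"].astype(str)
        # canonical order: by birth year then id, so row order is irrelevant
        df = df.sort_values(["birth_year", "id"], kind="stable")
        ids = [str(a) for a in df["id"]]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate animal ids in pedigree")
        known = set(ids)

        def parent(v):
            v = "" if pd.isna(v) else str(v)
            if v in ("", "0", "0.0"):
                return None
            if v not in known:
                raise PedigreeError(f"parent {v!r} not listed as an animal")
            return v

        sires = [parent(v) for v in df["sire"]]
        dams = [parent(v) for v in df["dam"]]
        order = _toposort(ids, sires, dams)
        pos = {a: k for k, a in enumerate(order)}
        df.index = ids
        df = df.loc[order]
        sire_ix = np.array([UNKNOWN if s is None else pos[s]
                            for s in (sires[ids.index(a)] for a in order)])
        dam_ix = np.array([UNKNOWN if d is None else pos[d]
                           for d in (dams[ids.index(a)] for a in order)])
        years = df["birth_year"].to_numpy(dtype=np.int64)
        for i in range(len(order)):
            for p in (sire_ix[i], dam_ix[i]):
                if p != UNKNOWN and years[p] > years[i]:
                    msg = (f"parent {order[p]} born {years[p]} after "
                           f"offspring {order[i]} born {years[i]}")
                    if strict_years:
                        raise PedigreeError(msg)
        return cls(ids=list(order), sire=sire_ix, dam=dam_ix,
                   sex=df["sex"].to_numpy(dtype=object), birth_year=years)

    def to_frame(self) -> pd.DataFrame:
        sire = ["0" if s == UNKNOWN else self.ids[s] for s in self.sire]
        dam = ["0" if d == UNKNOWN else self.ids[d] for d in self.dam]
        return pd.DataFrame({"id": self.ids, "sire": sire, "dam": dam,
                             "sex": self.sex, "birth_year": self.birth_year})

    # -- basics ----------------------------------------------------------
    def __len__(self):
        return len(self.ids)

    @property
    def n(self):
        return len(self.ids)

    def index_of(self, animals) -> np.ndarray:
        try:
            return np.array([self._index[str(a)] for a in animals], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"animal {e.args[0]!r} not in pedigree") from None

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def _check_order(self):
        n = len(self.ids)
        for i in range(n):
            if (self.sire[i] >= i and self.sire[i] != UNKNOWN) or \
               (self.dam[i] >= i and self.dam[i] != UNKNOWN):
                raise PedigreeError(
                    f"pedigree not topologically ordered at {self.ids[i]}")


def _toposort(ids, sires, dams):
    """Kahn topological sort; stable in input order; raises on cycles."""
    pos = {a: i for i, a in enumerate(ids)}
    children = {a: [] for a in ids}
    indeg = {a: 0 for a in ids}
    for a, s, d in zip(ids, sires, dams):
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    ready = [a for a in ids if indeg[a] == 0]
    ready.sort(key=pos.__getitem__)
    out = []
    import heapq
    heap = [(pos[a], a) for a in ready]
    heapq.heapify(heap)
    while heap:
        _, a = heapq.heappop(heap)
        out.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (pos[c], c))
    if len(out) != len(ids):
        bad = next(a for a in ids if indeg[a] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving {bad!r}")
    return out


# -- genetic groups ------------------------------------------------------

@dataclass
class GeneticGroupMap:
    """Assignment of unknown-parent slots to genetic groups.

    Groups are keyed by (sex of the animal, birth-year bin, which parent is
    missing) and appended after all real animals as phantom-parent columns,
    ordered lexicographically by group id.
    """

    group_ids: list                      # ordered group labels
    sire_group: np.ndarray               # per animal: group index or -1
    dam_group: np.ndarray

    @property
    def n_groups(self):
        return len(self.group_ids)


def make_group_map(ped: Pedigree, bin_width: int = 5) -> GeneticGroupMap:
    y0 = int(ped.birth_year.min())
    keys = {}
    sire_g = np.full(ped.n, -1, dtype=np.int64)
    dam_g = np.full(ped.n, -1, dtype=np.int64)
    raw = []
    for i in range(ped.n):
        b = (int(ped.birth_year[i]) - y0) // bin_width
        if ped.sire[i] == UNKNOWN:
            raw.append((i, "sire", (str(ped.sex[i]), b, "sire")))
        if ped.dam[i] == UNKNOWN:
            raw.append((i, "dam", (str(ped.sex[i]), b, "dam")))
    labels = sorted({k for _, _, k in raw})
    keys = {k: j for j, k in enumerate(labels)}
    for i, slot, k in raw:
        (sire_g if slot == "sire" else dam_g)[i] = keys[k]
    gids = [f"G_{s}_{b}_{m}" for (s, b, m) in labels]
    return GeneticGroupMap(group_ids=gids, sire_group=sire_g, dam_group=dam_g)


# -- inbreeding and relationship matrices --------------------------------

def compute_inbreeding(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Exact inbreeding coefficients by Meuwissen & Luo's algorithm.

    Returns (F, D) where D[i] is the Mendelian-sampling variance factor:
    D_i = 0.5 − 0.25 (F_s + F_d), with F = −1 substituted for an unknown
    parent (giving 0.75 with one parent known, 1 with none).
    """
    n = ped.n
    F = np.zeros(n)
    D = np.zeros(n)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        fs = F[sire[i]] if sire[i] != UNKNOWN else -1.0
        fd = F[dam[i]] if dam[i] != UNKNOWN else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if sire[i] == UNKNOWN or dam[i] == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate A_ii = sum_j L_ij^2 D_j walking ancestors downward
        coeff = {i: 1.0}
        a_ii = 0.0
        while coeff:
            j = max(coeff)
            c = coeff.pop(j)
            a_ii += c * c * D[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    coeff[p] = coeff.get(p, 0.0) + 0.5 * c
        F[i] = a_ii - 1.0
    return F, D


def compute_A_tabular(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the recursive tabular method."""
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return A


def compute_A_inverse(ped: Pedigree, groups: GeneticGroupMap | None = None
                      ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse A⁻¹ by Henderson's rules with exact inbreeding.

    With ``groups``, the system is extended by phantom-parent group columns
    (appended after all animals); unknown parents are replaced by their
    group, while the Mendelian-sampling variance D still treats them as
    unknown, following the classical unknown-parent-group construction.
    Returns (A_inv, F).
    """
    F, D = compute_inbreeding(ped)
    n = ped.n
    ng = groups.n_groups if groups is not None else 0
    rows, cols, vals = [], [], []

    def parents_of(i):
        out = []
        s, d = ped.sire[i], ped.dam[i]
        if s != UNKNOWN:
            out.append(s)
        elif groups is not None and groups.sire_group[i] >= 0:
            out.append(n + groups.sire_group[i])
        if d != UNKNOWN:
            out.append(d)
        elif groups is not None and groups.dam_group[i] >= 0:
            out.append(n + groups.dam_group[i])
        return out

    for i in range(n):
        alpha = 1.0 / D[i]
        ps = parents_of(i)
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in ps:
            rows += [i, p]; cols += [p, i]; vals += [-alpha / 2, -alpha / 2]
        for p in ps:
            for q in ps:
                rows.append(p); cols.append(q); vals.append(alpha / 4)
    m = n + ng
    A_inv = sp.coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsr()
    return A_inv, F


def extract_A22(ped: Pedigree, genotyped, A: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """A22 (genotyped block of A) and its inverse.

    For small pedigrees the dense tabular A is used directly; otherwise the
    columns of A for genotyped animals are obtained by solving the sparse
    A⁻¹ system, which avoids forming the full dense A.
    """
    ix = ped.index_of(genotyped)
    if A is not None:
        A22 = A[np.ix_(ix, ix)]
    elif ped.n <= 1500:
        A22 = compute_A_tabular(ped)[np.ix_(ix, ix)]
    else:
        A_inv, _ = compute_A_inverse(ped)
        rhs = np.zeros((ped.n, len(ix)))
        rhs[ix, np.arange(len(ix))] = 1.0
        lu = sp.linalg.splu(A_inv.tocsc(), permc_spec="MMD_AT_PLUS_A")
        cols = lu.solve(rhs)
        A22 = cols[ix, :]
        A22 = 0.5 * (A22 + A22.T)
    A22_inv = np.linalg.inv(A22)
    A22_inv = 0.5 * (A22_inv + A22_inv.T)
    return A22, A22_inv


def restrict_to_generations(ped: Pedigree, animals, depth: int = 4) -> Pedigree:
    """Ancestor closure of ``animals`` up to ``depth`` generations back.

    Used to build the reduced pedigree for variance-component estimation on
    a recent cohort.
    """
    keep = set(ped.index_of(animals).tolist())
    frontier = set(keep)
    for _ in range(depth):
        nxt = set()
        for i in frontier:
            for p in (ped.sire[i], ped.dam[i]):
                if p != UNKNOWN and p not in keep:
                    nxt.add(int(p))
        keep |= nxt
        frontier = nxt
        if not frontier:
            break
    order = sorted(keep)
    pos = {i: k for k, i in enumerate(order)}
    sire = np.array([pos.get(int(ped.sire[i]), UNKNOWN)
                     if ped.sire[i] != UNKNOWN else UNKNOWN for i in order])
    dam = np.array([pos.get(int(ped.dam[i]), UNKNOWN)
                    if ped.dam[i] != UNKNOWN else UNKNOWN for i in order])
    return Pedigree(ids=[ped.ids[i] for i in order], sire=sire, dam=dam,
                    sex=ped.sex[order], birth_year=ped.birth_year[order])
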