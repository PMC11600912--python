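"""Genomic relationship machinery: marker QC, VanRaden G, blending, H⁻¹.

The genomic relationship matrix follows VanRaden's first method with
observed allele frequencies; G is linearly adjusted to the pedigree block
A22 (matching diagonal and off-diagonal means) before blending with the
polygenic weight, and the single-step H⁻¹ adds the genomic correction
(G_w⁻¹ − A22⁻¹) on the genotyped block of A⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MarkerSet",
    "filter_maf",
    "compute_G",
    "tune_G_to_A",
    "blend_polygenic",
    "build_H_inverse",
    "h_diagonal",
]


class MarkerQCError(ValueError):
    pass


@dataclass
class MarkerSet:
    """SNP dosage matrix with per-marker allele frequencies.

    ``M`` holds dosages 0/1/2 with NaN for missing; ``freqs`` are the
    observed alternate-allele frequencies, computed once from the observed
    dosages and then carried through filtering unchanged.
    """

    animal_ids: list
    marker_ids: list
    M: np.ndarray
    freqs: np.ndarray | None = None

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        ok = np.isnan(self.M) | np.isin(self.M, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(f"invalid dosage {self.M[tuple(bad)]!r} at "
                             f"animal {self.animal_ids[bad[0]]}, "
                             f"marker {self.marker_ids[bad[1]]}")
        if self.freqs is None:
            self.freqs = np.nanmean(self.M, axis=0) / 2.0
        self.freqs = np.asarray(self.freqs, dtype=float)

    @property
    def n_animals(self):
        return len(self.animal_ids)

    @property
    def n_markers(self):
        return len(self.marker_ids)

    def maf(self) -> np.ndarray:
        return np.minimum(self.freqs, 1.0 - self.freqs)

    def imputed(self) -> np.ndarray:
        """Dosages with missing cells mean-imputed to 2p."""
        M = self.M.copy()
        miss = np.isnan(M)
        if miss.any():
            M[miss] = np.broadcast_to(2.0 * self.freqs, M.shape)[miss]
        return M

    def centred(self) -> np.ndarray:
        """Column-centred dosage matrix Z = M − 2p (missing mean-imputed)."""
        return self.imputed() - 2.0 * self.freqs

    def scale(self) -> float:
        """VanRaden denominator 2 Σ p(1−p)."""
        return float(2.0 * np.sum(self.freqs * (1.0 - self.freqs)))

    def subset_animals(self, animals) -> "MarkerSet":
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        ix = [pos[a] for a in animals]
        return replace(self, animal_ids=list(animals), M=self.M[ix, :],
                       freqs=self.freqs)


def filter_maf(markers: MarkerSet, threshold: float = 0.05) -> MarkerSet:
    """Retain markers with minor allele frequency ≥ threshold.

    Frequencies are computed once on the input set and carried over; the
    operation is idempotent.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    keep = markers.maf() >= threshold
    if not keep.any():
        raise MarkerQCError("no markers left after MAF filtering")
    return replace(markers,
                   marker_ids=[m for m, k in zip(markers.marker_ids, keep) if k],
                   M=markers.M[:, keep], freqs=markers.freqs[keep])


def compute_G(markers: MarkerSet) -> np.ndarray:
    """VanRaden genomic relationship matrix G = ZZ′ / (2 Σ p(1−p))."""
    if markers.n_animals < 2:
        raise ValueError("need at least two genotyped animals")
    s = markers.scale()
    if s <= 0.0:
        raise MarkerQCError("all markers monomorphic: zero VanRaden denominator")
    Z = markers.centred()
    G = (Z @ Z.T) / s
    return 0.5 * (G + G.T)


def tune_G_to_A(G_raw: np.ndarray, A22: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Adjust G to A22 compatibility: G_tuned = α + β·G_raw.

    α and β solve the 2×2 linear system equating the diagonal mean and the
    off-diagonal mean of G_tuned with those of A22.  Returns
    (G_tuned, alpha, beta).
    """
    n = G_raw.shape[0]
    dmask = np.eye(n, dtype=bool)
    gd, go = G_raw[dmask].mean(), G_raw[~dmask].mean() if n > 1 else 0.0
    ad, ao = A22[dmask].mean(), A22[~dmask].mean() if n > 1 else 0.0
    # [1 gd; 1 go] [alpha; beta] = [ad; ao]
    det = go - gd
    if abs(det) < 1e-12 * max(1.0, abs(gd)):
        raise ValueError("degenerate G (diagonal mean equals off-diagonal "
                         "mean): cannot tune to A")
    beta = (ao - ad) / det
    alpha = ad - beta * gd
    return alpha + beta * G_raw, float(alpha), float(beta)


def blend_polygenic(G_tuned: np.ndarray, A22: np.ndarray, w_pg: float) -> np.ndarray:
    """G_w = (1 − w_pg)·G_tuned + w_pg·A22.

    ``w_pg`` is the polygenic weight: the fraction of additive genetic
    variance attributed to the pedigree rather than the markers.
    """
    if not 0.0 <= w_pg <= 1.0:
        raise ValueError("polygenic weight must lie in [0, 1]")
    if G_tuned.shape != A22.shape:
        raise ValueError("dimension mismatch between G and A22")
    return (1.0 - w_pg) * G_tuned + w_pg * A22


def build_H_inverse(A_inv: sp.spmatrix, A22_inv: np.ndarray,
                    G_w: np.ndarray, genotyped_ix: np.ndarray,
                    ridge_below: float = 0.05, w_pg: float | None = None
                    ) -> sp.csr_matrix:
    """Single-step H⁻¹ = A⁻¹ + [0, 0; 0, G_w⁻¹ − A22⁻¹] on genotyped rows.

    ``genotyped_ix`` are positions of the genotyped animals within the
    (possibly group-extended) A⁻¹ ordering.  A small ridge (1e−8 on the
    diagonal) guards the inversion of G_w when the polygenic weight is
    below ``ridge_below`` and the marker block may be rank deficient.
    """
    genotyped_ix = np.asarray(genotyped_ix, dtype=np.int64)
    if genotyped_ix.size == 0:
        return sp.csr_matrix(A_inv)
    Gw = G_w.copy()
    if w_pg is not None and w_pg < ridge_below:
        Gw[np.diag_indices_from(Gw)] += 1e-8
    try:
        Gw_inv = np.linalg.inv(Gw)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular blended genomic matrix; raise the polygenic weight "
            "or add a ridge") from e
    corr = Gw_inv - A22_inv
    corr = 0.5 * (corr + corr.T)
    n = A_inv.shape[0]
    block = sp.coo_matrix(
        (corr.ravel(),
         (np.repeat(genotyped_ix, genotyped_ix.size),
          np.tile(genotyped_ix, genotyped_ix.size))), shape=(n, n))
    return (sp.csr_matrix(A_inv) + block.tocsr()).tocsr()


def h_diagonal(A: np.ndarray, A22_inv: np.ndarray, G_w: np.ndarray | None,
               genotyped_ix: np.ndarray) -> np.ndarray:
    """Diagonal of the joint relationship matrix H.

    For genotyped animals this is diag(G_w); for the others the pedigree
    diagonal plus the genomic projection
    A12 A22⁻¹ (G_w − A22) A22⁻¹ A21 restricted to the diagonal.  With no
    genotypes it reduces to diag(A) = 1 + F.
    """
    d = np.diag(A).copy()
    if G_w is None or len(genotyped_ix) == 0:
        return d
    g = np.asarray(genotyped_ix, dtype=np.int64)
    others = np.setdiff1d(np.arange(A.shape[0]), g)
    d[g] = np.diag(G_w)
    if others.size:
        P = A[np.ix_(others, g)] @ A22_inv           # A12 A22⁻¹
        A22 = A[np.ix_(g, g)]
        Mid = G_w - A22
        d[others] += np.einsum("ij,jk,ik->i", P, Mid, P)
    return d
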