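"""Multi-parity animal-model mixed-model equations in three flavours.

Parities 1–5 of one yield trait are modelled as correlated traits with
genetic covariance G0 and residual covariance R0; fixed effects are
herd × year × season (shared across parities, one reference level dropped)
and farm-type-within-parity.  The genetic prior is A⁻¹ (ABLUP), the
single-step H⁻¹ (ssGBLUP), or the equivalent marker-effects system
(ssSNPBLUP) whose unknowns are breeding values for all animals plus SNP
effects and a genomic-mean effect per parity; the marker system never
forms G or its inverse.

Equation ordering: fixed effects, then animals × parities (animal-major,
pedigree order, genetic groups appended after real animals), then the
genomic mean, then SNPs × parities (SNP-major).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator

from .pedigree import (Pedigree, compute_A_inverse, extract_A22,
                       make_group_map, GeneticGroupMap)
from .genomic import (MarkerSet, filter_maf, compute_G, tune_G_to_A,
                      blend_polygenic, build_H_inverse)

N_PARITIES = 5

__all__ = [
    "ModelSpec",
    "MMESystem",
    "EvaluationResult",
    "MixedModelEvaluator",
    "assemble_mme",
    "assemble_sssnpblup",
    "solve_mme",
    "evaluate_herd",
]

FLAVOURS = ("ablup", "ssgblup", "sssnpblup")


@dataclass
class ModelSpec:
    """Variance components and model options for one evaluation run."""

    G0: np.ndarray
    R0: np.ndarray
    flavour: str = "ssgblup"
    w_pg: float = 0.5
    use_groups: bool = False
    group_bin_width: int = 5
    maf_threshold: float = 0.05
    method: str = "direct"
    tol: float = 1e-10
    max_iter: int = 5000

    def __post_init__(self):
        self.G0 = np.asarray(self.G0, dtype=float)
        self.R0 = np.asarray(self.R0, dtype=float)
        if self.flavour not in FLAVOURS:
            raise ValueError(f"unknown flavour {self.flavour!r}")
        for name, S in (("G0", self.G0), ("R0", self.R0)):
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"{name} must be positive definite")
        if not 0.0 <= self.w_pg <= 1.0:
            raise ValueError("w_pg must lie in [0, 1]")


class _EffectIndex:
    """Column bookkeeping for the coefficient matrix."""

    def __init__(self, phen: pd.DataFrame, n_animals: int, n_groups: int,
                 n_markers: int):
        self.hys_levels = sorted(phen["hys"].unique())
        self.ft_levels = sorted(phen["farm_type"].unique())
        self._hys_pos = {h: i for i, h in enumerate(self.hys_levels)}
        self._ft_pos = {f: i for i, f in enumerate(self.ft_levels)}
        self.n_hys = len(self.hys_levels)
        self.n_ft = len(self.ft_levels)
        self.n_fixed = (self.n_hys - 1) + N_PARITIES * self.n_ft
        self.n_animals = n_animals
        self.n_groups = n_groups
        self.n_markers = n_markers
        self.offset_animal = self.n_fixed
        self.offset_snp = self.n_fixed + N_PARITIES * (n_animals + n_groups)
        self.n_total = self.offset_snp
        if n_markers:
            # genomic mean (5) + SNP effects (5 per marker)
            self.n_total += N_PARITIES * (1 + n_markers)

    def hys_col(self, level):
        p = self._hys_pos[level]
        return None if p == 0 else p - 1

    def ft_col(self, level, parity):
        return (self.n_hys - 1) + (parity - 1) * self.n_ft + self._ft_pos[level]

    def animal_col(self, animal_ix, parity):
        return self.offset_animal + N_PARITIES * animal_ix + (parity - 1)

    def fixed_labels(self):
        lab = [f"hys:{h}" for h in self.hys_levels[1:]]
        for j in range(1, N_PARITIES + 1):
            lab += [f"ft:{f}:parity{j}" for f in self.ft_levels]
        return lab


@dataclass
class MMESystem:
    """Assembled sparse mixed-model equations C·x = rhs."""

    C: sp.csr_matrix
    rhs: np.ndarray
    index: _EffectIndex
    animal_ids: list
    spec: ModelSpec
    genotyped: list = field(default_factory=list)
    marker_ids: list = field(default_factory=list)
    groups: GeneticGroupMap | None = None
    _lu: object = field(default=None, repr=False)

    @property
    def n_equations(self):
        return self.C.shape[0]

    def factorize(self):
        if self._lu is None:
            # symmetric-pattern ordering: far less fill-in on the dense
            # genotyped block than the default column ordering
            self._lu = spla.splu(self.C.tocsc(),
                                 permc_spec="MMD_AT_PLUS_A")
        return self._lu

    def pev_blocks(self, animals) -> dict:
        """5×5 prediction-error covariance blocks of requested animals.

        Extracted from the inverse coefficient matrix: dense inversion for
        small systems, otherwise exact column solves against the cached
        sparse factorization.
        """
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        out = {}
        if self.n_equations <= 2000:
            Cinv = np.linalg.inv(self.C.toarray())
            for a in animals:
                c0 = self.index.animal_col(pos[str(a)], 1)
                out[str(a)] = Cinv[c0:c0 + N_PARITIES, c0:c0 + N_PARITIES]
        else:
            lu = self.factorize()
            for a in animals:
                c0 = self.index.animal_col(pos[str(a)], 1)
                rhs = np.zeros((self.n_equations, N_PARITIES))
                rhs[c0:c0 + N_PARITIES] = np.eye(N_PARITIES)
                X = lu.solve(rhs)
                out[str(a)] = X[c0:c0 + N_PARITIES, :]
        for a, P in out.items():
            out[a] = 0.5 * (P + P.T)
        return out


@dataclass
class EvaluationResult:
    """Per-animal per-parity (g)EBVs with solver diagnostics."""

    ebv: pd.DataFrame                      # index animal, columns parity1..5
    fixed_effects: pd.Series
    snp_effects: pd.DataFrame | None
    group_effects: pd.DataFrame | None
    diagnostics: dict
    system: MMESystem

    @property
    def gebv(self) -> pd.DataFrame:
        """Synonym under the genomic flavours."""
        return self.ebv


# ---------------------------------------------------------------------------
# assembly


def _data_part(phen: pd.DataFrame, ped: Pedigree, index: _EffectIndex,
               R0: np.ndarray):
    """Record contributions W′R⁻¹W and W′R⁻¹y.

    The residual covariance for each animal is the R0 submatrix of its
    observed parities only (trait-wise missing-record handling).
    """
    pattern_cache: dict[tuple, np.ndarray] = {}
    rows, cols, vals = [], [], []
    rhs = np.zeros(index.n_total)
    a_index = {a: i for i, a in enumerate(ped.ids)}
    for animal, sub in phen.groupby("animal", sort=False):
        sub = sub.sort_values("parity")
        parities = sub["parity"].to_numpy(dtype=int)
        if len(set(parities)) != len(parities):
            raise ValueError(f"duplicate parity record for animal {animal}")
        O = tuple(int(j) - 1 for j in parities)
        E = pattern_cache.get(O)
        if E is None:
            sub_R = R0[np.ix_(O, O)]
            try:
                E = np.linalg.inv(sub_R)
            except np.linalg.LinAlgError as e:
                raise np.linalg.LinAlgError(
                    f"singular residual submatrix for parity pattern {O}") from e
            pattern_cache[O] = E
        y = sub["value"].to_numpy(dtype=float)
        try:
            a_ix = a_index[str(animal)]
        except KeyError:
            raise KeyError(f"phenotyped animal {animal!r} absent from pedigree")
        rec_cols = []
        for j, hys, ft in zip(parities, sub["hys"], sub["farm_type"]):
            cl = []
            hc = index.hys_col(hys)
            if hc is not None:
                cl.append(hc)
            cl.append(index.ft_col(ft, int(j)))
            cl.append(index.animal_col(a_ix, int(j)))
            rec_cols.append(cl)
        Ey = E @ y
        nr = len(y)
        for a in range(nr):
            for ca in rec_cols[a]:
                rhs[ca] += Ey[a]
            for b in range(nr):
                e = E[a, b]
                for ca in rec_cols[a]:
                    for cb in rec_cols[b]:
                        rows.append(ca)
                        cols.append(cb)
                        vals.append(e)
    C_data = sp.coo_matrix((vals, (rows, cols)),
                           shape=(index.n_total, index.n_total)).tocsr()
    return C_data, rhs


def _marker_system_prior(A_star_inv, A22_inv, Z, scale, alpha, beta,
                         genotyped_ix, w_pg, G0_inv, n_extended):
    """Joint precision of (breeding values, genomic mean, SNP effects).

    Derived by eliminating nothing: u₂ = 1c + Zg + a₂ with
    Var(c) = (1−w)α·G0, Var(g) = (1−w)β/s·G0 per SNP and
    Var(a₂) = w·A22 ⊗ G0; the pedigree ties u₁ to u₂ through A⁻¹.
    Eliminating (c, g) recovers H⁻¹ built from
    G_w = (1−w)(α + β·ZZ′/s) + w·A22, so the flavours agree exactly.
    """
    k = w_pg
    m = Z.shape[1]
    n5 = N_PARITIES
    corr = ((1.0 - k) / k) * A22_inv
    ng = len(genotyped_ix)
    scatter = sp.coo_matrix(
        (corr.ravel(), (np.repeat(genotyped_ix, ng), np.tile(genotyped_ix, ng))),
        shape=(n_extended, n_extended))
    Quu = sp.kron((sp.csr_matrix(A_star_inv) + scatter.tocsr()).tocsr(),
                  G0_inv, format="csr")

    ones = np.ones((ng, 1))
    A22inv_1 = A22_inv @ ones                 # ng×1
    A22inv_Z = A22_inv @ Z                    # ng×m
    uc = np.zeros((n_extended, 1))
    uc[genotyped_ix] = -(1.0 / k) * A22inv_1
    ug = np.zeros((n_extended, m))
    ug[genotyped_ix] = -(1.0 / k) * A22inv_Z
    Quc = sp.kron(sp.csr_matrix(uc), G0_inv, format="csr")
    Qug = sp.kron(sp.csr_matrix(ug), G0_inv, format="csr")

    cc = (1.0 / k) * float((ones.T @ A22inv_1).item())
    if abs(alpha) > 1e-10:
        cc += 1.0 / ((1.0 - k) * alpha)
    cg = (1.0 / k) * (ones.T @ A22inv_Z)      # 1×m
    gg = (1.0 / k) * (Z.T @ A22inv_Z)
    gg[np.diag_indices_from(gg)] += scale / ((1.0 - k) * beta)
    Qcc = sp.kron(sp.csr_matrix([[cc]]), G0_inv, format="csr")
    Qcg = sp.kron(sp.csr_matrix(cg), G0_inv, format="csr")
    Qgg = sp.kron(sp.csr_matrix(gg), G0_inv, format="csr")

    return sp.bmat([[Quu, Quc, Qug],
                    [Quc.T, Qcc, Qcg],
                    [Qug.T, Qcg.T, Qgg]], format="csr")


def assemble_mme(phenotypes: pd.DataFrame, pedigree: Pedigree,
                 spec: ModelSpec, markers: MarkerSet | None = None,
                 genotyped=None) -> MMESystem:
    """Assemble the multi-parity MME for the requested flavour.

    ``markers`` holds dosages for (at least) the genotyped animals;
    ``genotyped`` names the animals whose genotypes enter the evaluation.
    Marker allele frequencies are recomputed on the genotyped subset and
    markers failing the MAF threshold are dropped before building the
    genomic structures.
    """
    flavour = spec.flavour
    genotyped = list(genotyped) if genotyped else []
    if flavour != "ablup" and not genotyped:
        flavour = "ablup"            # degenerates to the pedigree model

    groups = make_group_map(pedigree, spec.group_bin_width) if spec.use_groups else None
    A_inv, F = compute_A_inverse(pedigree, groups)
    n = pedigree.n
    n_groups = groups.n_groups if groups else 0
    n_ext = n + n_groups

    ms = None
    if flavour != "ablup":
        sub = markers.subset_animals(genotyped)
        ms = MarkerSet(animal_ids=sub.animal_ids, marker_ids=sub.marker_ids,
                       M=sub.M, freqs=None)      # observed freqs on subset
        if spec.maf_threshold > 0:
            ms = filter_maf(ms, spec.maf_threshold)
        A22, A22_inv = extract_A22(pedigree, genotyped)
        genotyped_ix = pedigree.index_of(genotyped)

    n_markers = ms.n_markers if (ms is not None and flavour == "sssnpblup"
                                 and spec.w_pg < 1.0) else 0
    index = _EffectIndex(phenotypes, n, n_groups, n_markers)
    C_data, rhs = _data_part(phenotypes, pedigree, index, spec.R0)

    G0_inv = np.linalg.inv(spec.G0)
    if flavour == "ablup":
        prior = sp.kron(A_inv, G0_inv, format="csr")
    elif flavour == "ssgblup":
        G_raw = compute_G(ms)
        G_tuned, _, _ = tune_G_to_A(G_raw, A22)
        G_w = blend_polygenic(G_tuned, A22, spec.w_pg)
        H_inv = build_H_inverse(A_inv, A22_inv, G_w, genotyped_ix,
                                w_pg=spec.w_pg)
        prior = sp.kron(H_inv, G0_inv, format="csr")
    else:  # sssnpblup
        if spec.w_pg == 0.0:
            raise ValueError("ssSNPBLUP requires w_pg > 0 (the marker block "
                             "is rank deficient without a polygenic ridge)")
        if spec.w_pg == 1.0:
            prior = sp.kron(A_inv, G0_inv, format="csr")
        else:
            G_raw = compute_G(ms)
            _, alpha, beta = tune_G_to_A(G_raw, A22)
            if beta <= 0:
                raise ValueError("non-positive tuning slope: genomic and "
                                 "pedigree relationships are incompatible")
            prior = _marker_system_prior(
                A_inv, A22_inv, ms.centred(), ms.scale(), alpha, beta,
                genotyped_ix, spec.w_pg, G0_inv, n_ext)
    if n_groups:
        # tiny ridge keeps the group equations non-singular (they carry no
        # records and are confounded with a fixed-effect constant)
        g0 = index.offset_animal + N_PARITIES * n
        g1 = index.offset_animal + N_PARITIES * n_ext
        ridge = sp.coo_matrix(
            (np.full(g1 - g0, 1e-8), (np.arange(g0, g1), np.arange(g0, g1))),
            shape=(index.n_total, index.n_total)).tocsr()
        C_data = C_data + ridge

    if index.n_fixed:
        # vague prior on fixed effects: disconnected levels stay estimable
        fr = sp.coo_matrix((np.full(index.n_fixed, 1e-6),
                            (np.arange(index.n_fixed), np.arange(index.n_fixed))),
                           shape=(index.n_total, index.n_total)).tocsr()
        C_data = C_data + fr

    prior_full = sp.coo_matrix(prior)
    off = index.offset_animal
    prior_full = sp.coo_matrix(
        (prior_full.data, (prior_full.row + off, prior_full.col + off)),
        shape=(index.n_total, index.n_total)).tocsr()
    C = (C_data + prior_full).tocsr()
    return MMESystem(C=C, rhs=rhs, index=index, animal_ids=list(pedigree.ids),
                     spec=spec, genotyped=genotyped,
                     marker_ids=list(ms.marker_ids) if ms is not None else [],
                     groups=groups)


def assemble_sssnpblup(phenotypes: pd.DataFrame, pedigree: Pedigree,
                       spec: ModelSpec, markers: MarkerSet,
                       genotyped) -> MMESystem:
    """Assemble the marker-effects single-step system explicitly."""
    import dataclasses
    return assemble_mme(phenotypes, pedigree,
                        dataclasses.replace(spec, flavour="sssnpblup"),
                        markers, genotyped)


def solve_mme(system: MMESystem, method: str | None = None,
              tol: float | None = None, max_iter: int | None = None
              ) -> EvaluationResult:
    """Solve the assembled equations.

    Direct sparse LU for small/indefinite systems (the marker-effects
    system may carry a negative-precision tuning entry), preconditioned
    conjugate gradients with a Jacobi preconditioner otherwise.
    """
    method = method or system.spec.method
    tol = tol if tol is not None else system.spec.tol
    max_iter = max_iter or system.spec.max_iter
    C, rhs = system.C, system.rhs
    if method == "direct":
        x = system.factorize().solve(rhs)
        iters = 0
    elif method == "pcg":
        d = C.diagonal()
        M = sp.diags(np.where(d > 0, 1.0 / d, 1.0))
        hist = []

        def cb(xk):
            hist.append(float(np.linalg.norm(rhs - C @ xk)))

        x, info = spla.cg(C, rhs, rtol=tol, maxiter=max_iter, M=M, callback=cb)
        if info != 0:
            raise RuntimeError(
                f"PCG did not converge in {max_iter} iterations; "
                f"residual history tail {hist[-5:]}")
        iters = len(hist)
    else:
        raise ValueError(f"unknown solver method {method!r}")
    rel = float(np.linalg.norm(rhs - C @ x) / max(np.linalg.norm(rhs), 1e-300))

    ix = system.index
    n = len(system.animal_ids)
    cols = [f"parity{j}" for j in range(1, 6)]
    u = x[ix.offset_animal: ix.offset_animal + N_PARITIES * n]
    ebv = pd.DataFrame(u.reshape(n, N_PARITIES), index=system.animal_ids,
                       columns=cols)
    fixed = pd.Series(x[: ix.n_fixed], index=ix.fixed_labels())
    groups_df = None
    if ix.n_groups:
        g = x[ix.offset_animal + N_PARITIES * n: ix.offset_snp]
        groups_df = pd.DataFrame(g.reshape(ix.n_groups, N_PARITIES),
                                 index=system.groups.group_ids, columns=cols)
    snp_df = None
    if ix.n_markers:
        s = x[ix.offset_snp + N_PARITIES:]
        snp_df = pd.DataFrame(s.reshape(ix.n_markers, N_PARITIES),
                              index=system.marker_ids, columns=cols)
    if not np.all(np.isfinite(ebv.to_numpy())):
        raise RuntimeError("non-finite breeding values in solution")
    return EvaluationResult(
        ebv=ebv, fixed_effects=fixed, snp_effects=snp_df,
        group_effects=groups_df,
        diagnostics={"method": method, "iterations": iters,
                     "relative_residual": rel,
                     "n_equations": system.n_equations},
        system=system)


# ---------------------------------------------------------------------------
# estimator front end


class MixedModelEvaluator(BaseEstimator):
    """Animal-model evaluator over parities-as-traits.

    Parameters mirror :class:`ModelSpec`; `fit` accepts either a
    ``SyntheticHerd`` or a phenotype frame plus pedigree/markers, and sets
    ``ebv_`` (per-animal per-parity breeding values), ``fixed_effects_``,
    ``snp_effects_`` and ``system_``.
    """

    def __init__(self, G0=None, R0=None, flavour="ssgblup", w_pg=0.5,
                 use_groups=False, group_bin_width=5, maf_threshold=0.05,
                 method="direct", tol=1e-10, max_iter=5000):
        self.G0 = G0
        self.R0 = R0
        self.flavour = flavour
        self.w_pg = w_pg
        self.use_groups = use_groups
        self.group_bin_width = group_bin_width
        self.maf_threshold = maf_threshold
        self.method = method
        self.tol = tol
        self.max_iter = max_iter

    def _spec(self):
        if self.G0 is None or self.R0 is None:
            raise ValueError("G0 and R0 variance components are required")
        return ModelSpec(G0=self.G0, R0=self.R0, flavour=self.flavour,
                         w_pg=self.w_pg, use_groups=self.use_groups,
                         group_bin_width=self.group_bin_width,
                         maf_threshold=self.maf_threshold, method=self.method,
                         tol=self.tol, max_iter=self.max_iter)

    def fit(self, data, pedigree=None, markers=None, genotyped=None):
        from .simulate import SyntheticHerd

        if isinstance(data, SyntheticHerd):
            phen, pedigree = data.phenotypes, data.pedigree
            markers, genotyped = data.markers, data.genotyped
        else:
            phen = data
        if pedigree is None:
            raise ValueError("a pedigree is required")
        system = assemble_mme(phen, pedigree, self._spec(), markers, genotyped)
        result = solve_mme(system)
        self.result_ = result
        self.system_ = system
        self.ebv_ = result.ebv
        self.fixed_effects_ = result.fixed_effects
        self.snp_effects_ = result.snp_effects
        self.diagnostics_ = result.diagnostics
        return self

    def predict(self, animals=None) -> pd.DataFrame:
        """Fitted breeding values, optionally for a subset of animals."""
        if not hasattr(self, "ebv_"):
            raise RuntimeError("estimator is not fitted")
        return self.ebv_ if animals is None else self.ebv_.loc[list(animals)]


def evaluate_herd(herd, spec: ModelSpec) -> EvaluationResult:
    """One-call evaluation of a synthetic herd under a model spec."""
    system = assemble_mme(herd.phenotypes, herd.pedigree, spec,
                          herd.markers, herd.genotyped)
    return solve_mme(system)
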