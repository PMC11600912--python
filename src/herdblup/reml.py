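"""Multi-parity REML variance components on the pedigree animal model.

Average-information REML with an EM fallback: the score and the AI matrix
are computed exactly from the inverted mixed-model coefficient matrix
(problem sizes are desk-scale), steps are accepted only if the REML
log-likelihood does not decrease (with step halving), and non-PD proposals
are repaired by eigenvalue bending.  Standard errors come from the inverse
AI matrix at convergence; heritability SEs by the delta method.

The model matches the evaluation model without genomic data or genetic
groups: herd × year × season and farm-type-within-parity fixed effects,
additive animal effects with covariance A ⊗ G0, and residuals whose
per-animal covariance is the R0 submatrix of the observed parities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .pedigree import Pedigree, compute_A_inverse, compute_A_tabular, compute_inbreeding

__all__ = ["TraitCovariances", "MultiParityREML", "estimate_reml", "heritability"]


@dataclass
class TraitCovariances:
    """Estimated genetic and residual covariances among parities."""

    G0: np.ndarray
    R0: np.ndarray
    parities: list                       # parity labels for rows/cols
    G0_se: np.ndarray | None = None
    R0_se: np.ndarray | None = None
    ai_inv: np.ndarray | None = None     # parameter covariance (G then R, vech)
    loglik_path: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def h2(self) -> np.ndarray:
        return np.diag(self.G0) / (np.diag(self.G0) + np.diag(self.R0))

    def h2_se(self) -> np.ndarray:
        """Delta-method SE of h²_j from the AI parameter covariance."""
        if self.ai_inv is None:
            raise ValueError("no AI matrix available for standard errors")
        nt = len(self.parities)
        pairs = [(a, b) for a in range(nt) for b in range(a, nt)]
        pos = {p: k for k, p in enumerate(pairs)}
        npar = len(pairs)
        out = np.zeros(nt)
        for j in range(nt):
            g, r = self.G0[j, j], self.R0[j, j]
            t = g + r
            grad = np.zeros(2 * npar)
            grad[pos[(j, j)]] = r / t**2
            grad[npar + pos[(j, j)]] = -g / t**2
            out[j] = np.sqrt(max(grad @ self.ai_inv @ grad, 0.0))
        return out


def heritability(cov: TraitCovariances) -> pd.DataFrame:
    """Per-parity h² = G0_jj/(G0_jj + R0_jj), with SEs when available."""
    tot = np.diag(cov.G0) + np.diag(cov.R0)
    if np.any(tot <= 0):
        raise ValueError("zero total variance: heritability undefined")
    df = pd.DataFrame({"parity": cov.parities, "h2": cov.h2})
    if cov.ai_inv is not None:
        df["se"] = cov.h2_se()
    return df


def _sym_pairs(nt):
    return [(a, b) for a in range(nt) for b in range(a, nt)]


def _bend(S, floor=1e-8, rel=1e-5):
    """Eigenvalue bending onto the PD cone; floor scales with the matrix."""
    if not np.isfinite(S).all():
        raise np.linalg.LinAlgError("non-finite covariance proposal")
    w, V = np.linalg.eigh(S)
    f = max(floor, rel * max(w.max(), 0.0))
    if w.min() > f:
        return S, False
    w = np.clip(w, f, None)
    return V @ np.diag(w) @ V.T, True


class _REMLWork:
    """Static structure of one REML problem (design, pedigree, patterns)."""

    def __init__(self, phen: pd.DataFrame, ped: Pedigree):
        self.ped = ped
        self.q = ped.n
        phen = phen.sort_values(["animal", "parity"], kind="stable")
        self.parities = sorted(int(j) for j in phen["parity"].unique())
        self.nt = len(self.parities)
        tmap = {j: t for t, j in enumerate(self.parities)}

        hys_levels = sorted(phen["hys"].unique())
        ft_levels = sorted(phen["farm_type"].unique())
        hpos = {h: i for i, h in enumerate(hys_levels)}
        fpos = {f: i for i, f in enumerate(ft_levels)}
        self.n_fixed = (len(hys_levels) - 1) + self.nt * len(ft_levels)
        self.p = self.n_fixed + self.nt * self.q
        a_index = {a: i for i, a in enumerate(ped.ids)}

        rows, cols = [], []
        y = []
        self.rec_animal = []
        self.rec_trait = []
        anim_slices = []
        patterns = []
        r = 0
        for animal, sub in phen.groupby("animal", sort=False):
            a_ix = a_index[str(animal)]
            start = r
            pat = []
            for j, hys, ft, val in zip(sub["parity"], sub["hys"],
                                       sub["farm_type"], sub["value"]):
                t = tmap[int(j)]
                pat.append(t)
                if hpos[hys] > 0:
                    rows.append(r)
                    cols.append(hpos[hys] - 1)
                rows.append(r)
                cols.append((len(hys_levels) - 1) + t * len(ft_levels) + fpos[ft])
                rows.append(r)
                cols.append(self.n_fixed + self.nt * a_ix + t)
                y.append(float(val))
                self.rec_animal.append(a_ix)
                self.rec_trait.append(t)
                r += 1
            anim_slices.append((a_ix, slice(start, r), tuple(pat)))
        self.N = r
        self.y = np.asarray(y)
        self.W = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                               shape=(self.N, self.p)).tocsr()
        self.anim_slices = anim_slices
        self.n_phenotyped = len(anim_slices)
        self.rec_prow = np.zeros(self.N, dtype=np.int64)
        for irow, (_, sl, _) in enumerate(anim_slices):
            self.rec_prow[sl] = irow

        self.A_inv, F = compute_A_inverse(ped)
        self.A = compute_A_tabular(ped) if self.q <= 2000 else None
        _, D = compute_inbreeding(ped)
        self.logdet_A = float(np.sum(np.log(D)))
        self.A_inv_dense = self.A_inv.toarray()

    # -- assembled state at a parameter point ---------------------------
    def rinv_blocks(self, R0):
        cache = {}
        for _, _, pat in self.anim_slices:
            if pat not in cache:
                cache[pat] = np.linalg.inv(R0[np.ix_(pat, pat)])
        return cache

    def build_rinv(self, R0):
        cache = self.rinv_blocks(R0)
        rows, cols, vals = [], [], []
        logdet_R = 0.0
        for _, sl, pat in self.anim_slices:
            E = cache[pat]
            k = sl.stop - sl.start
            idx = np.arange(sl.start, sl.stop)
            rows.append(np.repeat(idx, k))
            cols.append(np.tile(idx, k))
            vals.append(E.ravel())
            logdet_R += float(np.linalg.slogdet(R0[np.ix_(pat, pat)])[1])
        Rinv = sp.coo_matrix((np.concatenate(vals),
                              (np.concatenate(rows), np.concatenate(cols))),
                             shape=(self.N, self.N)).tocsr()
        return Rinv, logdet_R, cache

    def loglik(self, G0, R0, want_state=False):
        nt, q = self.nt, self.q
        try:
            Rinv, logdet_R, cache = self.build_rinv(R0)
        except np.linalg.LinAlgError:
            if want_state:
                raise
            return -np.inf
        G0_inv = np.linalg.inv(G0)
        prior = sp.kron(self.A_inv, G0_inv, format="csr")
        C = (self.W.T @ Rinv @ self.W).tolil()
        Cd = C.toarray()
        Cd[self.n_fixed:, self.n_fixed:] += prior.toarray()
        # vague prior on fixed effects: keeps disconnected levels estimable
        Cd[np.arange(self.n_fixed), np.arange(self.n_fixed)] += 1e-6
        rhs = self.W.T @ (Rinv @ self.y)
        try:
            cho = la.cho_factor(Cd, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            if want_state:
                raise
            return -np.inf
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        x = la.cho_solve(cho, rhs, check_finite=False)
        yRy = float(self.y @ (Rinv @ self.y))
        yPy = yRy - float(rhs @ x)
        logdet_G = nt * self.logdet_A + q * float(np.linalg.slogdet(G0)[1])
        ll = -0.5 * (logdet_R + logdet_G + logdet_C + yPy)
        if not want_state:
            return ll
        return ll, {"Rinv": Rinv, "cache": cache, "cho": cho, "x": x,
                    "rhs": rhs, "Cd": Cd, "G0_inv": G0_inv}

    def derivatives(self, G0, R0, state):
        """Exact REML score and AI matrix; also EM-update candidates."""
        nt, q, nf = self.nt, self.q, self.n_fixed
        pairs = _sym_pairs(nt)
        npar = len(pairs)
        Rinv, cache, cho, x = (state["Rinv"], state["cache"], state["cho"],
                               state["x"])
        G0_inv = state["G0_inv"]
        Cinv = la.cho_solve(cho, np.eye(self.p), check_finite=False)
        ehat = self.y - self.W @ x
        r = Rinv @ ehat

        U = x[nf:].reshape(q, nt)             # animal solutions
        Cuu = Cinv[nf:, nf:]
        Cuu4 = Cuu.reshape(q, nt, q, nt)
        Ainv_d = self.A_inv_dense

        # genetic traces: T = G⁻¹ − G⁻¹ C^{uu} G⁻¹, contracted with A⊗Δ
        Gi = sp.kron(self.A_inv, G0_inv, format="csr")
        GCG = Gi @ Cuu @ Gi.T
        Tmat = Gi.toarray() - np.asarray(GCG)
        T4 = Tmat.reshape(q, nt, q, nt)
        A = self.A if self.A is not None else np.linalg.inv(Ainv_d)
        Sg = np.einsum("ji,iajb->ab", A, T4, optimize=True)
        Ut = G0_inv @ U.T                      # ũ_i = G0⁻¹û_i per animal
        Qg = Ut @ Ainv_d @ Ut.T                # û′(A⁻¹⊗G0⁻¹ΔG0⁻¹)û contraction

        # residual traces
        T1 = np.zeros((nt, nt))
        for _, sl, pat in self.anim_slices:
            T1[np.ix_(pat, pat)] += cache[pat]
        VW = (Rinv @ self.W).tocsr()
        B = VW @ Cinv                          # N×p dense
        Mfull = np.asarray(B @ VW.T.toarray())  # R⁻¹W C⁻¹ W′R⁻¹, record space
        T2 = np.zeros((nt, nt))
        Qr = np.zeros((nt, nt))
        Rs = np.zeros((self.n_phenotyped, nt))
        EM_R = np.zeros((nt, nt))
        for irow, (a_ix, sl, pat) in enumerate(self.anim_slices):
            Mi = Mfull[sl, sl]
            T2[np.ix_(pat, pat)] += Mi
            ri = r[sl]
            Rs[irow, list(pat)] = ri
            R0p = R0[:, list(pat)]
            EM_R += R0p @ (np.outer(ri, ri) + Mi) @ R0p.T
            EM_R += R0 - R0p @ cache[pat] @ R0p.T
        Qr = Rs.T @ Rs
        EM_R /= self.n_phenotyped

        def contract(S, a, b):
            return S[a, b] + S[b, a] if a != b else S[a, a]

        score = np.zeros(2 * npar)
        for k, (a, b) in enumerate(pairs):
            score[k] = -0.5 * (contract(Sg, a, b) - contract(Qg, a, b))
            score[npar + k] = -0.5 * (contract(T1 - T2, a, b)
                                      - contract(Qr, a, b))

        # AI matrix from working variates
        Fmat = np.zeros((self.N, 2 * npar))
        rec_a = np.asarray(self.rec_animal)
        rec_t = np.asarray(self.rec_trait)
        for k, (a, b) in enumerate(pairs):
            D = np.zeros((nt, nt))
            D[a, b] = D[b, a] = 1.0
            vals = U @ (D @ G0_inv).T          # q×nt
            Fmat[:, k] = vals[rec_a, rec_t]
            w = Rs @ D.T                       # per-animal Δ·scatter(r)
            Fmat[:, npar + k] = w[self.rec_prow, rec_t]
        RF = Rinv @ Fmat
        WTRF = self.W.T @ RF
        PF = RF - Rinv @ (self.W @ la.cho_solve(cho, WTRF, check_finite=False))
        AI = 0.5 * (Fmat.T @ PF)
        AI = 0.5 * (AI + AI.T)

        # EM candidates
        EM_G = (U.T @ Ainv_d @ U
                + np.einsum("ij,iajb->ab", Ainv_d, Cuu4, optimize=True)) / q
        EM_G = 0.5 * (EM_G + EM_G.T)
        EM_R = 0.5 * (EM_R + EM_R.T)
        return score, AI, EM_G, EM_R


def _theta(G0, R0, pairs):
    return np.array([G0[a, b] for a, b in pairs]
                    + [R0[a, b] for a, b in pairs])


def _unpack(theta, nt, pairs):
    G0 = np.zeros((nt, nt))
    R0 = np.zeros((nt, nt))
    npar = len(pairs)
    for k, (a, b) in enumerate(pairs):
        G0[a, b] = G0[b, a] = theta[k]
        R0[a, b] = R0[b, a] = theta[npar + k]
    return G0, R0


class MultiParityREML(BaseEstimator):
    """AI-REML estimator of the parity covariance matrices.

    After ``fit``, exposes ``G0_``, ``R0_``, ``h2_``, ``h2_se_``,
    ``loglik_path_`` and the full :class:`TraitCovariances` as
    ``covariances_``.
    """

    def __init__(self, max_iter=30, tol=1e-3, var_floor=1e-8, verbose=False):
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor
        self.verbose = verbose

    def fit(self, phenotypes: pd.DataFrame, pedigree: Pedigree,
            start: TraitCovariances | None = None):
        work = _REMLWork(phenotypes, pedigree)
        nt = work.nt
        pairs = _sym_pairs(nt)
        npar = len(pairs)

        if start is not None:
            G0 = np.asarray(start.G0, dtype=float).copy()
            R0 = np.asarray(start.R0, dtype=float).copy()
        else:
            v = np.array([phenotypes.loc[phenotypes["parity"] == j, "value"].var()
                          for j in work.parities])
            G0 = 0.4 * np.diag(v)
            R0 = 0.6 * np.diag(v)

        ll, state = work.loglik(G0, R0, want_state=True)
        path = [ll]
        converged = False
        AI = None
        it = 0
        for it in range(1, self.max_iter + 1):
            score, AI, EM_G, EM_R = work.derivatives(G0, R0, state)
            theta = _theta(G0, R0, pairs)

            best = None

            def consider(G0_c, R0_c):
                nonlocal best
                try:
                    G0_c, _ = _bend(G0_c, self.var_floor)
                    R0_c, _ = _bend(R0_c, self.var_floor)
                except np.linalg.LinAlgError:
                    return None
                ll_c = work.loglik(G0_c, R0_c)
                if np.isfinite(ll_c) and (best is None or ll_c > best[0]):
                    best = (ll_c, G0_c, R0_c)
                return ll_c

            # fast path: undamped AI step; accept straight away if it climbs
            try:
                step0 = np.linalg.solve(AI + 1e-8 * np.eye(len(AI)), score)
            except np.linalg.LinAlgError:
                step0 = None
            if step0 is not None and np.isfinite(step0).all():
                ll0 = consider(*_unpack(theta + step0, nt, pairs))
                if ll0 is not None and ll0 > ll + 1e-3:
                    ll_n, G0_n, R0_n = best
                    delta = np.linalg.norm(
                        _theta(G0_n, R0_n, pairs) - theta)
                    scale = max(np.linalg.norm(theta), 1e-12)
                    G0, R0 = G0_n, R0_n
                    ll, state = work.loglik(G0, R0, want_state=True)
                    path.append(ll)
                    if self.verbose:
                        print(f"iter {it}: logL={ll:.6f} "
                              f"Δθ={delta / scale:.2e} (AI)")
                    if delta / scale < self.tol:
                        converged = True
                        break
                    continue

            # slow path: EM step (guaranteed ascent at κ = 1) plus
            # over-relaxed extrapolations along the EM direction, which
            # cure the geometric EM crawl near variance boundaries
            em_dir = _theta(EM_G, EM_R, pairs) - theta
            prev = -np.inf
            for kappa in (1.0, 2.0, 4.0, 8.0):
                ll_em = consider(*_unpack(theta + kappa * em_dir, nt, pairs))
                if ll_em is None or ll_em < prev:
                    break
                prev = ll_em
            # candidates 2..: Levenberg-damped AI steps (AI can be
            # near-singular when sparsely recorded parities leave
            # parameters weakly identified); keep whichever candidate
            # climbs highest
            dAI = np.diag(AI).copy()
            top = np.abs(dAI).max()
            dAI[dAI <= 0] = top if top > 0 else 1.0
            for lam in (1e-4, 1e-2, 1.0):
                try:
                    step = np.linalg.solve(AI + lam * np.diag(dAI), score)
                except np.linalg.LinAlgError:
                    continue
                if not np.isfinite(step).all():
                    continue
                before = best[0] if best is not None else -np.inf
                for frac in (1.0, 0.5):
                    ll_c = consider(*_unpack(theta + frac * step, nt, pairs))
                    if ll_c is not None and ll_c > before:
                        break
                if best is not None and best[0] > ll + abs(ll) * 1e-6:
                    break
            if best is None or best[0] < ll - 1e-6:
                break                          # numerically stuck: stop
            ll_n, G0_n, R0_n = best
            delta = np.linalg.norm(_theta(G0_n, R0_n, pairs) - theta)
            scale = max(np.linalg.norm(theta), 1e-12)
            gain = ll_n - ll
            G0, R0 = G0_n, R0_n
            ll, state = work.loglik(G0, R0, want_state=True)
            path.append(ll)
            if self.verbose:
                print(f"iter {it}: logL={ll:.6f} Δθ={delta / scale:.2e}")
            if delta / scale < self.tol or gain < 1e-6 * max(1.0, abs(ll)):
                converged = True
                break

        se = None
        ai_inv = None
        if AI is not None:
            try:
                ai_inv = np.linalg.inv(AI + 1e-10 * np.eye(len(AI)))
                se = np.sqrt(np.clip(np.diag(ai_inv), 0.0, None))
            except np.linalg.LinAlgError:
                pass
        G0_se = R0_se = None
        if se is not None:
            G0_se = np.zeros((nt, nt))
            R0_se = np.zeros((nt, nt))
            for k, (a, b) in enumerate(pairs):
                G0_se[a, b] = G0_se[b, a] = se[k]
                R0_se[a, b] = R0_se[b, a] = se[npar + k]
        cov = TraitCovariances(G0=G0, R0=R0, parities=work.parities,
                               G0_se=G0_se, R0_se=R0_se, ai_inv=ai_inv,
                               loglik_path=path, n_iter=it,
                               converged=converged)
        self.covariances_ = cov
        self.G0_, self.R0_ = G0, R0
        self.h2_ = cov.h2
        self.h2_se_ = cov.h2_se() if ai_inv is not None else None
        self.loglik_path_ = path
        self.converged_ = converged
        return self


def estimate_reml(phenotypes, pedigree, start=None, max_iter=30, tol=1e-3
                  ) -> TraitCovariances:
    """Functional wrapper over :class:`MultiParityREML`."""
    est = MultiParityREML(max_iter=max_iter, tol=tol)
    est.fit(phenotypes, pedigree, start=start)
    return est.covariances_
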