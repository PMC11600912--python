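"""Synthetic Holstein-like herdbook generator.

Emulates the data structure a single-step dairy evaluation consumes: an
overlapping-generation pedigree with few widely-used sires, five correlated
parities of a 305-day yield trait with heritability declining across
parities, herd × year × season and farm-type fixed effects, and selective
genotyping concentrated in recent birth years.  Founders are drawn in
Hardy–Weinberg proportions and descendants by gene dropping over
independent loci; true breeding values combine a QTL (marker) part with a
pedigree-correlated residual polygenic part so that the marker-explained
share of genetic variance is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree, UNKNOWN

__all__ = [
    "SimConfig",
    "SyntheticHerd",
    "default_G0",
    "default_R0",
    "simulate_herd",
    "truncate_records",
    "subset_genotypes",
]

N_PARITIES = 5


class ConfigError(ValueError):
    pass


def default_G0(h2=(0.47, 0.36, 0.29, 0.25, 0.21), phen_var=1.0) -> np.ndarray:
    """Genetic covariance with declining heritability across parities.

    Phenotypic variance is 1 per parity by default (trait units are
    standardized); genetic correlations decay as 0.9^|j−k|, the typical
    pattern for repeated lactation yields.
    """
    sd = np.sqrt(np.asarray(h2) * phen_var)
    corr = 0.9 ** np.abs(np.subtract.outer(np.arange(5), np.arange(5)))
    return corr * np.outer(sd, sd)


def default_R0(h2=(0.47, 0.36, 0.29, 0.25, 0.21), phen_var=1.0) -> np.ndarray:
    """Residual covariance completing phenotypic variance; mild positive
    residual correlations between neighbouring parities (0.25·0.8^(lag−1))."""
    sd = np.sqrt((1.0 - np.asarray(h2)) * phen_var)
    lag = np.abs(np.subtract.outer(np.arange(5), np.arange(5)))
    corr = np.where(lag == 0, 1.0, 0.25 * 0.8 ** (lag - 1))
    return corr * np.outer(sd, sd)


def _default_schedule(year_index: int, n_years: int, sex: str) -> float:
    """Fraction genotyped per birth-year cohort.

    Bulls are genotyped nearly exhaustively throughout; cow genotyping is
    negligible early and ramps up over the most recent eight cohorts,
    reproducing the recent-year concentration seen in real herdbooks.
    """
    if sex == "M":
        return 0.9
    ramp = 8
    k = year_index - (n_years - ramp)
    if k < 0:
        return 0.0
    return 0.1 + 0.7 * k / max(ramp - 1, 1)


@dataclass
class SimConfig:
    """Study conditions for one synthetic herd."""

    n_founders: int = 80
    n_years: int = 15
    cows_per_year: int = 120
    bulls_per_year: int = 6
    n_markers: int = 400
    n_qtl: int = 100
    founder_maf_range: tuple = (0.05, 0.5)
    G0: np.ndarray = field(default_factory=default_G0)
    R0: np.ndarray = field(default_factory=default_R0)
    marker_share: float = 0.8      # share of genetic variance on markers
    n_herds: int = 8
    seasons_per_year: int = 2
    hys_sd: float = 0.5
    farm_type_sd: float = 0.25
    parity_means: tuple = (10.0, 11.0, 11.5, 11.5, 11.0)
    start_year: int = 2000
    genotyping_schedule: object = None   # callable (year_index, n_years, sex) -> frac
    selection: bool = False              # truncation selection of parents on TBV
    seed: int = 0

    def __post_init__(self):
        self.G0 = np.asarray(self.G0, dtype=float)
        self.R0 = np.asarray(self.R0, dtype=float)
        if self.n_founders <= 0:
            raise ConfigError("n_founders must be positive")
        if self.n_qtl > self.n_markers:
            raise ConfigError("n_qtl cannot exceed n_markers")
        for name, S in (("G0", self.G0), ("R0", self.R0)):
            if S.shape != (N_PARITIES, N_PARITIES) or not np.allclose(S, S.T):
                raise ConfigError(f"{name} must be symmetric 5×5")
            if np.linalg.eigvalsh(S).min() < -1e-10:
                raise ConfigError(f"{name} must be positive semidefinite")
        if self.genotyping_schedule is None:
            self.genotyping_schedule = _default_schedule


@dataclass
class SyntheticHerd:
    """A simulated herdbook: pedigree, genotypes, phenotypes and truth."""

    pedigree: Pedigree
    markers: "MarkerSet"
    phenotypes: pd.DataFrame          # animal,parity,value,hys,farm_type,calving_year
    true_breeding_values: pd.DataFrame  # index animal, columns parity1..5
    genotyped: list                    # animal ids with retained genotypes
    true_params: dict

    @property
    def last_year(self) -> int:
        return int(self.phenotypes["calving_year"].max())

    def genotyped_markers(self):
        """MarkerSet restricted to currently genotyped animals."""
        return self.markers.subset_animals(self.genotyped)


def _psd_sqrt(S):
    w, V = np.linalg.eigh(S)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def _inbreeding_step(i, sire, dam, F, D):
    """Meuwissen–Luo walk for one animal given its ancestors' F and D."""
    s, d = sire[i], dam[i]
    fs = F[s] if s != UNKNOWN else -1.0
    fd = F[d] if d != UNKNOWN else -1.0
    D[i] = 0.5 - 0.25 * (fs + fd)
    if s == UNKNOWN or d == UNKNOWN:
        F[i] = 0.0
        return
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


def simulate_herd(config: SimConfig) -> "SyntheticHerd":
    """Simulate one herdbook; deterministic given ``config.seed``."""
    from .genomic import MarkerSet

    rng = np.random.default_rng(config.seed)
    ny, m = config.n_years, config.n_markers
    n = config.n_founders + (ny - 1) * (config.cows_per_year
                                        + config.bulls_per_year)

    # founder allele frequencies and QTL effects, scaled so the founder
    # Hardy–Weinberg marker variance equals marker_share · G0 exactly
    lo, hi = config.founder_maf_range
    p0 = rng.uniform(lo, hi, size=m)
    qtl_ix = rng.choice(m, size=config.n_qtl, replace=False)
    B = rng.standard_normal((config.n_qtl, N_PARITIES))
    Dw = 2.0 * p0[qtl_ix] * (1.0 - p0[qtl_ix])
    Sm = B.T @ (B * Dw[:, None])
    if config.marker_share > 0:
        Lm = np.linalg.cholesky(Sm + 1e-12 * np.eye(N_PARITIES))
        Lt = np.linalg.cholesky(config.marker_share * config.G0
                                + 1e-12 * np.eye(N_PARITIES))
        B = B @ np.linalg.inv(Lm).T @ Lt.T
    else:
        B = np.zeros_like(B)
    Lp = _psd_sqrt((1.0 - config.marker_share) * config.G0)

    ids = [f"A{i:05d}" for i in range(n)]
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    sex = np.empty(n, dtype=object)
    byear = np.zeros(n, dtype=np.int64)
    hap = np.zeros((n, m, 2), dtype=np.int8)
    F = np.zeros(n)
    Dms = np.zeros(n)
    poly = np.zeros((n, N_PARITIES))
    tbv = np.zeros((n, N_PARITIES))
    males_by_year: dict[int, list[int]] = {}
    females_by_year: dict[int, list[int]] = {}
    cursor = 0

    def make_animal(s_ix, d_ix, sx, y):
        nonlocal cursor
        i = cursor
        cursor += 1
        sire[i], dam[i], sex[i], byear[i] = s_ix, d_ix, sx, y
        for h, par in enumerate((s_ix, d_ix)):
            if par == UNKNOWN:
                hap[i, :, h] = rng.random(m) < p0
            else:
                which = rng.integers(0, 2, size=m)
                hap[i, :, h] = hap[par, np.arange(m), which]
        _inbreeding_step(i, sire, dam, F, Dms)
        pa = np.zeros(N_PARITIES)
        if s_ix != UNKNOWN:
            pa += 0.5 * poly[s_ix]
        if d_ix != UNKNOWN:
            pa += 0.5 * poly[d_ix]
        poly[i] = pa + np.sqrt(Dms[i]) * (Lp @ rng.standard_normal(N_PARITIES))
        dose = hap[i].sum(axis=1).astype(float)
        tbv[i] = (dose[qtl_ix] - 2.0 * p0[qtl_ix]) @ B + poly[i]
        (males_by_year if sx == "M" else females_by_year).setdefault(y, []).append(i)
        return i

    n_fm = max(4, 3 * config.bulls_per_year)
    for k in range(config.n_founders):
        make_animal(UNKNOWN, UNKNOWN, "M" if k < n_fm else "F",
                    config.start_year)

    for t in range(1, ny):
        y = config.start_year + t
        sires_avail = [i for yy in range(max(config.start_year, y - 8), y - 1)
                       for i in males_by_year.get(yy, [])]
        dams_avail = [i for yy in range(max(config.start_year, y - 10), y - 1)
                      for i in females_by_year.get(yy, [])]
        n_off = config.cows_per_year + config.bulls_per_year
        service = None
        if sires_avail:
            n_service = max(2, min(len(sires_avail), config.bulls_per_year * 3))
            if config.selection:
                service = np.array(sorted(sires_avail, key=lambda i: -tbv[i, 0])
                                   [:n_service])
            else:
                service = rng.choice(sires_avail, size=n_service, replace=False)
        chosen_dams = []
        if dams_avail:
            take = min(len(dams_avail), n_off)
            if config.selection:
                chosen_dams = sorted(dams_avail, key=lambda i: -tbv[i, 0])[:take]
            else:
                chosen_dams = list(rng.choice(dams_avail, size=take,
                                              replace=False))
        for k in range(n_off):
            s_ix = int(rng.choice(service)) if service is not None else UNKNOWN
            d_ix = int(chosen_dams[k]) if k < len(chosen_dams) else UNKNOWN
            make_animal(s_ix, d_ix, "M" if k < config.bulls_per_year else "F", y)

    ped = Pedigree(ids=ids, sire=sire, dam=dam, sex=sex, birth_year=byear)

    # ---- fixed effects and phenotypes ----------------------------------
    herd_of = rng.integers(0, config.n_herds, size=n)
    farm_type_of_herd = rng.integers(0, 2, size=config.n_herds)  # kibbutz/moshav
    ft_eff = rng.normal(0.0, config.farm_type_sd, size=(2, N_PARITIES))
    hys_eff: dict[tuple, float] = {}
    Lr = _psd_sqrt(config.R0)
    resid = rng.standard_normal((n, N_PARITIES)) @ Lr.T

    last_cy = config.start_year + ny - 1
    rec = {k: [] for k in ("animal", "parity", "value", "hys",
                           "farm_type", "calving_year")}
    for i in range(n):
        if sex[i] != "F":
            continue
        for j in range(1, N_PARITIES + 1):
            cy = int(byear[i]) + 1 + j
            if cy > last_cy:
                break
            season = int(rng.integers(0, config.seasons_per_year))
            hys = (int(herd_of[i]), cy, season)
            if hys not in hys_eff:
                hys_eff[hys] = rng.normal(0.0, config.hys_sd)
            ft = int(farm_type_of_herd[herd_of[i]])
            val = (config.parity_means[j - 1] + hys_eff[hys]
                   + ft_eff[ft, j - 1] + tbv[i, j - 1] + resid[i, j - 1])
            rec["animal"].append(ids[i])
            rec["parity"].append(j)
            rec["value"].append(float(val))
            rec["hys"].append(f"H{hys[0]}Y{hys[1]}S{hys[2]}")
            rec["farm_type"].append(f"FT{ft}")
            rec["calving_year"].append(cy)
    phen = pd.DataFrame(rec)
    if phen.empty:
        raise ConfigError("simulation produced no phenotype records; "
                          "increase n_years")

    # ---- genotyping schedule -------------------------------------------
    genotyped = []
    for t in range(ny):
        y = config.start_year + t
        for sx, pool in (("M", males_by_year.get(y, [])),
                         ("F", females_by_year.get(y, []))):
            frac = float(config.genotyping_schedule(t, ny, sx))
            k = int(round(frac * len(pool)))
            if k > 0:
                chosen = rng.choice(pool, size=k, replace=False)
                genotyped.extend(int(c) for c in chosen)
    genotyped = sorted(genotyped)
    markers = MarkerSet(animal_ids=ids,
                        marker_ids=[f"SNP{j:05d}" for j in range(m)],
                        M=hap.sum(axis=2).astype(float))

    tbv_df = pd.DataFrame(tbv, index=ids,
                          columns=[f"parity{j}" for j in range(1, 6)])
    return SyntheticHerd(
        pedigree=ped, markers=markers, phenotypes=phen,
        true_breeding_values=tbv_df,
        genotyped=[ids[i] for i in genotyped],
        true_params={"G0": config.G0.copy(), "R0": config.R0.copy(),
                     "qtl_index": qtl_ix, "qtl_effects": B,
                     "founder_freqs": p0,
                     "marker_share": config.marker_share,
                     "seed": config.seed})


def truncate_records(herd: SyntheticHerd, cutoff_year: int) -> SyntheticHerd:
    """Drop phenotype records with calving year past the cutoff.

    Pedigree, genotypes and truth are retained, so genotyped young animals
    without records stay in the evaluation — the forward-prediction design.
    """
    keep = herd.phenotypes["calving_year"] <= cutoff_year
    if not keep.any():
        raise ValueError(f"cutoff year {cutoff_year} precedes all records")
    return replace(herd, phenotypes=herd.phenotypes.loc[keep].reset_index(drop=True))


def subset_genotypes(herd: SyntheticHerd, sex: str, fraction: float,
                     seed: int = 0) -> SyntheticHerd:
    """Randomly retain round(N·fraction) of one sex's genotypes.

    Sampling is without replacement and deterministic given ``seed``; the
    other sex's genotypes are untouched.
    """
    if sex not in ("M", "F"):
        raise ValueError(f"unknown sex code {sex!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    ped = herd.pedigree
    sex_of = {a: ped.sex[i] for i, a in enumerate(ped.ids)}
    this_sex = [a for a in herd.genotyped if sex_of[a] == sex]
    other = [a for a in herd.genotyped if sex_of[a] != sex]
    k = int(round(fraction * len(this_sex)))
    rng = np.random.default_rng(seed)
    kept = list(rng.choice(this_sex, size=k, replace=False)) if k else []
    order = {a: i for i, a in enumerate(ped.ids)}
    new_set = sorted(kept + other, key=order.__getitem__)
    return replace(herd, genotyped=new_set)
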