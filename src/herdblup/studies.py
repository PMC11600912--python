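"""Canned study drivers: the package's headline analyses at desk scale.

Each function freezes one study condition (herd sizes, replicate counts,
grids) and recomputes its quantities from scratch through the library.
The herd sizes are scaled-down analogues of a national Holstein herdbook
(tens of cohorts of ~25–140 cows, a handful of progeny-tested bulls per
year, selective genotyping of recent cohorts); docs/methods.md discusses
the choices.  The cow/bull equivalence worked example runs on the
published correlation edge values, which are inputs to that arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiments import (compute_equivalence, run_fraction_experiment,
                          run_polygenic_sweep, run_truncation_experiment)
from .genomic import (blend_polygenic, build_H_inverse, compute_G, tune_G_to_A)
from .model import ModelSpec, evaluate_herd
from .outputs import LactationIndex
from .pedigree import (Pedigree, compute_A_inverse, compute_A_tabular,
                       extract_A22, restrict_to_generations)
from .reml import MultiParityREML
from .simulate import SimConfig, simulate_herd

__all__ = [
    "published_equivalence_example",
    "relationship_oracles",
    "flavour_equivalence",
    "degenerate_limits",
    "reml_recovery",
    "truncation_slope_study",
    "fraction_monotonicity_study",
    "polygenic_sweep_study",
]

# Published correlation edge values: (all genotypes, only bulls,
# only cows) per trait, with the genotyped-cow and genotyped-bull counts.
PUBLISHED_EDGE_CORRELATIONS = {
    "milk": (0.64, 0.54, 0.59),
    "fat": (0.57, 0.52, 0.50),
    "protein": (0.56, 0.45, 0.46),
}
PUBLISHED_N_GENOTYPED_COWS = 5207
PUBLISHED_N_GENOTYPED_BULLS = 1471


def published_equivalence_example() -> dict:
    """Cows-per-bull equivalence ratios from the published edge values."""
    out = {}
    for trait, (r_full, r_bulls, r_cows) in PUBLISHED_EDGE_CORRELATIONS.items():
        out[trait] = compute_equivalence(r_full, r_bulls, r_cows,
                                         PUBLISHED_N_GENOTYPED_COWS, PUBLISHED_N_GENOTYPED_BULLS)
    return out


def _random_pedigree(rng, n, n_founders):
    """Random overlapping-generation pedigree for oracle checks."""
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = np.array(["M" if rng.random() < 0.3 else "F" for _ in range(n)],
                   dtype=object)
    byear = np.zeros(n, dtype=np.int64)
    for i in range(n_founders, n):
        byear[i] = byear[max(n_founders, i - n_founders)] + 1
        lo = max(0, i - 6 * n_founders)
        males = [j for j in range(lo, i) if sex[j] == "M"]
        females = [j for j in range(lo, i) if sex[j] == "F"]
        if males and rng.random() > 0.1:
            sire[i] = int(rng.choice(males))
        if females and rng.random() > 0.1:
            dam[i] = int(rng.choice(females))
    return Pedigree(ids=[f"R{i}" for i in range(n)], sire=sire, dam=dam,
                    sex=sex, birth_year=2000 + byear)


def relationship_oracles(seed: int = 1, n_pedigrees: int = 50) -> dict:
    """Max deviations of the fast relationship constructions from their
    brute-force oracles.

    A⁻¹ (Henderson rules + Meuwissen–Luo inbreeding) against the tabular
    A on random pedigrees of ≤ 300 animals, and the sparse single-step
    H⁻¹ against a directly assembled-and-inverted H on 30-animal
    instances.
    """
    rng = np.random.default_rng(seed)
    a_dev = 0.0
    for _ in range(n_pedigrees):
        n = int(rng.integers(50, 301))
        ped = _random_pedigree(rng, n, n_founders=max(8, n // 12))
        A = compute_A_tabular(ped)
        A_inv, F = compute_A_inverse(ped)
        a_dev = max(a_dev, float(np.abs(A_inv.toarray() @ A - np.eye(n)).max()))
        a_dev = max(a_dev, float(np.abs(np.diag(A) - 1.0 - F).max()))

    h_dev = 0.0
    for _ in range(10):
        ped = _random_pedigree(rng, 30, 8)
        A = compute_A_tabular(ped)
        gix = np.sort(rng.choice(30, 10, replace=False))
        gids = [ped.ids[i] for i in gix]
        A22, A22_inv = extract_A22(ped, gids, A=A)
        from .genomic import MarkerSet
        M = rng.integers(0, 3, size=(10, 150)).astype(float)
        ms = MarkerSet(gids, [f"m{j}" for j in range(150)], M)
        G_t, _, _ = tune_G_to_A(compute_G(ms), A22)
        G_w = blend_polygenic(G_t, A22, 0.4)
        others = np.setdiff1d(np.arange(30), gix)
        P = A[np.ix_(others, gix)] @ A22_inv
        D = G_w - A22
        H = A.copy()
        H[np.ix_(gix, gix)] = G_w
        H[np.ix_(others, gix)] += P @ D
        H[np.ix_(gix, others)] += D @ P.T
        H[np.ix_(others, others)] += P @ D @ P.T
        A_inv, _ = compute_A_inverse(ped)
        H_inv = build_H_inverse(A_inv, A22_inv, G_w, gix)
        h_dev = max(h_dev, float(np.abs(np.linalg.inv(H)
                                        - H_inv.toarray()).max()))
    return {"a_inverse_max_dev": a_dev, "h_inverse_max_dev": h_dev,
            "n_pedigrees": n_pedigrees}


EQUIV_HERD = dict(n_years=8, cows_per_year=50, bulls_per_year=4,
                  n_founders=40, n_markers=200, n_qtl=60)


def flavour_equivalence(seed: int = 1, w_grid=(0.1, 0.5, 0.9)) -> dict:
    """ssSNPBLUP total breeding values against ssGBLUP on one herd."""
    cfg = SimConfig(seed=seed, **EQUIV_HERD)
    herd = simulate_herd(cfg)
    base = dict(G0=cfg.G0, R0=cfg.R0)
    dev = 0.0
    for w in w_grid:
        eg = evaluate_herd(herd, ModelSpec(flavour="ssgblup", w_pg=w,
                                           **base)).ebv.to_numpy()
        es = evaluate_herd(herd, ModelSpec(flavour="sssnpblup", w_pg=w,
                                           **base)).ebv.to_numpy()
        dev = max(dev, float(np.abs(eg - es).max() / np.abs(eg).max()))
    return {"max_rel_dev": dev, "n_animals": herd.pedigree.n,
            "n_markers": cfg.n_markers, "w_grid": list(w_grid)}


def degenerate_limits(seed: int = 1) -> dict:
    """The identities that anchor the single-step algebra.

    No genotypes → ssGBLUP equals ABLUP; polygenic weight 1 → ssGBLUP
    equals ABLUP; a zero prediction-error block gives r² = 1; a founder
    with no data sits at r² = 0.
    """
    import dataclasses

    from .model import assemble_mme, solve_mme
    from .outputs import compute_exact_reliability

    cfg = SimConfig(seed=seed, **EQUIV_HERD)
    herd = simulate_herd(cfg)
    base = dict(G0=cfg.G0, R0=cfg.R0)
    ea = evaluate_herd(herd, ModelSpec(flavour="ablup", **base)).ebv.to_numpy()
    no_geno = dataclasses.replace(herd, genotyped=[])
    d1 = float(np.abs(evaluate_herd(no_geno, ModelSpec(flavour="ssgblup",
                                                       **base))
                      .ebv.to_numpy() - ea).max())
    d2 = float(np.abs(evaluate_herd(herd, ModelSpec(flavour="ssgblup",
                                                    w_pg=1.0, **base))
                      .ebv.to_numpy() - ea).max())

    # founder with no records, descendants or genotypes: r² = 0
    rows = pd.DataFrame({
        "id": ["a", "b", "lonely"], "sire": "0", "dam": "0",
        "sex": ["F", "F", "M"], "birth_year": 2000})
    ped = Pedigree.from_frame(rows)
    phen = pd.DataFrame({"animal": ["a", "b"], "parity": 1,
                         "value": [4.0, 6.0], "hys": "H0",
                         "farm_type": "FT0", "calving_year": 2004})
    spec = ModelSpec(flavour="ablup", **base)
    system = assemble_mme(phen, ped, spec)
    solve_mme(system)
    hd = pd.Series(1.0, index=ped.ids)
    rel = compute_exact_reliability(system, hd, spec.G0, ["lonely"])
    founder_r2 = float(rel.r2["lonely"])

    # zero prediction-error block: r² = 1 by the formula directly
    w = LactationIndex().vector()
    r2_zero_pev = 1.0 - float(w @ np.zeros((5, 5)) @ w) / \
        float(w @ spec.G0 @ w)
    return {"no_geno_vs_ablup_max_dev": d1, "wpg1_vs_ablup_max_dev": d2,
            "founder_no_data_r2": founder_r2, "zero_pev_r2": r2_zero_pev}


REML_HERD = dict(n_years=12, cows_per_year=25, bulls_per_year=3,
                 n_founders=24, n_markers=30, n_qtl=12, n_herds=3,
                 seasons_per_year=1, hys_sd=0.3)


def reml_recovery(seed: int = 1, n_replicates: int = 20) -> dict:
    """Heritability recovery across seeded replicates.

    Each replicate simulates a herd under the declining-h² covariance
    pattern, restricts the pedigree to four ancestor generations of the
    recorded cows, runs AI-REML and checks each parity's h² against its
    simulated truth at two reported standard errors; also verifies the
    log-likelihood never decreased across accepted iterations.
    """
    within = []
    monotone = []
    h2_all = []
    for r in range(n_replicates):
        cfg = SimConfig(seed=(seed * 1009 + r) % (2**31 - 1), **REML_HERD)
        herd = simulate_herd(cfg)
        cows = sorted(set(herd.phenotypes["animal"]))
        ped = restrict_to_generations(herd.pedigree, cows, depth=4)
        est = MultiParityREML(max_iter=25, tol=1e-3).fit(
            herd.phenotypes, ped)
        truth = np.diag(cfg.G0) / (np.diag(cfg.G0) + np.diag(cfg.R0))
        within.extend((np.abs(est.h2_ - truth) <= 2 * est.h2_se_).tolist())
        path = est.loglik_path_
        monotone.append(all(b >= a - 1e-6 for a, b in zip(path, path[1:])))
        h2_all.append(est.h2_)
    return {"coverage_2se": float(np.mean(within)),
            "monotone_fraction": float(np.mean(monotone)),
            "mean_h2": np.mean(h2_all, axis=0).tolist(),
            "true_h2": truth.tolist(),
            "n_replicates": n_replicates}


VALIDATION_HERD = dict(n_years=14, cows_per_year=140, bulls_per_year=10,
                       n_founders=60, n_markers=300, n_qtl=80)


def truncation_slope_study(seed: int = 1, n_seeds: int = 10) -> dict:
    """Forward-prediction regression across replicate herds.

    Unselected herds, true variance components, ssGBLUP at polygenic
    weight 0.5, cutoff four years before the last calving — the regime
    where truncated-data PTAs are unbiased predictors and the replicate
    mean slope sits at one.
    """
    fits = []
    for r in range(n_seeds):
        cfg = SimConfig(seed=(seed * 2003 + r) % (2**31 - 1),
                        **VALIDATION_HERD)
        herd = simulate_herd(cfg)
        spec = ModelSpec(G0=cfg.G0, R0=cfg.R0, flavour="ssgblup", w_pg=0.5)
        fit, _, _ = run_truncation_experiment(herd, herd.last_year - 4, spec)
        fits.append(fit)
    return {"mean_slope": float(np.mean([f.b for f in fits])),
            "mean_correlation": float(np.mean([f.r for f in fits])),
            "slopes": [f.b for f in fits],
            "n_candidates": [f.n for f in fits],
            "n_seeds": n_seeds}


# few service bulls and many cows per cohort give candidate sires
# daughter-dominated complete-data evaluations — the regime in which cow
# genotypes chiefly inform the truncated arm
FRACTION_HERD = dict(n_years=12, cows_per_year=120, bulls_per_year=4,
                     n_founders=50, n_markers=200, n_qtl=60)


def fraction_monotonicity_study(seed: int = 1, sex: str = "F",
                                replicates: int = 10) -> dict:
    """Genotyped-fraction subsampling: mean correlation per fraction."""
    cfg = SimConfig(seed=seed * 4001 % (2**31 - 1), **FRACTION_HERD)
    herd = simulate_herd(cfg)
    spec = ModelSpec(G0=cfg.G0, R0=cfg.R0, flavour="ssgblup", w_pg=0.5)
    table = run_fraction_experiment(herd, herd.last_year - 4, spec, sex,
                                    replicates=replicates, seed=seed)
    r = table["mean_r"].to_numpy()
    inversions = int(np.sum(np.diff(r) < 0))
    return {"fractions": table["fraction"].tolist(),
            "mean_r": r.tolist(), "n_inversions": inversions,
            "replicates": replicates}


def polygenic_sweep_study(seed: int = 1, n_seeds: int = 6) -> dict:
    """Polygenic-weight sweep: slope and correlation series over the grid,
    averaged across replicate herds, with their trend correlation."""
    grid = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2))
    slopes = np.zeros((n_seeds, len(grid)))
    corrs = np.zeros((n_seeds, len(grid)))
    for r in range(n_seeds):
        cfg = SimConfig(seed=(seed * 5003 + r) % (2**31 - 1), **FRACTION_HERD)
        herd = simulate_herd(cfg)
        spec = ModelSpec(G0=cfg.G0, R0=cfg.R0, flavour="ssgblup")
        res = run_polygenic_sweep(herd, herd.last_year - 4, spec, grid=grid)
        slopes[r] = res.slopes
        corrs[r] = res.correlations
    mean_b = slopes.mean(axis=0)
    mean_r = corrs.mean(axis=0)
    trend = float(np.corrcoef(mean_b, mean_r)[0, 1])
    slope_dir = float(np.polyfit(grid, mean_b, 1)[0])
    corr_dir = float(np.polyfit(grid, mean_r, 1)[0])
    return {"grid": list(grid), "mean_slopes": mean_b.tolist(),
            "mean_correlations": mean_r.tolist(),
            "trend_correlation": trend,
            "slope_trend_per_unit_w": slope_dir,
            "correlation_trend_per_unit_w": corr_dir,
            "n_seeds": n_seeds}
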