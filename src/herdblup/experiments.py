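"""Forward-prediction validation experiments.

The validation design regresses PTAs computed from complete data
(observed) on PTAs computed from data truncated at a cutoff calving year
(predicted) for candidate sires whose first daughters calved after the
cutoff: a slope below one signals overdispersion (inflation) of young-bull
predictions.  On top of that sit the polygenic-weight sweep, the
genotyped-fraction subsampling with the cow/bull equivalence arithmetic,
and simple averaging of two methods' PTAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelSpec, evaluate_herd
from .outputs import LactationIndex, compute_bvt, compute_pta
from .simulate import SyntheticHerd, truncate_records, subset_genotypes

__all__ = [
    "RegressionFit",
    "CandidateRule",
    "EquivalenceResult",
    "SweepResult",
    "fit_validation_regression",
    "select_candidates",
    "run_truncation_experiment",
    "run_fraction_experiment",
    "compute_equivalence",
    "run_polygenic_sweep",
    "average_evaluations",
]


class ExperimentError(RuntimeError):
    pass


def _stars(p):
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class RegressionFit:
    """OLS of observed on predicted PTAs with the validation tests."""

    a: float                 # intercept
    b: float                 # slope
    r: float                 # Pearson correlation
    se_a: float
    se_b: float
    p_a: float               # H0: a = 0
    p_b: float               # H0: b = 1
    n: int

    @property
    def stars_a(self):
        return _stars(self.p_a)

    @property
    def stars_b(self):
        return _stars(self.p_b)


def fit_validation_regression(observed, predicted) -> RegressionFit:
    """Least-squares line observed = a + b·predicted.

    Two-sided t-tests (n − 2 df) for intercept zero and slope one, with
    the conventional significance brackets 0.05 / 0.01 / 0.001.
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    n = len(y)
    if n < 3:
        raise ValueError("need at least three pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression input")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ZeroDivisionError("zero variance in the predictor")
    b = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    a = float(y.mean() - b * x.mean())
    resid = y - a - b * x
    s2 = float(resid @ resid) / (n - 2)
    se_b = float(np.sqrt(s2 / sxx))
    se_a = float(np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)))
    sy = y.std(ddof=1)
    r = float(b * x.std(ddof=1) / sy) if sy > 0 else 1.0
    df = n - 2
    p_a = 2 * stats.t.sf(abs(a / se_a), df) if se_a > 0 else (0.0 if a else 1.0)
    p_b = 2 * stats.t.sf(abs((b - 1.0) / se_b), df) if se_b > 0 else (0.0 if b != 1 else 1.0)
    return RegressionFit(a=a, b=b, r=r, se_a=se_a, se_b=se_b,
                         p_a=float(p_a), p_b=float(p_b), n=n)


@dataclass
class CandidateRule:
    """Selects validation sires: first daughter calving after the cutoff.

    ``min_reliability`` mirrors the real-data threshold of 0.75 on current
    reliabilities; it defaults to None (off) because scaled-down synthetic
    herds yield lower reliabilities throughout.
    """

    min_reliability: float | None = None
    require_genotyped: bool = True


def select_candidates(herd: SyntheticHerd, cutoff_year: int,
                      rule: CandidateRule | None = None) -> list:
    rule = rule or CandidateRule()
    ped = herd.pedigree
    sire_of_record = herd.phenotypes["animal"].map(
        {a: ped.sire[i] for i, a in enumerate(ped.ids)})
    first_calving = herd.phenotypes.groupby(sire_of_record)["calving_year"].min()
    geno = set(herd.genotyped)
    out = []
    for six, year in first_calving.items():
        if six < 0:
            continue
        a = ped.ids[int(six)]
        if ped.sex[int(six)] != "M":
            continue
        if year <= cutoff_year:
            continue
        if rule.require_genotyped and a not in geno:
            continue
        out.append(a)
    return sorted(out)


def _pta_of(result, index: LactationIndex | None, base_cohort=None) -> pd.Series:
    bvt = compute_bvt(result.ebv, index, base_cohort)
    return compute_pta(bvt)


def run_truncation_experiment(herd: SyntheticHerd, cutoff_year: int,
                              spec: ModelSpec,
                              candidate_rule: CandidateRule | None = None,
                              index: LactationIndex | None = None):
    """Truncated-vs-complete forward prediction on candidate sires.

    Returns (RegressionFit, candidates, pta_frame) where ``pta_frame`` has
    the predicted (truncated-data) and observed (complete-data) PTAs.
    """
    rule = candidate_rule or CandidateRule()
    candidates = select_candidates(herd, cutoff_year, rule)
    if not candidates:
        raise ExperimentError("no validation sires with first daughter "
                              "calvings after the cutoff")
    truncated = truncate_records(herd, cutoff_year)
    res_t = evaluate_herd(truncated, spec)
    res_c = evaluate_herd(herd, spec)
    if rule.min_reliability is not None:
        from .outputs import compute_exact_reliability
        from .pedigree import compute_A_tabular
        A = compute_A_tabular(herd.pedigree)
        hd = pd.Series(np.diag(A), index=herd.pedigree.ids)
        rel = compute_exact_reliability(res_c.system, hd, spec.G0, candidates,
                                        index)
        candidates = [a for a in candidates
                      if rel.r2[a] >= rule.min_reliability]
        if not candidates:
            raise ExperimentError("no candidate sires pass the reliability "
                                  "threshold")
    pta_t = _pta_of(res_t, index).loc[candidates]
    pta_c = _pta_of(res_c, index).loc[candidates]
    fit = fit_validation_regression(pta_c.to_numpy(), pta_t.to_numpy())
    frame = pd.DataFrame({"predicted": pta_t, "observed": pta_c})
    return fit, candidates, frame


def run_fraction_experiment(herd: SyntheticHerd, cutoff_year: int,
                            spec: ModelSpec, sex: str,
                            fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
                            replicates: int = 10, seed: int = 0,
                            candidate_rule: CandidateRule | None = None,
                            index: LactationIndex | None = None) -> pd.DataFrame:
    """Correlation between complete- and truncated-data candidate PTAs as a
    function of the genotyped fraction of one sex.

    Each replicate draws one random subset of that sex's genotypes (the
    other sex stays fully genotyped) and evaluates both arms — complete
    and truncated records — with that same genotype set, so the zero
    fraction for both sexes reduces to the pedigree-only comparison.
    Replicate seeds derive from ``seed`` by a counter; fractions 0 and 1
    are deterministic and run once.
    """
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rule = candidate_rule or CandidateRule(require_genotyped=False)
    candidates = select_candidates(herd, cutoff_year, rule)
    if len(candidates) < 4:
        raise ExperimentError("too few candidate sires")

    # the sampled pool is restricted to genotyped animals with phenotypic
    # data before the cutoff (own records for cows, daughter records for
    # bulls) — the training animals whose genotypes inform the truncated
    # arm; genotyped animals of that sex outside the pool stay out of the
    # experiment altogether, so a zero fraction of both sexes reduces to
    # the pedigree-only comparison
    import dataclasses

    ped = herd.pedigree
    pre = herd.phenotypes.loc[herd.phenotypes["calving_year"] <= cutoff_year,
                              "animal"]
    recorded = set(pre)
    sires_with_data = {ped.ids[ped.sire[i]] for i, a in enumerate(ped.ids)
                       if a in recorded and ped.sire[i] >= 0}
    pool = recorded | sires_with_data
    sex_of = {a: ped.sex[i] for i, a in enumerate(ped.ids)}
    base = dataclasses.replace(
        herd, genotyped=[g for g in herd.genotyped
                         if sex_of[g] != sex or g in pool])

    rows = []
    counter = 0
    for f in fractions:
        reps = 1 if f in (0.0, 1.0) else replicates
        rs = []
        used_seeds = []
        for _ in range(reps):
            sub_seed = seed * 100003 + counter
            counter += 1
            sub = subset_genotypes(base, sex, f, seed=sub_seed)
            res_c = evaluate_herd(sub, spec)
            pta_c = _pta_of(res_c, index).loc[candidates].to_numpy()
            res_t = evaluate_herd(truncate_records(sub, cutoff_year), spec)
            pta_t = _pta_of(res_t, index).loc[candidates].to_numpy()
            rs.append(float(np.corrcoef(pta_c, pta_t)[0, 1]))
            used_seeds.append(sub_seed)
        rows.append({"sex": sex, "fraction": f, "mean_r": float(np.mean(rs)),
                     "sd_r": float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
                     "replicates": reps, "seeds": used_seeds})
    return pd.DataFrame(rows)


@dataclass
class EquivalenceResult:
    """Per-animal contribution to the validation correlation, per sex."""

    cow_contribution: float
    bull_contribution: float
    ratio: float                  # bulls-to-cows
    ratio_reported: str = field(init=False)

    def __post_init__(self):
        r = round(self.ratio, 1)
        self.ratio_reported = str(int(r)) if r == int(r) else str(r)


def compute_equivalence(r_full: float, r_only_bulls: float,
                        r_only_cows: float, n_cows: int, n_bulls: int
                        ) -> EquivalenceResult:
    """How many genotyped cows equal one genotyped bull.

    Edge-value arithmetic: the per-cow contribution is the correlation gain
    from no cows to all cows divided by the cow count (bulls likewise), and
    the ratio is bull over cow contribution, reported to one decimal with a
    trailing ".0" dropped.
    """
    cow = (r_full - r_only_bulls) / n_cows
    bull = (r_full - r_only_cows) / n_bulls
    if cow == 0:
        raise ZeroDivisionError("zero per-cow contribution: ratio undefined")
    return EquivalenceResult(cow_contribution=cow, bull_contribution=bull,
                             ratio=bull / cow)


@dataclass
class SweepResult:
    """Validation fits across the polygenic-weight grid."""

    grid: list
    fits: list
    trend_correlation: float      # corr(slope series, correlation series)

    @property
    def slopes(self):
        return np.array([f.b for f in self.fits])

    @property
    def correlations(self):
        return np.array([f.r for f in self.fits])


def run_polygenic_sweep(herd: SyntheticHerd, cutoff_year: int,
                        spec: ModelSpec,
                        grid=tuple(np.round(np.arange(0.1, 0.95, 0.1), 2)),
                        candidate_rule: CandidateRule | None = None,
                        index: LactationIndex | None = None) -> SweepResult:
    """One truncation experiment per polygenic weight.

    Reports the correlation between the slope series and the correlation
    series over the grid — the accuracy/inflation trade-off statistic.
    """
    from dataclasses import replace as dc_replace

    grid = [float(w) for w in grid]
    if any(not 0.0 < w < 1.0 for w in grid):
        raise ValueError("polygenic-weight grid must lie in (0, 1)")
    fits = []
    for w in grid:
        spec_w = dc_replace(spec, w_pg=w)
        fit, _, _ = run_truncation_experiment(herd, cutoff_year, spec_w,
                                              candidate_rule, index)
        fits.append(fit)
    if len(grid) >= 2:
        trend = float(np.corrcoef([f.b for f in fits],
                                  [f.r for f in fits])[0, 1])
    else:
        trend = float("nan")
    return SweepResult(grid=grid, fits=fits, trend_correlation=trend)


def average_evaluations(pta_a: pd.Series, pta_b: pd.Series) -> pd.Series:
    """Simple average of two methods' PTAs over identical animal sets."""
    if set(pta_a.index) != set(pta_b.index):
        raise ValueError("animal id mismatch between the two PTA sets")
    return (pta_a + pta_b.loc[pta_a.index]) / 2.0
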