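"""Lactation index, transmitting abilities and exact reliabilities.

The five parity EBVs are combined into a total breeding value with the
lactation index BVT = (EBV₁ + 0.73·EBV₂ + 0.51·EBV₃ + 0.34·EBV₄ +
0.21·EBV₅)/2.79, after normalising each parity to the mean EBV of a base
cohort.  PTA is half the (g)EBV.  Exact reliabilities use the
prediction-error covariance blocks P_i of the inverted mixed-model
coefficient matrix:

    r²_i = 1 − (w P_i w′) / ((w G0 w′) · diag(H)_i)

where w is the index weight vector (r² is invariant to its scaling) and
diag(H)_i the animal's diagonal in the joint relationship matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LactationIndex",
    "ReliabilityResult",
    "compute_bvt",
    "compute_pta",
    "compute_exact_reliability",
]


@dataclass
class LactationIndex:
    """Weights combining parity EBVs into a total breeding value."""

    weights: tuple = (1.0, 0.73, 0.51, 0.34, 0.21)
    denominator: float = 2.79

    def vector(self, normalized: bool = True) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / self.denominator if normalized else w


@dataclass
class ReliabilityResult:
    """Per-animal prediction-error blocks and exact reliabilities."""

    pev: dict                 # animal -> 5×5 PEV block
    h_diag: pd.Series
    r2: pd.Series


def compute_bvt(ebv: pd.DataFrame, idx: LactationIndex | None = None,
                base_cohort=None) -> pd.Series:
    """Total breeding value per animal.

    ``ebv`` has one row per animal and the five parity columns;
    ``base_cohort`` (animal ids) defines the normalisation base whose mean
    EBV is subtracted per parity before weighting.
    """
    idx = idx or LactationIndex()
    E = ebv.to_numpy(dtype=float)
    if E.shape[1] != 5:
        raise ValueError("expected five parity EBV columns")
    if base_cohort is not None:
        base = [str(a) for a in base_cohort]
        if not base:
            raise ValueError("empty normalisation base cohort")
        E = E - ebv.loc[base].to_numpy(dtype=float).mean(axis=0)
    w = np.asarray(idx.weights, dtype=float)
    return pd.Series(E @ w / idx.denominator, index=ebv.index, name="bvt")


def compute_pta(values):
    """Predicted transmitting ability: half the (g)EBV or BVT."""
    return values / 2.0


def compute_exact_reliability(system, h_diag: pd.Series, G0: np.ndarray,
                              animals, idx: LactationIndex | None = None,
                              clamp_tol: float = 1e-6) -> ReliabilityResult:
    """Exact reliabilities from the inverted coefficient matrix.

    ``system`` is an assembled-and-solved :class:`MMESystem` built without
    genetic groups; ``h_diag`` maps animal id to its diagonal of the joint
    relationship matrix (the pedigree diagonal 1 + F for non-genotyped
    animals).  Values outside [0, 1] by less than ``clamp_tol`` are clamped
    with a warning; larger excursions raise.
    """
    if getattr(system, "groups", None) is not None:
        raise ValueError("exact reliabilities require a system assembled "
                         "without genetic groups")
    idx = idx or LactationIndex()
    w = idx.vector(normalized=True)
    denom_g = float(w @ G0 @ w)
    animals = [str(a) for a in animals]
    pev = system.pev_blocks(animals)
    out = {}
    for a in animals:
        P = pev[a]
        hd = float(h_diag.loc[a])
        r2 = 1.0 - float(w @ P @ w) / (denom_g * hd)
        if r2 < -clamp_tol or r2 > 1.0 + clamp_tol:
            raise ValueError(f"reliability {r2:.6f} for animal {a} outside "
                             "[0, 1] beyond numerical tolerance")
        if r2 < 0.0 or r2 > 1.0:
            warnings.warn(f"clamping reliability {r2:.2e} for animal {a}")
            r2 = min(max(r2, 0.0), 1.0)
        out[a] = r2
    return ReliabilityResult(pev=pev, h_diag=h_diag.loc[animals],
                             r2=pd.Series(out, name="r2"))
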