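import numpy as np
import pandas as pd
import pytest

from herdblup.model import ModelSpec, assemble_mme, solve_mme
from herdblup.outputs import (LactationIndex, compute_bvt, compute_pta,
                              compute_exact_reliability)
from herdblup.pedigree import compute_A_tabular, compute_A_inverse

from conftest import make_pedigree


class TestLactationIndex:
    def test_weights_sum_to_denominator(self):
        idx = LactationIndex()
        assert sum(idx.weights) == pytest.approx(idx.denominator, abs=1e-12)

    def test_constant_ebv_idempotent(self):
        ebv = pd.DataFrame(10.0, index=["a", "b"],
                           columns=[f"parity{j}" for j in range(1, 6)])
        assert compute_bvt(ebv).to_numpy() == pytest.approx([10.0, 10.0])

    def test_single_parity_unit(self):
        ebv = pd.DataFrame([[2.79, 0, 0, 0, 0]], index=["a"],
                           columns=[f"parity{j}" for j in range(1, 6)])
        assert compute_bvt(ebv)["a"] == pytest.approx(1.0)

    def test_random_matches_dot_product(self, rng):
        E = rng.standard_normal((7, 5))
        ebv = pd.DataFrame(E, index=[f"a{i}" for i in range(7)],
                           columns=[f"parity{j}" for j in range(1, 6)])
        w = np.array([1.0, 0.73, 0.51, 0.34, 0.21])
        assert compute_bvt(ebv).to_numpy() == pytest.approx(E @ w / 2.79)

    def test_base_cohort_normalisation_absorbs_constant(self, rng):
        E = rng.standard_normal((6, 5))
        ids = [f"a{i}" for i in range(6)]
        cols = [f"parity{j}" for j in range(1, 6)]
        ebv = pd.DataFrame(E, index=ids, columns=cols)
        shifted = pd.DataFrame(E + 42.0, index=ids, columns=cols)
        b1 = compute_bvt(ebv, base_cohort=ids)
        b2 = compute_bvt(shifted, base_cohort=ids)
        assert b1.to_numpy() == pytest.approx(b2.to_numpy(), abs=1e-10)

    def test_empty_base_cohort_rejected(self):
        ebv = pd.DataFrame(1.0, index=["a"],
                           columns=[f"parity{j}" for j in range(1, 6)])
        with pytest.raises(ValueError):
            compute_bvt(ebv, base_cohort=[])


class TestPTA:
    @pytest.mark.parametrize("value,expected", [(10.0, 5.0), (0.0, 0.0),
                                                (-3.4, -1.7)])
    def test_halving(self, value, expected):
        assert compute_pta(value) == expected


def _five_trait_spec(**kw):
    G0 = np.diag([0.47, 0.36, 0.29, 0.25, 0.21])
    R0 = np.eye(5) - G0
    return ModelSpec(G0=G0, R0=R0, **kw)


def _records(animals, value=5.0, parity=1):
    return pd.DataFrame({
        "animal": animals, "parity": parity, "value": value,
        "hys": "H0", "farm_type": "FT0", "calving_year": 2004})


class TestExactReliability:
    def test_founder_without_data_zero(self):
        """A founder with no records, descendants or genotyped relatives
        has prediction-error variance equal to its prior: r² = 0."""
        ped = make_pedigree([("a", "0", "0", "F", 2000),
                             ("b", "0", "0", "F", 2000),
                             ("lonely", "0", "0", "M", 2000)])
        spec = _five_trait_spec(flavour="ablup")
        system = assemble_mme(_records(["a", "b"], value=[4.0, 6.0]), ped, spec)
        solve_mme(system)
        hd = pd.Series(1.0, index=ped.ids)
        rel = compute_exact_reliability(system, hd, spec.G0, ["lonely"])
        assert rel.r2["lonely"] == pytest.approx(0.0, abs=1e-6)
        assert rel.pev["lonely"] == pytest.approx(spec.G0, abs=1e-6)

    def test_recorded_animals_positive(self):
        ped = make_pedigree([("a", "0", "0", "F", 2000),
                             ("b", "0", "0", "F", 2000)])
        spec = _five_trait_spec(flavour="ablup")
        system = assemble_mme(_records(["a", "b"], value=[4.0, 6.0]), ped, spec)
        rel = compute_exact_reliability(system, pd.Series(1.0, index=ped.ids),
                                        spec.G0, ["a", "b"])
        assert (rel.r2 > 0.0).all()
        assert (rel.r2 < 1.0).all()

    def test_scaling_of_index_weights_irrelevant(self):
        ped = make_pedigree([("a", "0", "0", "F", 2000),
                             ("b", "0", "0", "F", 2000)])
        spec = _five_trait_spec(flavour="ablup")
        system = assemble_mme(_records(["a", "b"], value=[4.0, 6.0]), ped, spec)
        hd = pd.Series(1.0, index=ped.ids)
        r_norm = compute_exact_reliability(
            system, hd, spec.G0, ["a"], LactationIndex()).r2["a"]
        raw = LactationIndex(denominator=1.0)     # unnormalised weights
        r_raw = compute_exact_reliability(system, hd, spec.G0, ["a"],
                                          raw).r2["a"]
        assert r_norm == pytest.approx(r_raw, abs=1e-12)

    def test_single_trait_reduction_matches_dense_oracle(self, rng):
        """With a degenerate index (weight on parity 1 only) and a diagonal
        G0, r² equals the textbook animal-model reliability computed from a
        densely inverted single-trait MME."""
        from conftest import random_pedigree
        ped = random_pedigree(rng, n=50, n_founders=10)
        recorded = [a for i, a in enumerate(ped.ids) if ped.sex[i] == "F"][:25]
        vals = rng.normal(5.0, 1.0, len(recorded))
        phen = _records(recorded, value=vals)
        spec = _five_trait_spec(flavour="ablup")
        system = assemble_mme(phen, ped, spec)
        A = compute_A_tabular(ped)
        hd = pd.Series(np.diag(A), index=ped.ids)
        idx1 = LactationIndex(weights=(1.0, 0, 0, 0, 0), denominator=1.0)
        rel = compute_exact_reliability(system, hd, spec.G0, ped.ids, idx1)

        # dense single-trait oracle
        sg, se = spec.G0[0, 0], spec.R0[0, 0]
        n = ped.n
        X = np.ones((len(recorded), 1))
        Z = np.zeros((len(recorded), n))
        for r, a in enumerate(recorded):
            Z[r, ped.index_of([a])[0]] = 1.0
        A_inv = np.linalg.inv(A)
        C = np.block([[X.T @ X / se, X.T @ Z / se],
                      [Z.T @ X / se, Z.T @ Z / se + A_inv / sg]])
        C[0, 0] += 1e-6
        Cinv = np.linalg.inv(C)
        for i, a in enumerate(ped.ids):
            pev = Cinv[1 + i, 1 + i]
            r2_oracle = 1.0 - pev / (sg * A[i, i])
            assert rel.r2[a] == pytest.approx(r2_oracle, abs=1e-6)

    def test_groups_system_rejected(self):
        ped = make_pedigree([("a", "0", "0", "F", 2000)])
        spec = _five_trait_spec(flavour="ablup", use_groups=True)
        system = assemble_mme(_records(["a"]), ped, spec)
        with pytest.raises(ValueError, match="groups"):
            compute_exact_reliability(system, pd.Series(1.0, index=ped.ids),
                                      spec.G0, ["a"])


class TestReliabilityMonotonicity:
    def test_truncated_not_above_complete(self, small_herd, small_config):
        """Removing late records never raises a sire's reliability."""
        from herdblup.simulate import truncate_records
        spec = ModelSpec(G0=small_config.G0, R0=small_config.R0,
                         flavour="ablup")
        cutoff = small_herd.last_year - 3
        ped = small_herd.pedigree
        A = compute_A_tabular(ped)
        hd = pd.Series(np.diag(A), index=ped.ids)
        sires = sorted({ped.ids[s] for s in ped.sire if s >= 0})[:15]
        sys_full = assemble_mme(small_herd.phenotypes, ped, spec)
        sys_trunc = assemble_mme(
            truncate_records(small_herd, cutoff).phenotypes, ped, spec)
        r_full = compute_exact_reliability(sys_full, hd, spec.G0, sires).r2
        r_trunc = compute_exact_reliability(sys_trunc, hd, spec.G0, sires).r2
        assert (r_trunc <= r_full + 1e-6).all()
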