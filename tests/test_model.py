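import dataclasses

import numpy as np
import pandas as pd
import pytest

from herdblup.model import (ModelSpec, MixedModelEvaluator, assemble_mme,
                            solve_mme, evaluate_herd)
from herdblup.pedigree import compute_A_inverse, compute_A_tabular

from conftest import make_pedigree

G0_DIAG = np.diag([0.47, 0.36, 0.29, 0.25, 0.21])
R0_DIAG = np.eye(5) - G0_DIAG


def tiny_spec(**kw):
    return ModelSpec(G0=G0_DIAG + 0.02, R0=R0_DIAG + 0.02, **kw)


def one_animal_phen(value=5.0):
    return pd.DataFrame({"animal": ["a"], "parity": [1], "value": [value],
                         "hys": ["H0"], "farm_type": ["FT0"],
                         "calving_year": [2002]})


class TestAssembly:
    def test_single_record_mean_absorbs(self):
        """One animal, one record, one fixed level: EBV stays at zero."""
        ped = make_pedigree([("a", "0", "0", "F", 2000)])
        system = assemble_mme(one_animal_phen(), ped, tiny_spec(flavour="ablup"))
        res = solve_mme(system)
        assert abs(res.ebv.loc["a"].to_numpy()).max() < 1e-4

    def test_duplicated_herds_mirror_solutions(self):
        rows, phen = [], []
        for tag in ("x", "y"):
            for i in range(6):
                rows.append((f"{tag}{i}", "0", "0", "F", 2000))
                phen.append({"animal": f"{tag}{i}", "parity": 1,
                             "value": float(i), "hys": f"H{tag}",
                             "farm_type": "FT0", "calving_year": 2003})
        ped = make_pedigree(rows)
        res = solve_mme(assemble_mme(pd.DataFrame(phen), ped,
                                     tiny_spec(flavour="ablup")))
        for i in range(6):
            assert res.ebv.loc[f"x{i}"].to_numpy() == pytest.approx(
                res.ebv.loc[f"y{i}"].to_numpy(), abs=1e-5)

    def test_dense_textbook_oracle(self, small_herd):
        """Sparse assembly equals a dense brute-force build of the same
        equations (record loop with explicit kron prior)."""
        phen = small_herd.phenotypes.query("parity <= 2").iloc[:300]
        animals = sorted(set(phen["animal"]))
        keep = set(animals)
        ped = small_herd.pedigree
        # restrict pedigree to phenotyped animals + ancestors
        from herdblup.pedigree import restrict_to_generations
        sub_ped = restrict_to_generations(ped, animals, depth=10)
        spec = tiny_spec(flavour="ablup")
        system = assemble_mme(phen, sub_ped, spec)
        x_fast = solve_mme(system)

        # dense oracle
        n = sub_ped.n
        p = system.index.n_total
        C = np.zeros((p, p))
        rhs = np.zeros(p)
        for animal, sub in phen.groupby("animal"):
            sub = sub.sort_values("parity")
            O = [int(j) - 1 for j in sub["parity"]]
            E = np.linalg.inv(spec.R0[np.ix_(O, O)])
            W = np.zeros((len(O), p))
            for r, (j, hys, ft) in enumerate(zip(sub["parity"], sub["hys"],
                                                 sub["farm_type"])):
                hc = system.index.hys_col(hys)
                if hc is not None:
                    W[r, hc] = 1.0
                W[r, system.index.ft_col(ft, int(j))] = 1.0
                a_ix = sub_ped.index_of([animal])[0]
                W[r, system.index.animal_col(a_ix, int(j))] = 1.0
            C += W.T @ E @ W
            rhs += W.T @ E @ sub["value"].to_numpy()
        A_inv, _ = compute_A_inverse(sub_ped)
        prior = np.kron(A_inv.toarray(), np.linalg.inv(spec.G0))
        nf = system.index.n_fixed
        C[nf:, nf:] += prior
        C[np.arange(nf), np.arange(nf)] += 1e-6
        x_dense = np.linalg.solve(C, rhs)
        u = x_dense[nf:nf + 5 * n].reshape(n, 5)
        assert np.allclose(u, x_fast.ebv.to_numpy(), atol=1e-6)


class TestFlavourEquivalences:
    @pytest.mark.parametrize("w_pg", [0.1, 0.5, 0.9])
    def test_sssnpblup_matches_ssgblup(self, small_herd, small_config, w_pg):
        """The marker-effects system reproduces H⁻¹ ssGBLUP breeding values."""
        base = dict(G0=small_config.G0, R0=small_config.R0)
        res_g = evaluate_herd(small_herd, ModelSpec(flavour="ssgblup",
                                                    w_pg=w_pg, **base))
        res_s = evaluate_herd(small_herd, ModelSpec(flavour="sssnpblup",
                                                    w_pg=w_pg, **base))
        eg, es = res_g.ebv.to_numpy(), res_s.ebv.to_numpy()
        assert np.abs(eg - es).max() / np.abs(eg).max() < 1e-4
        assert res_s.snp_effects is not None

    def test_w_pg_one_equals_ablup(self, small_herd, small_config):
        base = dict(G0=small_config.G0, R0=small_config.R0)
        res_a = evaluate_herd(small_herd, ModelSpec(flavour="ablup", **base))
        res_g = evaluate_herd(small_herd, ModelSpec(flavour="ssgblup",
                                                    w_pg=1.0, **base))
        res_s = evaluate_herd(small_herd, ModelSpec(flavour="sssnpblup",
                                                    w_pg=1.0, **base))
        ea = res_a.ebv.to_numpy()
        assert np.abs(res_g.ebv.to_numpy() - ea).max() < 1e-8
        assert np.abs(res_s.ebv.to_numpy() - ea).max() < 1e-8

    def test_no_genotypes_degenerates_to_ablup(self, small_herd, small_config):
        base = dict(G0=small_config.G0, R0=small_config.R0)
        empty = dataclasses.replace(small_herd, genotyped=[])
        res_a = evaluate_herd(small_herd, ModelSpec(flavour="ablup", **base))
        res_g = evaluate_herd(empty, ModelSpec(flavour="ssgblup", **base))
        assert np.abs(res_g.ebv.to_numpy() - res_a.ebv.to_numpy()).max() < 1e-12

    def test_w_pg_zero_sssnpblup_rejected(self, small_herd, small_config):
        with pytest.raises(ValueError, match="w_pg"):
            evaluate_herd(small_herd, ModelSpec(G0=small_config.G0,
                                                R0=small_config.R0,
                                                flavour="sssnpblup", w_pg=0.0))


class TestSolvers:
    def test_pcg_matches_direct(self, small_herd, small_config):
        spec = ModelSpec(G0=small_config.G0, R0=small_config.R0,
                         flavour="ablup", tol=1e-10, max_iter=20000)
        system = assemble_mme(small_herd.phenotypes, small_herd.pedigree, spec)
        res_d = solve_mme(system, method="direct")
        res_p = solve_mme(system, method="pcg")
        assert np.abs(res_d.ebv.to_numpy() - res_p.ebv.to_numpy()).max() < 1e-6
        assert res_p.diagnostics["iterations"] > 0

    def test_residual_contract(self, small_herd, small_spec):
        res = evaluate_herd(small_herd, small_spec)
        assert res.diagnostics["relative_residual"] < 1e-8

    def test_nonconvergence_reported(self, small_herd, small_config):
        spec = ModelSpec(G0=small_config.G0, R0=small_config.R0,
                         flavour="ablup", tol=1e-12, max_iter=2)
        system = assemble_mme(small_herd.phenotypes, small_herd.pedigree, spec)
        with pytest.raises(RuntimeError, match="PCG"):
            solve_mme(system, method="pcg")


class TestModelInvariances:
    def test_uninformative_animal_leaves_solutions_unchanged(self):
        rows = [("s", "0", "0", "M", 2000), ("d", "0", "0", "F", 2000),
                ("o", "s", "d", "F", 2002)]
        phen = pd.DataFrame({
            "animal": ["d", "o"], "parity": [1, 1], "value": [4.0, 6.0],
            "hys": ["H0", "H0"], "farm_type": ["FT0", "FT0"],
            "calving_year": [2002, 2004]})
        spec = tiny_spec(flavour="ablup")
        res1 = solve_mme(assemble_mme(phen, make_pedigree(rows), spec))
        rows2 = rows + [("z", "0", "0", "F", 2003)]
        res2 = solve_mme(assemble_mme(phen, make_pedigree(rows2), spec))
        for a in ("s", "d", "o"):
            assert res1.ebv.loc[a].to_numpy() == pytest.approx(
                res2.ebv.loc[a].to_numpy(), abs=1e-10)
        assert abs(res2.ebv.loc["z"].to_numpy()).max() < 1e-10

    def test_constant_shift_of_one_level_absorbed(self, small_herd, small_spec):
        res1 = evaluate_herd(small_herd, small_spec)
        phen = small_herd.phenotypes.copy()
        level = phen["hys"].iloc[0]
        phen.loc[phen["hys"] == level, "value"] += 100.0
        shifted = dataclasses.replace(small_herd, phenotypes=phen)
        res2 = evaluate_herd(shifted, small_spec)
        assert np.abs(res1.ebv.to_numpy() - res2.ebv.to_numpy()).max() < 1e-3


class TestGeneticGroups:
    def test_no_data_animal_sits_at_group_mean(self):
        rows = []
        phen = []
        for i in range(8):
            rows.append((f"a{i}", "0", "0", "F", 2000))
            phen.append({"animal": f"a{i}", "parity": 1, "value": -1.0,
                         "hys": "H0", "farm_type": "FT0",
                         "calving_year": 2002})
        for i in range(8):
            rows.append((f"b{i}", "0", "0", "F", 2012))
            phen.append({"animal": f"b{i}", "parity": 1, "value": 1.0,
                         "hys": "H0", "farm_type": "FT0",
                         "calving_year": 2014})
        rows.append(("x", "0", "0", "F", 2012))   # no records
        ped = make_pedigree(rows)
        spec = tiny_spec(flavour="ablup", use_groups=True, group_bin_width=5)
        res = solve_mme(assemble_mme(pd.DataFrame(phen), ped, spec))
        gx = res.group_effects
        # x's phantom sire/dam groups are the late-bin groups
        late = [g for g in gx.index if g.endswith(("_2_sire", "_2_dam"))
                and g.startswith("G_F")]
        expected = gx.loc[late, "parity1"].mean()
        assert res.ebv.loc["x", "parity1"] == pytest.approx(expected, abs=1e-5)
        # shrinks toward the (positive) group mean, not zero
        assert res.ebv.loc["x", "parity1"] > 0.05


    def test_groups_with_single_step_runs(self, small_herd, small_config):
        spec = ModelSpec(G0=small_config.G0, R0=small_config.R0,
                         flavour="ssgblup", w_pg=0.5, use_groups=True)
        res = evaluate_herd(small_herd, spec)
        assert np.isfinite(res.ebv.to_numpy()).all()
        assert res.group_effects is not None

    def test_assemble_sssnpblup_wrapper(self, small_herd, small_config):
        from herdblup.model import assemble_sssnpblup
        spec = ModelSpec(G0=small_config.G0, R0=small_config.R0,
                         flavour="ablup")
        system = assemble_sssnpblup(small_herd.phenotypes,
                                    small_herd.pedigree, spec,
                                    small_herd.markers, small_herd.genotyped)
        assert system.spec.flavour == "sssnpblup"
        assert system.index.n_markers > 0


class TestEstimatorInterface:
    def test_fit_predict_roundtrip(self, small_herd, small_config):
        est = MixedModelEvaluator(G0=small_config.G0, R0=small_config.R0,
                                  flavour="ssgblup", w_pg=0.5)
        est.fit(small_herd)
        assert est.ebv_.shape == (small_herd.pedigree.n, 5)
        two = est.predict(small_herd.pedigree.ids[:2])
        assert list(two.index) == small_herd.pedigree.ids[:2]

    def test_get_set_params(self):
        est = MixedModelEvaluator(w_pg=0.3)
        assert est.get_params()["w_pg"] == 0.3
        est.set_params(w_pg=0.7, flavour="ablup")
        assert est.w_pg == 0.7 and est.flavour == "ablup"

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            MixedModelEvaluator().predict()
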