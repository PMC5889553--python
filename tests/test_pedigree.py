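"""Pedigree relationship machinery, REML and MME solutions."""

import numpy as np
import pandas as pd
import pytest

from gsduroc import (
    Pedigree,
    PedigreeBLUP,
    VarianceComponents,
    build_A,
    build_A_inverse,
    em_reml,
    solve_mme,
    split_train_validation,
)
from gsduroc.pedigree import _Spectral, wald_screen_fixed_effects

from conftest import random_pedigree


class TestRelationshipMatrix:
    def test_unrelated_founders_give_identity(self):
        ped = Pedigree(
            np.array(["a", "b", "c"], object),
            np.array(["0"] * 3, object),
            np.array(["0"] * 3, object),
        )
        assert np.array_equal(build_A(ped), np.eye(3))

    def test_textbook_relationships(self, small_pedigree):
        A = build_A(small_pedigree)
        i = {a: k for k, a in enumerate(small_pedigree.animal)}
        assert A[i["s1"], i["x"]] == 0.5  # parent-offspring
        assert A[i["x"], i["y"]] == 0.5  # full sibs
        assert A[i["x"], i["z"]] == 0.0  # unrelated
        # offspring of unrelated parents is not inbred
        assert A[i["x"], i["x"]] == 1.0

    def test_inbred_diagonal(self):
        # mating a sire to his own daughter: F = 0.25
        ped = Pedigree.from_frame(
            pd.DataFrame(
                {
                    "animal": ["s", "d", "x", "k"],
                    "sire": ["0", "0", "s", "s"],
                    "dam": ["0", "0", "d", "x"],
                }
            )
        )
        A = build_A(ped)
        assert A[3, 3] == pytest.approx(1.25)

    def test_sparse_inverse_matches_dense_inverse(self):
        rng = np.random.default_rng(5)
        ped = random_pedigree(50, rng)
        A = build_A(ped)
        Ainv = build_A_inverse(ped).toarray()
        assert np.max(np.abs(Ainv - np.linalg.inv(A))) < 1e-8
        assert np.max(np.abs(A @ Ainv - np.eye(50))) < 1e-8

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(ValueError, match="cycl|sorted"):
            Pedigree.from_frame(
                pd.DataFrame(
                    {"animal": ["a", "b"], "sire": ["b", "a"], "dam": ["0", "0"]}
                )
            )

    def test_unknown_parent_rejected_when_not_listed(self):
        with pytest.raises(ValueError, match="not in pedigree"):
            Pedigree(
                np.array(["a"], object), np.array(["ghost"], object), np.array(["0"], object)
            )


class TestEmReml:
    def test_pure_noise_unrelated_animals_hits_boundary(self):
        rng = np.random.default_rng(0)
        n = 300
        y = rng.normal(0, 1, n)
        vc = em_reml(y, np.ones((n, 1)), np.eye(n))
        # A = I makes a and e jointly unidentifiable, but the returned
        # components must still reproduce the phenotypic variance
        assert vc.sigma_a2 + vc.sigma_e2 == pytest.approx(np.var(y), rel=0.1)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(1)
        ped = random_pedigree(120, rng, n_founders=20)
        A = build_A(ped)
        g = rng.multivariate_normal(np.zeros(120), A)
        y = g + rng.normal(0, 1, 120)
        vc1 = em_reml(y, np.ones((120, 1)), A)
        vc2 = em_reml(y + 100.0, np.ones((120, 1)), A)
        assert vc1.sigma_a2 == pytest.approx(vc2.sigma_a2, rel=1e-4)
        assert vc1.sigma_e2 == pytest.approx(vc2.sigma_e2, rel=1e-4)

    def test_returned_components_are_a_local_optimum(self):
        # seed chosen to give an interior (non-boundary) REML optimum
        rng = np.random.default_rng(1)
        ped = random_pedigree(20, rng, n_founders=8)
        A = build_A(ped)
        y = rng.multivariate_normal(np.zeros(20), 0.6 * A + 0.4 * np.eye(20))
        X = np.ones((20, 1))
        vc = em_reml(y, X, A)
        sp = _Spectral(y, X, A)
        base = sp.loglik_reml(vc.sigma_a2, vc.sigma_e2)
        for fa, fe in [(1.1, 1.0), (0.9, 1.0), (1.0, 1.1), (1.0, 0.9), (1.1, 0.9)]:
            assert base >= sp.loglik_reml(vc.sigma_a2 * fa, vc.sigma_e2 * fe) - 1e-9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            em_reml(np.ones(10), np.ones((10, 1)), np.eye(10))


class TestSolveMme:
    def test_matches_dense_gls_blup(self):
        """Henderson MME equals V^-1-based GLS BLUP on a 30-animal pedigree."""
        rng = np.random.default_rng(7)
        ped = random_pedigree(30, rng)
        A = build_A(ped)
        ids = ped.animal
        y = rng.normal(0, 1, 30)
        X = np.column_stack([np.ones(30), rng.normal(0, 1, 30)])
        vc = VarianceComponents(0.7, 0.3)
        sol = solve_mme(y, X, ids, ped, vc)
        V = 0.7 * A + 0.3 * np.eye(30)
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        a = 0.7 * A @ Vi @ (y - X @ b)
        assert np.max(np.abs(sol.b_hat - b)) < 1e-8
        assert np.max(np.abs(sol.ebv.to_numpy() - a)) < 1e-8

    def test_single_record_shrinkage_identity(self):
        """One founder, y = mu + a + e with mu known: EBV = h2 (y - mu)."""
        ped = Pedigree(np.array(["f"], object), np.array(["0"], object), np.array(["0"], object))
        y = np.array([3.0])
        vc = VarianceComponents(0.4, 0.6)  # h2 = 0.4
        # known mu=1 absorbed by offsetting y; no fixed effects estimated
        sol = solve_mme(y - 1.0, np.zeros((1, 0)), np.array(["f"], object), ped, vc)
        assert sol.ebv["f"] == pytest.approx(0.4 * (3.0 - 1.0))

    def test_masked_terminal_animal_gets_parent_average(self):
        rng = np.random.default_rng(3)
        ped = random_pedigree(40, rng, n_founders=10)
        # add a terminal masked animal with phenotyped parents
        ped = Pedigree(
            np.append(ped.animal, "term"),
            np.append(ped.sire, "a3"),
            np.append(ped.dam, "a7"),
        )
        y = rng.normal(0, 1, 41)
        ids = ped.animal
        mask = np.zeros(41, bool)
        mask[-1] = True
        vc = VarianceComponents(0.5, 0.5)
        sol = solve_mme(y, np.ones((41, 1)), ids, ped, vc, mask=mask)
        assert sol.ebv["term"] == pytest.approx(
            0.5 * (sol.ebv["a3"] + sol.ebv["a7"]), abs=1e-10
        )

    def test_no_genetic_variance_zeroes_ebv(self):
        rng = np.random.default_rng(4)
        ped = random_pedigree(15, rng)
        y = rng.normal(0, 1, 15)
        sol = solve_mme(
            y, np.ones((15, 1)), ped.animal, ped, VarianceComponents(0.0, 1.0)
        )
        assert np.all(sol.ebv.to_numpy() == 0)

    def test_h2_one_no_fixed_effects_gives_centred_phenotypes(self):
        """With h2 -> 1, one record each, EBV approaches y - ybar."""
        rng = np.random.default_rng(8)
        ped = random_pedigree(25, rng, n_founders=25)
        y = rng.normal(0, 1, 25)
        sol = solve_mme(
            y, np.ones((25, 1)), ped.animal, ped, VarianceComponents(1.0, 1e-8)
        )
        assert np.allclose(sol.ebv.to_numpy(), y - y.mean(), atol=1e-5)

    def test_corrected_phenotype_identity(self):
        rng = np.random.default_rng(9)
        ped = random_pedigree(30, rng)
        y = rng.normal(0, 1, 30)
        X = np.column_stack([np.ones(30), rng.normal(0, 1, 30)])
        sol = solve_mme(y, X, ped.animal, ped, VarianceComponents(0.5, 0.5))
        yc = sol.corrected()
        assert np.max(np.abs(yc.to_numpy() - (y - X @ sol.b_hat))) < 1e-10


class TestSplitAndScreening:
    def test_split_partitions_by_birthdate(self):
        ped = Pedigree(
            np.array(["a", "b", "c"], object),
            np.array(["0"] * 3, object),
            np.array(["0"] * 3, object),
            birthdate=np.array([10, 20, 30]),
        )
        tr, va = split_train_validation(ped, 20)
        assert list(tr) == ["a"] and list(va) == ["b", "c"]
        tr, va = split_train_validation(ped, 100)
        assert len(va) == 0
        assert set(tr) | set(va) == {"a", "b", "c"}

    def test_fixed_effects_spec_builds_constrained_design(self):
        from gsduroc import FixedEffectsSpec

        ph = pd.DataFrame(
            {
                "cg": ["a", "a", "b", "b", "c", "c"],
                "machine": ["m0", "m1"] * 3,
                "age": [140.0, 150, 160, 145, 155, 165],
            }
        )
        spec = FixedEffectsSpec(factors=("cg", "machine"), covariates=("age",))
        X, slices = spec.build_design(ph)
        # intercept + 2 cg dummies + 1 machine dummy + centred age
        assert X.shape == (6, 5)
        assert np.allclose(X[:, 0], 1.0)
        assert abs(X[:, slices["age"]].sum()) < 1e-10
        assert np.linalg.matrix_rank(X) == 5

    def test_wald_screen_flags_real_and_null_covariates(self):
        rng = np.random.default_rng(11)
        ped = random_pedigree(200, rng, n_founders=40)
        x_real = rng.normal(0, 1, 200)
        x_null = rng.normal(0, 1, 200)
        y = 2.0 * x_real + rng.normal(0, 1, 200)
        X = np.column_stack([np.ones(200), x_real, x_null])
        sol = solve_mme(y, X, ped.animal, ped, VarianceComponents(0.3, 0.7))
        res = wald_screen_fixed_effects(
            sol, {"real": slice(1, 2), "null": slice(2, 3)}
        )
        assert res["real"]["keep"]
        assert not res["null"]["keep"]


class TestPedigreeBlupEstimator:
    def test_sklearn_param_interface(self):
        est = PedigreeBLUP(sigma_a2=1.0, sigma_e2=2.0)
        assert est.get_params()["sigma_a2"] == 1.0
        est.set_params(sigma_e2=3.0)
        assert est.sigma_e2 == 3.0

    def test_fit_predict_roundtrip(self, small_pedigree):
        rng = np.random.default_rng(12)
        y = rng.normal(0, 1, 7)
        est = PedigreeBLUP(sigma_a2=0.5, sigma_e2=0.5).fit(
            None, y, pedigree=small_pedigree, pheno_ids=small_pedigree.animal
        )
        assert est.predict(["x"]).shape == (1,)
        assert est.h2_ == pytest.approx(0.5)
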