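"""Matrix builders: A^-1, G, H^-1, ZZ', and the MME coefficient operator."""

import numpy as np
import pytest
import scipy.sparse as sp

import mclogdet as mc
from mclogdet.operators import HInvOperator, MMEOperator, RandomEffect


class TestAinv:
    def test_single_founder(self):
        ped = mc.Pedigree(sire=np.array([0]), dam=np.array([0]))
        ainv, d = mc.ainv_build(ped)
        assert np.allclose(ainv.toarray(), [[1.0]])
        assert np.allclose(d, [1.0])

    def test_trio_known_values(self, trio_ped):
        ainv, d = mc.ainv_build(trio_ped)
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        assert np.allclose(ainv.toarray(), expected)
        assert np.allclose(d, [1.0, 1.0, 0.5])

    def test_inverts_tabular_a(self, ped200):
        A = mc.tabular_relationship(ped200)
        ainv, _ = mc.ainv_build(ped200)
        assert np.abs(ainv.toarray() @ A - np.eye(ped200.n)).max() < 1e-8

    def test_without_inbreeding_flag(self, ped200):
        _, d = mc.ainv_build(ped200, with_inbreeding=False)
        non = ~ped200.is_founder
        assert np.allclose(d[non], 0.5)
        assert np.allclose(d[~non], 1.0)

    def test_meuwissen_luo_matches_tabular_diagonal(self, ped200):
        A = mc.tabular_relationship(ped200)
        F = ped200.inbreeding()
        assert np.allclose(1.0 + F, np.diag(A), atol=1e-10)


class TestLogdetA:
    def test_single_founder_zero(self):
        ped = mc.Pedigree(sire=np.array([0]), dam=np.array([0]))
        assert mc.logdet_a(ped) == 0.0

    def test_trio(self, trio_ped):
        assert np.isclose(mc.logdet_a(trio_ped), np.log(0.5))

    def test_matches_dense_factorization(self, ped200):
        A = mc.tabular_relationship(ped200)
        _, ld = np.linalg.slogdet(A)
        assert abs(mc.logdet_a(ped200) - ld) < 1e-10


class TestG:
    def test_single_heterozygote_blends_to_a22(self):
        geno = mc.GenotypeSet(ids=np.array([1]), matrix=np.array([[1]]))
        a22 = np.array([[1.0]])
        assert geno.freqs[0] == 0.5
        g = mc.g_build(geno, blend_weight=0.05, a22=a22)
        assert np.allclose(g, 0.05 * a22)

    def test_identical_rows_give_identical_relationships(self):
        rng = np.random.default_rng(0)
        Z = rng.integers(0, 3, size=(6, 40))
        Z[3] = Z[0]
        geno = mc.GenotypeSet(ids=np.arange(1, 7), matrix=Z)
        G = mc.g_build(geno, blend_weight=0.0)
        assert np.allclose(G[0], G[3])

    def test_mean_diagonal_near_one(self):
        spec = mc.SimSpec(n_founders=50, n_generations=2, n_offspring=50,
                          n_snp=5000, prop_genotyped=1.0, seed=13)
        ped = mc.simulate_pedigree(spec)
        geno = mc.simulate_genotypes(ped, spec)
        G = mc.g_build(geno, blend_weight=0.0)
        # diagonal averages 1 + f-like deviation; loose Monte Carlo band
        assert abs(np.diag(G).mean() - 1.0) < 0.1

    def test_monomorphic_error(self):
        geno = mc.GenotypeSet(ids=np.array([1, 2]), matrix=np.zeros((2, 4), int))
        with pytest.raises(ValueError, match="monomorphic"):
            mc.g_build(geno, blend_weight=0.0)


class TestHinv:
    def test_no_genotypes_reduces_to_ainv(self, ped200):
        hop = mc.hinv_operator(ped200, None)
        ainv, _ = mc.ainv_build(ped200)
        assert (hop.explicit_sparse() != ainv).nnz == 0

    def test_g_equal_a22_reduces_to_ainv(self, ped200):
        """With G := A22 the genotyped-block correction vanishes."""
        ainv, _ = mc.ainv_build(ped200)
        idx = np.arange(ped200.n - 30, ped200.n)
        hop = HInvOperator(ainv, idx, np.zeros((30, 30)))
        v = np.random.default_rng(1).standard_normal(ped200.n)
        assert np.allclose(hop.matvec(v), ainv @ v)

    def test_explicit_matches_partitioned_identity(self):
        """H^-1 inverts the H assembled from the partitioned-block product."""
        spec = mc.SimSpec(n_founders=20, n_generations=2, n_offspring=15,
                          n_snp=80, prop_genotyped=0.4, seed=17)
        ped = mc.simulate_pedigree(spec)
        geno = mc.simulate_genotypes(ped, spec)
        hop = mc.hinv_operator(ped, geno)
        n = ped.n
        gidx = geno.ids - 1
        nidx = np.setdiff1d(np.arange(n), gidx)
        perm = np.concatenate([nidx, gidx])
        ainv, _ = mc.ainv_build(ped)
        a_inv = ainv.toarray()[np.ix_(perm, perm)]
        n1 = nidx.size
        A11 = a_inv[:n1, :n1]
        A12 = a_inv[:n1, n1:]
        A21 = a_inv[n1:, :n1]
        G = mc.g_build(geno, 0.05, ped.relationship_subset(geno.ids))
        A11i = np.linalg.inv(A11)
        upper = np.block([[A11i, -A11i @ A12], [np.zeros((n - n1, n1)), np.eye(n - n1)]])
        mid = np.block([[A11, np.zeros((n1, n - n1))],
                        [np.zeros((n - n1, n1)), G]])
        lower = np.block([[A11i, np.zeros((n1, n - n1))],
                          [-A21 @ A11i, np.eye(n - n1)]])
        H = upper @ mid @ lower
        hinv = hop.explicit_sparse().toarray()[np.ix_(perm, perm)]
        assert np.abs(hinv @ H - np.eye(n)).max() < 1e-7

    def test_singular_blend_raises(self):
        # more animals than loci and no blending -> singular G
        rng = np.random.default_rng(3)
        Z = rng.integers(0, 3, size=(10, 3))
        ped = mc.Pedigree(sire=np.zeros(10, int), dam=np.zeros(10, int))
        geno = mc.GenotypeSet(ids=np.arange(1, 11), matrix=Z)
        with pytest.raises(ValueError, match="singular"):
            mc.hinv_operator(ped, geno, blend_weight=0.0)


class TestZZt:
    def test_identity_content(self):
        geno = mc.GenotypeSet(ids=np.arange(1, 4), matrix=2 * np.eye(3, dtype=int))
        op = mc.zzt_operator(geno, side="ZZt", center=False)
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(op.matvec(v), 4.0 * v)

    @pytest.mark.parametrize("side", ["ZZt", "ZtZ"])
    def test_matches_explicit_product(self, side):
        rng = np.random.default_rng(5)
        Z = rng.integers(0, 3, size=(10, 20))
        geno = mc.GenotypeSet(ids=np.arange(1, 11), matrix=Z)
        op = mc.zzt_operator(geno, side=side)
        Zc = geno.centered()
        M = Zc @ Zc.T if side == "ZZt" else Zc.T @ Zc
        v = rng.standard_normal(op.n)
        assert np.allclose(op.matvec(v), M @ v, atol=1e-10)
        op.check_symmetry()

    def test_trace_probe_frobenius(self):
        rng = np.random.default_rng(6)
        Z = rng.integers(0, 3, size=(8, 12))
        geno = mc.GenotypeSet(ids=np.arange(1, 9), matrix=Z)
        op = mc.zzt_operator(geno, side="ZZt", center=False)
        tr = sum(op.matvec(np.eye(8)[:, i])[i] for i in range(8))
        assert np.isclose(tr, np.linalg.norm(Z.astype(float)) ** 2)


class TestMME:
    def test_fixed_effects_only(self):
        y = np.arange(4.0)
        X = sp.identity(4, format="csr")
        frame = mc.ModelFrame(y=y, X=X, effects=[], record_animal=np.arange(1, 5))
        C = mc.mme_operator(frame, {"residual": 0.5})
        assert np.allclose(C.explicit_sparse().toarray(), np.eye(4) / 0.5)

    def test_zero_residual_variance_raises(self, pedigree_frame):
        with pytest.raises(ValueError, match="residual"):
            mc.mme_operator(pedigree_frame, {"animal": 0.3, "residual": 0.0})

    def test_action_matches_explicit_on_basis(self, small_frame):
        C = mc.mme_operator(small_frame, {"animal": 0.3, "residual": 0.7})
        E = C.explicit_sparse().toarray()
        rng = np.random.default_rng(2)
        for j in rng.integers(0, C.n, size=12):
            e = np.zeros(C.n)
            e[j] = 1.0
            assert np.allclose(C.matvec(e), E[:, j], atol=1e-10)

    def test_symmetry_probes(self, small_frame):
        C = mc.mme_operator(small_frame, {"animal": 0.3, "residual": 0.7})
        C.check_symmetry(probes=20, seed=1)

    def test_complex_action_by_linearity(self, small_frame):
        C = mc.mme_operator(small_frame, {"animal": 0.3, "residual": 0.7})
        rng = np.random.default_rng(4)
        z = rng.standard_normal(C.n) + 1j * rng.standard_normal(C.n)
        out = C.matvec(z)
        assert np.allclose(out, C.matvec(z.real) + 1j * C.matvec(z.imag))

    def test_pe_effect_identity_block(self):
        spec = mc.SimSpec(n_founders=20, n_generations=2, n_offspring=20,
                          prop_genotyped=0.0, n_cg=4, seed=9,
                          true_varcomps={"animal": 0.3, "pe": 0.2, "residual": 0.5},
                          n_records_per_animal=3)
        frame = mc.simulate_dataset(spec)
        assert [e.name for e in frame.effects] == ["animal", "pe"]
        C = mc.mme_operator(frame, {"animal": 0.3, "pe": 0.2, "residual": 0.5})
        lo, hi = frame.block_offsets()["pe"]
        E = C.explicit_sparse().toarray()
        pe_block = E[lo:hi, lo:hi]
        th = frame.incidence()
        base = (th.T @ th).toarray()[lo:hi, lo:hi]
        assert np.allclose(pe_block, base / 0.5 + np.eye(hi - lo) / 0.2)


class TestSymmetricOperator:
    def test_symmetry_check_rejects_asymmetric(self):
        M = np.array([[1.0, 2.0], [0.0, 1.0]])
        op = mc.SymmetricOperator.from_matrix(M)
        with pytest.raises(ValueError, match="symmetry"):
            op.check_symmetry()

    def test_real_only_callable_wrapping(self):
        M = np.diag([1.0, 2.0, 3.0])
        op = mc.SymmetricOperator.from_callable(
            3, lambda v: M @ np.asarray(v, dtype=float), real_only=True
        )
        z = np.array([1 + 2j, 0.5 - 1j, -1 + 0j])
        assert np.allclose(op.matvec(z), M @ z)

    def test_nonfinite_output_raises(self):
        op = mc.SymmetricOperator(2, lambda v: v * np.nan)
        with pytest.raises(FloatingPointError):
            op.matvec(np.ones(2))
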