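"""Contour quadrature, Hutchinson estimator and the exact LDL' reference."""

import numpy as np
import pytest

import mclogdet as mc
from mclogdet.eigenbounds import SpectrumBounds, lanczos_extremes
from mclogdet.logdet import _probe
from conftest import random_spd


def logm_apply(M, v):
    w, V = np.linalg.eigh(M)
    return V @ (np.log(w) * (V.T @ v))


class TestLogMatvec:
    def test_identity_gives_zero(self):
        op = mc.SymmetricOperator.from_matrix(np.eye(30))
        b = lanczos_extremes(op, 10, seed=0).widened()
        v = np.random.default_rng(0).standard_normal(30)
        out = mc.log_matvec(op, v, b)
        assert np.linalg.norm(out) <= 1e-8 * np.linalg.norm(v)

    def test_diagonal_closed_form(self):
        d = np.array([0.2, 1.0, 4.0, 9.0, 25.0])
        op = mc.SymmetricOperator.from_matrix(np.diag(d))
        bounds = SpectrumBounds(d[0], d[-1], 0.0, 0.0)
        v = np.array([1.0, -2.0, 0.3, 5.0, -0.7])
        cfg = mc.ApproxConfig(n_int=10, inner_solver="direct")
        out = mc.log_matvec(op, v, bounds, cfg)
        ref = np.log(d) * v
        assert np.abs(out - ref).max() < 1e-6 * max(1.0, np.abs(ref).max())

    @pytest.mark.parametrize("kappa", [1e2, 1e4])
    def test_random_spd_matches_eigendecomposition(self, kappa):
        M = random_spd(50, kappa, seed=1)
        op = mc.SymmetricOperator.from_matrix(M)
        w = np.linalg.eigvalsh(M)
        bounds = SpectrumBounds(w[0], w[-1], 0.0, 0.0)
        v = np.random.default_rng(2).standard_normal(50)
        n_int = 10 if kappa <= 1e2 else 16
        cfg = mc.ApproxConfig(n_int=n_int, inner_solver="direct")
        out = mc.log_matvec(op, v, bounds, cfg)
        ref = logm_apply(M, v)
        assert np.linalg.norm(out - ref) / np.linalg.norm(ref) < 1e-6

    def test_quadrature_error_decays_geometrically(self):
        """Each +2 nodes shrinks the error until roundoff, up to kappa=1e4."""
        M = random_spd(60, 1e4, seed=3)
        op = mc.SymmetricOperator.from_matrix(M)
        w = np.linalg.eigvalsh(M)
        bounds = SpectrumBounds(w[0], w[-1], 0.0, 0.0)
        v = np.random.default_rng(4).standard_normal(60)
        ref = logm_apply(M, v)
        errs = []
        for n_int in (6, 8, 10, 12, 14, 16):
            cfg = mc.ApproxConfig(n_int=n_int, inner_solver="direct")
            out = mc.log_matvec(op, v, bounds, cfg)
            errs.append(np.linalg.norm(out - ref) / np.linalg.norm(ref))
        for a, b in zip(errs, errs[1:]):
            assert b < a or a < 1e-12

    def test_nonpositive_bounds_rejected(self):
        op = mc.SymmetricOperator.from_matrix(np.eye(3))
        with pytest.raises(ValueError, match="shift"):
            mc.log_matvec(op, np.ones(3), SpectrumBounds(-0.1, 1.0, 0, 0))


class TestHutchinson:
    def test_identity_exact_zero(self):
        op = mc.SymmetricOperator.from_matrix(np.eye(25))
        est = mc.hutchinson_logdet(op, mc.ApproxConfig(n_samples=3, n_lanczos=5))
        assert abs(est.value) < 1e-8
        assert est.sd < 1e-8

    def test_diagonal_each_sample_exact(self):
        """Rademacher entries square to one, so v'log(D)v = sum log d_i."""
        d = np.linspace(0.5, 9.5, 80)
        op = mc.SymmetricOperator.from_matrix(np.diag(d))
        cfg = mc.ApproxConfig(n_samples=5, n_int=14, inner_solver="direct")
        est = mc.hutchinson_logdet(op, cfg)
        assert np.allclose(est.per_sample, np.sum(np.log(d)), atol=1e-6)
        assert est.sd < 1e-6

    def test_unbiased_over_many_single_probe_runs(self):
        """Mean of 200 independent single-probe estimates hits the truth."""
        M = random_spd(100, 1e3, seed=5)
        op = mc.SymmetricOperator.from_matrix(M)
        exact = mc.exact_logdet_ldl(M)
        bounds = lanczos_extremes(op, 100, seed=0).widened()
        cfg0 = mc.ApproxConfig(n_samples=1, n_int=12, inner_solver="direct")
        vals = []
        for s in range(200):
            cfg = mc.ApproxConfig(n_samples=1, n_int=12, inner_solver="direct", seed=s)
            vals.append(mc.hutchinson_logdet(op, cfg, bounds=bounds).value)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - exact) < 3 * se

    def test_estimate_statistics_consistent(self):
        M = random_spd(60, 1e2, seed=6)
        op = mc.SymmetricOperator.from_matrix(M)
        est = mc.hutchinson_logdet(op, mc.ApproxConfig(n_samples=8, seed=1))
        assert np.isclose(est.value, est.per_sample.mean())
        assert np.isclose(est.sd, est.per_sample.std(ddof=1))

    def test_common_random_numbers_reproducible(self):
        M = random_spd(50, 1e2, seed=7)
        op = mc.SymmetricOperator.from_matrix(M)
        cfg = mc.ApproxConfig(n_samples=4, seed=9, reuse_probes=True)
        a = mc.hutchinson_logdet(op, cfg)
        b = mc.hutchinson_logdet(op, cfg)
        assert a.value == b.value
        assert np.array_equal(a.per_sample, b.per_sample)

    def test_fresh_probes_differ_without_reuse(self):
        M = random_spd(50, 1e2, seed=7)
        op = mc.SymmetricOperator.from_matrix(M)
        cfg = mc.ApproxConfig(n_samples=4, seed=9, reuse_probes=False)
        a = mc.hutchinson_logdet(op, cfg)
        b = mc.hutchinson_logdet(op, cfg)
        assert a.value != b.value

    def test_probe_is_pure_function_of_seed_and_index(self):
        assert np.array_equal(_probe(3, 5, 100), _probe(3, 5, 100))
        assert not np.array_equal(_probe(3, 5, 100), _probe(3, 6, 100))

    def test_scale_equivariance_within_reported_sd(self):
        """logdet(cM) = logdet(M) + n log c for the full approximate path."""
        M = random_spd(120, 1e3, seed=8)
        op1 = mc.SymmetricOperator.from_matrix(M)
        op2 = mc.SymmetricOperator.from_matrix(3.0 * M)
        cfg = mc.ApproxConfig(n_samples=10, seed=2)
        e1 = mc.hutchinson_logdet(op1, cfg)
        e2 = mc.hutchinson_logdet(op2, cfg)
        shift = 120 * np.log(3.0)
        tol = 3 * np.hypot(e1.se, e2.se) + 1e-6
        assert abs((e2.value - e1.value) - shift) < tol


class TestExactLogdet:
    def test_identity(self):
        assert mc.exact_logdet_ldl(np.eye(17)) == 0.0

    def test_rank_one_all_ones(self):
        assert np.isclose(mc.exact_logdet_ldl(np.ones((2, 2))), np.log(2.0))

    @pytest.mark.parametrize("rank", [40, 70])
    def test_pseudo_determinant_known_nullspace(self, rank):
        rng = np.random.default_rng(10)
        B = rng.standard_normal((100, rank))
        M = B @ B.T  # PSD with rank-deficiency 100 - rank
        w = np.linalg.eigvalsh(M)
        ref = np.sum(np.log(w[w > 1e-8 * w[-1]]))
        assert abs(mc.exact_logdet_ldl(M) - ref) < 1e-8

    def test_indefinite_rejected(self):
        with pytest.raises(ValueError, match="indefinite"):
            mc.exact_logdet_ldl(np.diag([1.0, -1.0]))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            mc.exact_logdet_ldl(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_sparse_input(self):
        import scipy.sparse as sp

        M = sp.diags([2.0, 3.0, 4.0])
        assert np.isclose(mc.exact_logdet_ldl(M), np.log(24.0))


class TestHFromHinv:
    def test_zero(self):
        assert mc.logdet_h_from_hinv(0.0) == 0.0

    def test_small_dense_h(self):
        H = random_spd(20, 50, seed=11)
        Hinv = np.linalg.inv(H)
        assert np.isclose(
            mc.logdet_h_from_hinv(mc.exact_logdet_ldl(Hinv)),
            mc.exact_logdet_ldl(H),
            atol=1e-8,
        )

    def test_partitioned_identity_cross_check(self):
        """-log|H^-1| = -log|A11| + log|G| on a 50-animal fixture."""
        spec = mc.SimSpec(n_founders=20, n_generations=2, n_offspring=15,
                          n_snp=100, prop_genotyped=0.4, seed=12)
        ped = mc.simulate_pedigree(spec)
        geno = mc.simulate_genotypes(ped, spec)
        hop = mc.hinv_operator(ped, geno)
        lhs = mc.logdet_h_from_hinv(mc.exact_logdet_ldl(hop.explicit_sparse()))
        ainv, _ = mc.ainv_build(ped)
        gidx = geno.ids - 1
        nidx = np.setdiff1d(np.arange(ped.n), gidx)
        A11 = ainv.toarray()[np.ix_(nidx, nidx)]
        G = mc.g_build(geno, 0.05, ped.relationship_subset(geno.ids))
        rhs = -mc.exact_logdet_ldl(A11) + mc.exact_logdet_ldl(G)
        assert abs(lhs - rhs) < 1e-6

    def test_estimate_negation(self):
        M = random_spd(30, 10, seed=13)
        est = mc.hutchinson_logdet(mc.SymmetricOperator.from_matrix(M),
                                   mc.ApproxConfig(n_samples=3))
        neg = mc.logdet_h_from_hinv(est)
        assert neg.value == -est.value
        assert neg.sd == est.sd


class TestCost:
    def test_default_formula(self):
        assert mc.estimate_cost(mc.ApproxConfig(), 1.0) == 200 + 5 * 10 * 20

    def test_zero_samples_forbidden(self):
        with pytest.raises(ValueError):
            mc.ApproxConfig(n_samples=0)

    def test_doubling_n_int_doubles_sampling_term(self):
        base = mc.estimate_cost(mc.ApproxConfig(), 2.0)
        double = mc.estimate_cost(mc.ApproxConfig(n_int=20), 2.0)
        assert double - base == 2.0 * 5 * 10 * 20

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            mc.estimate_cost(mc.ApproxConfig(), 0.0)
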