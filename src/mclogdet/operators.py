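"""Pedigree, genomic and mixed-model matrices as explicit or matrix-free operators.

This module holds the package's core containers and the builders for the
matrices whose log-determinants the rest of the package estimates:

* ``Pedigree`` -- ordered animal/sire/dam triples, inbreeding coefficients and
  Mendelian sampling variances; Henderson's rules give the sparse inverse
  numerator relationship matrix A^-1 without ever forming A.
* ``GenotypeSet`` -- SNP allele counts (0/1/2) for a genotyped subset of the
  pedigree, from which the genomic relationship matrix G is built.
* ``ModelFrame`` -- phenotypes plus fixed/random incidence structure of a
  single-trait animal model y = Xb + sum_k W_k u_k + e.
* ``SymmetricOperator`` -- the matrix-free contract used by the Lanczos,
  COCG and contour-quadrature code: a dimension and a linear action on real
  or complex vectors.

All operators built here act on complex vectors by linearity (the underlying
data are real), which is what the shifted solves (w^2 I - M) z = v require.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "GenotypeSet",
    "RandomEffect",
    "ModelFrame",
    "SymmetricOperator",
    "ainv_build",
    "logdet_a",
    "tabular_relationship",
    "g_build",
    "hinv_operator",
    "HInvOperator",
    "zzt_operator",
    "mme_operator",
    "MMEOperator",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (bad ids, cycles)."""


@dataclass
class Pedigree:
    """Ordered pedigree with dense 1-based ids; 0 means unknown parent.

    Animal ``i`` (1-based) is row ``i - 1`` of ``sire``/``dam``.  Parents must
    precede offspring, which rules out cycles and lets every derived quantity
    be computed in a single forward pass.
    """

    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None

    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self.sire.shape != self.dam.shape or self.sire.ndim != 1:
            raise PedigreeError("sire and dam must be 1-d arrays of equal length")
        n = self.sire.size
        ids = np.arange(1, n + 1)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par < 0) or np.any(par > n):
                raise PedigreeError(f"{name} ids outside 0..{n}")
            if np.any(par >= ids):
                bad = int(ids[par >= ids][0])
                raise PedigreeError(
                    f"animal {bad}: {name} does not precede offspring "
                    "(pedigree must be sorted, cycles are impossible)"
                )

    @property
    def n(self) -> int:
        return self.sire.size

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == 0) & (self.dam == 0)

    # -- inbreeding and Mendelian sampling variances ------------------------

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficient F_i per animal (Meuwissen-Luo recursion).

        F_i = a_ii - 1 where a_ii is accumulated from the unit-triangular
        decomposition A = T D T': a_ii = sum_j T_ij^2 d_j over the ancestors
        j of i, with T_ij propagating halves up the pedigree.
        """
        if "F" in self._cache:
            return self._cache["F"]
        n = self.n
        sire, dam = self.sire, self.dam
        F = np.zeros(n)
        d = np.zeros(n)
        for i in range(n):
            s, m = sire[i], dam[i]
            Fs = F[s - 1] if s else -1.0
            Fd = F[m - 1] if m else -1.0
            d[i] = 0.5 - 0.25 * (Fs + Fd)
            if not s or not m:
                continue  # F stays 0 with an unknown parent
            # a_ii via lazy heap over the ancestor set only
            coeff: dict[int, float] = {i: 1.0}
            heap = [-i]
            a_ii = 0.0
            while heap:
                j = -heapq.heappop(heap)
                cj = coeff.pop(j, 0.0)
                if cj == 0.0:
                    continue
                a_ii += cj * cj * d[j]
                for p in (sire[j], dam[j]):
                    if p:
                        pj = p - 1
                        if pj in coeff:
                            coeff[pj] += 0.5 * cj
                        else:
                            coeff[pj] = 0.5 * cj
                            heapq.heappush(heap, -pj)
            F[i] = a_ii - 1.0
        self._cache["F"] = F
        self._cache["d_inbred"] = d
        return F

    def mendelian_variances(self, with_inbreeding: bool = True) -> np.ndarray:
        """Within-family (Mendelian sampling) variance d_i of each animal.

        d_i = 0.5 - 0.25 (F_s + F_d) with both parents known, using the
        convention F = -1 for an unknown parent (giving 0.75 with one known
        parent and 1 for founders).  |A| = prod_i d_i.
        """
        key = f"d_{with_inbreeding}"
        if key in self._cache:
            return self._cache[key]
        if with_inbreeding:
            self.inbreeding()
            d = self._cache["d_inbred"].copy()
        else:
            n_known = (self.sire > 0).astype(float) + (self.dam > 0).astype(float)
            d = 1.0 - 0.25 * n_known
        if np.any(d <= 0) or np.any(d > 1):
            raise PedigreeError("Mendelian sampling variances outside (0, 1]")
        self._cache[key] = d
        return d

    def tabular(self) -> np.ndarray:
        """Dense numerator relationship matrix A by the tabular method.

        Quadratic in pedigree size; intended for desk-scale reference use and
        for extracting the genotyped block A22.
        """
        if "A" in self._cache:
            return self._cache["A"]
        n = self.n
        A = np.zeros((n, n))
        sire, dam = self.sire, self.dam
        for i in range(n):
            s, m = sire[i], dam[i]
            row = np.zeros(i)
            if s:
                row += 0.5 * A[s - 1, :i]
            if m:
                row += 0.5 * A[m - 1, :i]
            A[i, :i] = row
            A[:i, i] = row
            a_sd = A[s - 1, m - 1] if (s and m) else 0.0
            A[i, i] = 1.0 + 0.5 * a_sd
        self._cache["A"] = A
        return A

    def relationship_subset(self, ids: Sequence[int]) -> np.ndarray:
        """A restricted to the given (1-based) animal ids, in the given order."""
        idx = np.asarray(ids, dtype=np.int64) - 1
        A = self.tabular()
        return A[np.ix_(idx, idx)]


@dataclass
class GenotypeSet:
    """SNP allele counts for the genotyped subset of a pedigree.

    ``ids`` are 1-based pedigree ids in the row order of ``matrix`` (values in
    {0, 1, 2}).  Allele frequencies default to the observed frequencies in
    the genotyped set itself.
    """

    ids: np.ndarray
    matrix: np.ndarray
    freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.ids.size:
            raise ValueError("genotype matrix must be n_geno x n_snp")
        if self.ids.size < 1:
            raise ValueError("need at least one genotyped animal")
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, [0, 1, 2])):
            raise ValueError("allele counts must be 0, 1 or 2")
        if self.freqs is None:
            self.freqs = self.matrix.mean(axis=0) / 2.0
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_geno(self) -> int:
        return self.ids.size

    @property
    def n_snp(self) -> int:
        return self.matrix.shape[1]

    def centered(self) -> np.ndarray:
        """Column-centered content matrix Z_c = Z - 2p."""
        return self.matrix.astype(float) - 2.0 * self.freqs


@dataclass
class RandomEffect:
    """One random effect: records-by-levels incidence and covariance kind."""

    name: str
    W: sp.csr_matrix
    kind: str = "pedigree"  # "pedigree" | "single-step" | "identity"

    def __post_init__(self) -> None:
        if self.kind not in ("pedigree", "single-step", "identity"):
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        self.W = sp.csr_matrix(self.W)

    @property
    def n_levels(self) -> int:
        return self.W.shape[1]


@dataclass
class ModelFrame:
    """Phenotypes and incidence structure of a single-trait mixed model.

    y = Xb + sum_k W_k u_k + e with Var(u_k) = sigma2_k K_k and
    Var(e) = I sigma2_e.  K_k is the pedigree relationship A, the single-step
    relationship H, or the identity, per the effect's ``kind``.
    """

    y: np.ndarray
    X: sp.csr_matrix
    effects: list[RandomEffect]
    record_animal: np.ndarray
    ped: Pedigree | None = None
    geno: GenotypeSet | None = None
    blend_weight: float = 0.05
    truth: dict | None = None  # simulated true effects, when known

    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = sp.csr_matrix(self.X)
        self.record_animal = np.asarray(self.record_animal, dtype=np.int64)
        n = self.y.size
        if self.X.shape[0] != n or self.record_animal.size != n:
            raise ValueError("X and record_animal must match the records")
        counts = np.asarray(self.X.sum(axis=0)).ravel()
        if np.any(counts == 0):
            raise ValueError("fixed-effect incidence has empty levels")
        for eff in self.effects:
            if eff.W.shape[0] != n:
                raise ValueError(f"effect {eff.name}: incidence rows != records")

    @property
    def n_records(self) -> int:
        return self.y.size

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_equations(self) -> int:
        return self.n_fixed + sum(e.n_levels for e in self.effects)

    def effect(self, name: str) -> RandomEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def incidence(self) -> sp.csr_matrix:
        """[X | W_1 | ... | W_K], fixed effects first (the equation order)."""
        if "theta" not in self._cache:
            self._cache["theta"] = sp.hstack(
                [self.X] + [e.W for e in self.effects], format="csr"
            )
        return self._cache["theta"]

    def normal_equations_base(self) -> sp.csr_matrix:
        """Theta' Theta -- the variance-free part of the MME coefficient matrix."""
        if "base" not in self._cache:
            th = self.incidence()
            self._cache["base"] = (th.T @ th).tocsr()
        return self._cache["base"]

    def rhs_base(self) -> np.ndarray:
        """Theta' y (scaled by 1/sigma2_e when the MME are formed)."""
        if "rhs" not in self._cache:
            self._cache["rhs"] = self.incidence().T @ self.y
        return self._cache["rhs"]

    def block_offsets(self) -> dict[str, tuple[int, int]]:
        """Equation index ranges: 'fixed' then each effect by name."""
        out = {"fixed": (0, self.n_fixed)}
        pos = self.n_fixed
        for e in self.effects:
            out[e.name] = (pos, pos + e.n_levels)
            pos += e.n_levels
        return out


# ---------------------------------------------------------------------------
# the matrix-free contract
# ---------------------------------------------------------------------------


class SymmetricOperator:
    """Symmetric linear operator: dimension + action on real/complex vectors.

    ``explicit`` optionally holds an assembled (sparse or dense) form for
    exact reference computations at desk scale; ``diag`` enables Jacobi
    preconditioning of shifted solves.
    """

    def __init__(
        self,
        n: int,
        matvec: Callable[[np.ndarray], np.ndarray],
        diag: np.ndarray | None = None,
        explicit=None,
        name: str = "operator",
    ):
        self.n = int(n)
        self._matvec = matvec
        self._diag = diag
        self.explicit = explicit
        self.name = name
        self.n_applications = 0

    @classmethod
    def from_matrix(cls, M, name: str = "matrix") -> "SymmetricOperator":
        if sp.issparse(M):
            M = M.tocsr()
            diag = M.diagonal()
        else:
            M = np.asarray(M)
            diag = np.diag(M).copy()
        return cls(M.shape[0], lambda v: M @ v, diag=diag, explicit=M, name=name)

    @classmethod
    def from_callable(
        cls,
        n: int,
        matvec: Callable[[np.ndarray], np.ndarray],
        diag: np.ndarray | None = None,
        real_only: bool = False,
        name: str = "callable",
    ) -> "SymmetricOperator":
        """Wrap a user matvec; ``real_only`` functions get complex support by
        linearity on real and imaginary parts."""
        if real_only:
            base = matvec

            def matvec(v: np.ndarray) -> np.ndarray:
                if np.iscomplexobj(v):
                    return base(v.real) + 1j * base(v.imag)
                return base(v)

        return cls(n, matvec, diag=diag, name=name)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v)
        if v.shape != (self.n,):
            raise ValueError(f"expected vector of length {self.n}")
        out = self._matvec(v)
        self.n_applications += 1
        if not np.all(np.isfinite(out)):
            raise FloatingPointError(f"{self.name}: non-finite operator output")
        return out

    def __matmul__(self, v: np.ndarray) -> np.ndarray:
        return self.matvec(v)

    @property
    def diag(self) -> np.ndarray | None:
        return self._diag

    def check_symmetry(self, probes: int = 5, seed: int = 0, rtol: float = 1e-8) -> float:
        """Max relative asymmetry |x'(My) - y'(Mx)| over random probe pairs."""
        rng = np.random.default_rng(seed)
        worst = 0.0
        for _ in range(probes):
            x = rng.standard_normal(self.n)
            y = rng.standard_normal(self.n)
            mx, my = self.matvec(x), self.matvec(y)
            scale = max(abs(x @ my), abs(y @ mx), 1e-300)
            worst = max(worst, abs(x @ my - y @ mx) / scale)
        if worst > rtol:
            raise ValueError(f"{self.name}: symmetry violated ({worst:.2e} > {rtol:.2e})")
        return worst

    def to_dense(self) -> np.ndarray:
        if self.explicit is not None:
            E = self.explicit
            return E.toarray() if sp.issparse(E) else np.asarray(E)
        eye = np.eye(self.n)
        return np.column_stack([self.matvec(eye[:, j]) for j in range(self.n)])


# ---------------------------------------------------------------------------
# pedigree operators
# ---------------------------------------------------------------------------


def ainv_build(
    ped: Pedigree, with_inbreeding: bool = True
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse A^-1 by Henderson's rules, plus the Mendelian variances d.

    Each animal contributes alpha_i = 1/d_i in the familiar pattern: alpha on
    its own diagonal, -alpha/2 to animal-parent pairs and alpha/4 among the
    known parents.
    """
    d = ped.mendelian_variances(with_inbreeding=with_inbreeding)
    alpha = 1.0 / d
    n = ped.n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    i = np.arange(n)
    s = ped.sire - 1  # -1 where unknown
    m = ped.dam - 1
    has_s = s >= 0
    has_m = m >= 0

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(i, i, alpha)
    for par, has in ((s, has_s), (m, has_m)):
        add(i[has], par[has], -0.5 * alpha[has])
        add(par[has], i[has], -0.5 * alpha[has])
        add(par[has], par[has], 0.25 * alpha[has])
    both = has_s & has_m
    add(s[both], m[both], 0.25 * alpha[both])
    add(m[both], s[both], 0.25 * alpha[both])

    ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return ainv, d


def logdet_a(ped: Pedigree, with_inbreeding: bool = True) -> float:
    """log|A| = sum_i log d_i (A factors as T D T' with unit-triangular T)."""
    d = ped.mendelian_variances(with_inbreeding=with_inbreeding)
    return float(np.sum(np.log(d)))


def tabular_relationship(ped: Pedigree) -> np.ndarray:
    """Dense A by the tabular method (reference/desk scale)."""
    return ped.tabular()


# ---------------------------------------------------------------------------
# genomic operators
# ---------------------------------------------------------------------------


def g_build(
    geno: GenotypeSet,
    blend_weight: float = 0.05,
    a22: np.ndarray | None = None,
) -> np.ndarray:
    """Genomic relationship G = Z_c Z_c' / (2 sum p(1-p)), blended with A22.

    The returned matrix is (1 - w) G + w A22 so that it is safely invertible
    for the single-step correction; ``blend_weight`` = 0 returns raw G.
    """
    if not 0.0 <= blend_weight < 1.0:
        raise ValueError("blend_weight must be in [0, 1)")
    p = geno.freqs
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0.0:
        raise ValueError("all loci are monomorphic: G denominator is zero")
    zc = geno.centered()
    G = (zc @ zc.T) / denom
    if blend_weight == 0.0:
        return G
    if a22 is None:
        raise ValueError("blending requires the pedigree block A22")
    a22 = np.asarray(a22)
    if a22.shape != G.shape:
        raise ValueError("A22 shape does not match the genotyped set")
    return (1.0 - blend_weight) * G + blend_weight * a22


class HInvOperator(SymmetricOperator):
    """Action of H^-1 = A^-1 + [0; G^-1 - A22^-1 on the genotyped block]."""

    def __init__(self, ainv: sp.csr_matrix, idx: np.ndarray, correction: np.ndarray,
                 name: str = "Hinv"):
        self.ainv = ainv
        self.idx = idx
        self.correction = correction
        n = ainv.shape[0]
        diag = ainv.diagonal().copy()
        if idx.size:
            diag[idx] += np.diag(correction)

        def mv(v: np.ndarray) -> np.ndarray:
            out = ainv @ v
            if idx.size:
                out = out.astype(np.result_type(out, correction @ v[idx]))
                out[idx] += correction @ v[idx]
            return out

        super().__init__(n, mv, diag=diag, name=name)

    def explicit_sparse(self) -> sp.csr_matrix:
        n = self.n
        corr = sp.coo_matrix(
            (
                self.correction.ravel(),
                (
                    np.repeat(self.idx, self.idx.size),
                    np.tile(self.idx, self.idx.size),
                ),
            ),
            shape=(n, n),
        )
        return (self.ainv + corr).tocsr()


def hinv_operator(
    ped: Pedigree,
    geno: GenotypeSet | None,
    blend_weight: float = 0.05,
    with_inbreeding: bool = True,
) -> HInvOperator:
    """Matrix-free H^-1 for single-step models.

    With no genotyped animals this is exactly A^-1.  Otherwise the genotyped
    block receives the dense correction G_b^-1 - A22^-1, where G_b is the
    blended genomic relationship and A22 the pedigree block (factorized at
    desk scale).
    """
    ainv, _ = ainv_build(ped, with_inbreeding=with_inbreeding)
    if geno is None or geno.n_geno == 0:
        return HInvOperator(ainv, np.empty(0, dtype=np.int64), np.empty((0, 0)))
    if np.any(geno.ids < 1) or np.any(geno.ids > ped.n):
        raise ValueError("genotyped ids must be a subset of pedigree ids")
    idx = geno.ids - 1
    a22 = ped.relationship_subset(geno.ids)
    gb = g_build(geno, blend_weight=blend_weight, a22=a22)
    try:
        gb_chol = np.linalg.cholesky(gb)
    except np.linalg.LinAlgError as exc:
        raise ValueError("blended G is singular; increase blend_weight") from exc
    gb_inv = np.linalg.inv(gb_chol.T) @ np.linalg.inv(gb_chol)
    a22_inv = np.linalg.inv(a22)
    correction = gb_inv - a22_inv
    correction = 0.5 * (correction + correction.T)
    op = HInvOperator(ainv, idx, correction)
    op._a22 = a22
    op._g_blended = gb
    return op


def zzt_operator(geno: GenotypeSet, side: str = "ZZt", center: bool = True) -> SymmetricOperator:
    """ZZ' (GBLUP) or Z'Z (SNP-BLUP) action without forming the product.

    The action is computed as Z (Z' v) or Z' (Z v); only Z itself is stored.
    """
    if side not in ("ZZt", "ZtZ"):
        raise ValueError("side must be 'ZZt' or 'ZtZ'")
    Z = geno.centered() if center else geno.matrix.astype(float)
    if side == "ZZt":
        n = Z.shape[0]
        mv = lambda v: Z @ (Z.T @ v)
        diag = np.einsum("ij,ij->i", Z, Z)
    else:
        n = Z.shape[1]
        mv = lambda v: Z.T @ (Z @ v)
        diag = np.einsum("ij,ij->j", Z, Z)
    return SymmetricOperator(n, mv, diag=diag, name=side)


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------


class MMEOperator(SymmetricOperator):
    """Coefficient matrix C of the mixed-model equations on the R^-1 scale.

    C = (1/sigma2_e) [X'X  X'W; W'X  W'W] + blockdiag(0, K_k^-1 / sigma2_k).
    Dense single-step corrections are kept separate from the sparse part and
    applied blockwise, so the action never assembles the dense block into the
    sparse structure unless ``explicit()`` is requested.
    """

    def __init__(self, sparse_part: sp.csr_matrix, corrections, name: str = "C"):
        self.sparse_part = sparse_part
        self.corrections = corrections  # list of (global row indices, dense block)
        diag = sparse_part.diagonal().copy()
        for idx, block in corrections:
            diag[idx] += np.diag(block)

        def mv(v: np.ndarray) -> np.ndarray:
            out = self.sparse_part @ v
            for idx, block in self.corrections:
                sub = block @ v[idx]
                out = out.astype(np.result_type(out, sub))
                out[idx] += sub
            return out

        super().__init__(sparse_part.shape[0], mv, diag=diag, name=name)

    def explicit_sparse(self) -> sp.csr_matrix:
        n = self.n
        out = self.sparse_part.copy()
        for idx, block in self.corrections:
            corr = sp.coo_matrix(
                (block.ravel(), (np.repeat(idx, idx.size), np.tile(idx, idx.size))),
                shape=(n, n),
            )
            out = out + corr
        return out.tocsr()


def _kinv_parts(frame: ModelFrame, eff: RandomEffect):
    """K^-1 for one effect as (sparse part, optional (idx, dense block))."""
    key = f"kinv_{eff.name}"
    if key in frame._cache:
        return frame._cache[key]
    if eff.kind == "identity":
        parts = (sp.identity(eff.n_levels, format="csr"), None)
    elif eff.kind == "pedigree":
        if frame.ped is None:
            raise ValueError(f"effect {eff.name}: pedigree kind needs frame.ped")
        ainv, _ = ainv_build(frame.ped)
        parts = (ainv, None)
    else:  # single-step
        if frame.ped is None or frame.geno is None:
            raise ValueError(f"effect {eff.name}: single-step needs ped and geno")
        hop = hinv_operator(frame.ped, frame.geno, blend_weight=frame.blend_weight)
        parts = (hop.ainv, (hop.idx, hop.correction))
    frame._cache[key] = parts
    return parts


def mme_operator(
    frame: ModelFrame,
    varcomps: Mapping[str, float],
    kinv_actions: Mapping[str, tuple] | None = None,
) -> MMEOperator:
    """Build the MME coefficient operator C for the given variance components.

    ``varcomps`` maps effect names to variances and must include
    ``"residual"``; equation order is fixed effects first, then each random
    effect's levels in ``frame.effects`` order.  ``kinv_actions`` may supply
    precomputed (sparse, dense-correction) pairs per effect.
    """
    sigma_e = float(varcomps["residual"])
    if sigma_e <= 0:
        raise ValueError("residual variance must be > 0")
    base = frame.normal_equations_base() / sigma_e
    offsets = frame.block_offsets()
    blocks: list[sp.spmatrix] = [sp.csr_matrix((frame.n_fixed, frame.n_fixed))]
    corrections = []
    for eff in frame.effects:
        sigma_k = float(varcomps[eff.name])
        if sigma_k <= 0:
            raise ValueError(f"variance for {eff.name} must be > 0")
        if kinv_actions is not None and eff.name in kinv_actions:
            kinv_sparse, dense_part = kinv_actions[eff.name]
        else:
            kinv_sparse, dense_part = _kinv_parts(frame, eff)
        blocks.append(kinv_sparse / sigma_k)
        if dense_part is not None:
            idx, block = dense_part
            lo, _ = offsets[eff.name]
            corrections.append((lo + idx, block / sigma_k))
    sparse_part = (base + sp.block_diag(blocks, format="csr")).tocsr()
    return MMEOperator(sparse_part, corrections)
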