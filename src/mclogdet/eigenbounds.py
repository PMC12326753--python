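"""Extreme eigenvalue estimation by Lanczos with full reorthogonalization.

The contour quadrature needs an interval [lambda_min, lambda_max] enclosing
the spectrum of the (positive definite) operator.  A Lanczos process with
full reorthogonalization builds a tridiagonal T whose extreme eigenvalues
(Ritz values) estimate the extremes of M from the inside; the reported Ritz
residual norms ||M x - lambda x|| quantify their convergence and drive the
safety margin applied before the contour is constructed.

When the iteration budget exceeds the basis budget the process restarts from
the current extreme Ritz vectors (a cheap implicit restart); extreme values
are combined monotonically across cycles, which preserves the interlacing
guarantee that Ritz values never leave the true spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .operators import SymmetricOperator

__all__ = ["SpectrumBounds", "lanczos_extremes"]


@dataclass(frozen=True)
class SpectrumBounds:
    """Estimated spectral interval of a symmetric positive definite operator."""

    lambda_min: float
    lambda_max: float
    residual_min: float  # ||M x - lambda x|| for the smallest Ritz pair
    residual_max: float
    n_matvec: int = 0

    @property
    def condition(self) -> float:
        """Condition-number estimate kappa = lambda_max / lambda_min."""
        return self.lambda_max / self.lambda_min

    def widened(self, floor_factor: float = 1e-10) -> "SpectrumBounds":
        """Safety-widened interval for contour construction.

        Ritz values lie inside the true spectrum, so the quadrature contour
        must be pushed outward by at least the residual norms; a relative
        floor keeps the margin nonzero even for fully converged pairs.  The
        lower end is clamped to stay positive (the operator is assumed
        numerically positive definite).
        """
        margin_lo = max(self.residual_min, floor_factor * self.lambda_max)
        margin_hi = max(self.residual_max, floor_factor * self.lambda_max)
        lo = self.lambda_min - margin_lo
        if lo <= 0.0:
            lo = 0.01 * self.lambda_min
        return SpectrumBounds(
            lambda_min=lo,
            lambda_max=self.lambda_max + margin_hi,
            residual_min=self.residual_min,
            residual_max=self.residual_max,
            n_matvec=self.n_matvec,
        )


def _rademacher(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 2, size=n) * 2.0 - 1.0


def _lanczos_cycle(op, v0, steps):
    """One Lanczos sweep with full reorthogonalization.

    Returns (ritz values, ritz vectors for the two extremes, residuals,
    matvecs used).  Stops early on breakdown (invariant subspace found).
    """
    n = op.n
    steps = min(steps, n)
    V = np.zeros((steps, n))
    alphas: list[float] = []
    betas: list[float] = []
    v = v0 / np.linalg.norm(v0)
    used = 0
    j = 0
    while j < steps:
        V[j] = v
        w = op.matvec(v)
        used += 1
        a = float(v @ w)
        alphas.append(a)
        w = w - a * v
        if j > 0:
            w = w - betas[-1] * V[j - 1]
        # full reorthogonalization against the whole basis (twice is enough)
        for _ in range(2):
            w = w - V[: j + 1].T @ (V[: j + 1] @ w)
        beta = float(np.linalg.norm(w))
        j += 1
        if j == steps or beta <= 1e-13 * max(1.0, abs(a)):
            break
        betas.append(beta)
        v = w / beta
    T_alphas = np.array(alphas)
    T_betas = np.array(betas[: len(alphas) - 1])
    if len(alphas) == 1:
        theta = T_alphas
        S = np.ones((1, 1))
    else:
        theta, S = sla.eigh_tridiagonal(T_alphas, T_betas)
    basis = V[: len(alphas)]
    x_min = basis.T @ S[:, 0]
    x_max = basis.T @ S[:, -1]
    return theta, x_min, x_max, used


def lanczos_extremes(
    op: SymmetricOperator,
    n_lanczos: int = 200,
    seed: int = 0,
    basis_size: int | None = None,
) -> SpectrumBounds:
    """Estimate the extreme eigenvalues of ``op``.

    ``n_lanczos`` is the total matrix-vector budget; ``basis_size`` caps the
    orthogonal basis per cycle (default: no restart within the budget).  The
    start vector is Rademacher drawn from ``seed`` for reproducibility.
    """
    if n_lanczos < 2:
        raise ValueError("need at least 2 Lanczos iterations")
    rng = np.random.default_rng(seed)
    if basis_size is None:
        basis_size = n_lanczos
    basis_size = max(2, min(basis_size, op.n))

    lam_min = np.inf
    lam_max = -np.inf
    x_for_min = x_for_max = None
    used_total = 0
    v0 = _rademacher(rng, op.n)
    while used_total < n_lanczos:
        steps = min(basis_size, n_lanczos - used_total)
        if steps < 2:
            break
        theta, x_min, x_max, used = _lanczos_cycle(op, v0, steps)
        used_total += used
        if theta[0] < lam_min:
            lam_min = float(theta[0])
            x_for_min = x_min
        if theta[-1] > lam_max:
            lam_max = float(theta[-1])
            x_for_max = x_max
        if used < steps or used_total >= n_lanczos:
            break  # breakdown: Krylov space exhausted, estimates are exact
        # restart from the current extreme Ritz vectors
        v0 = x_for_min + x_for_max
        if np.linalg.norm(v0) < 1e-12:
            v0 = _rademacher(rng, op.n)

    def _residual(x, lam):
        x = x / np.linalg.norm(x)
        return float(np.linalg.norm(op.matvec(x) - lam * x))

    res_min = _residual(x_for_min, lam_min)
    res_max = _residual(x_for_max, lam_max)
    used_total += 2
    return SpectrumBounds(
        lambda_min=lam_min,
        lambda_max=lam_max,
        residual_min=res_min,
        residual_max=res_max,
        n_matvec=used_total,
    )
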