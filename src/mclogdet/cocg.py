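"""Conjugate Orthogonal Conjugate Gradient solves of complex symmetric systems.

Each quadrature node of the contour integral requires the solution of
(w^2 I - M) z = v with a complex shift w^2 and a real symmetric M.  The
shifted matrix is complex *symmetric* (A^T = A) but not Hermitian, so the
appropriate short-recurrence Krylov method is COCG (van der Vorst &
Melissen): the classical CG recurrences with every inner product replaced by
the unconjugated bilinear form r^T r.  On real SPD data COCG reduces exactly
to CG.

COCG minimizes nothing, so the residual is not monotone; the solver reports
the final *recomputed* relative residual together with the full trace.
Bilinear-form breakdown (r^T z ~ 0 or p^T A p ~ 0) is flagged in the report
rather than raised, because a capped, slightly unconverged solve is still a
usable quadrature term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SolveReport", "cocg_solve"]


@dataclass
class SolveReport:
    """Outcome of one COCG solve."""

    solution: np.ndarray
    iterations: int
    relative_residual: float  # recomputed from the returned solution
    converged: bool
    breakdown: bool = False
    trace: list = field(default_factory=list)  # recurrence residual norms


def cocg_solve(
    shifted_apply,
    b: np.ndarray,
    max_iter: int = 20,
    tol: float = 1e-8,
    preconditioner: np.ndarray | None = None,
) -> SolveReport:
    """Solve A z = b for complex symmetric A given as a callable.

    ``preconditioner`` is the diagonal of A (Jacobi); pass None for no
    preconditioning.  Stops at the relative-residual tolerance or at
    ``max_iter`` operator applications, whichever comes first.
    """
    b = np.asarray(b, dtype=complex)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        raise ValueError("right-hand side must be nonzero")
    if preconditioner is not None:
        pinv = 1.0 / np.asarray(preconditioner, dtype=complex)
        if not np.all(np.isfinite(pinv)):
            pinv = None
    else:
        pinv = None

    x = np.zeros_like(b)
    r = b.copy()
    p = np.zeros_like(b)
    rho_prev = 0.0 + 0.0j
    trace: list[float] = []
    breakdown = False
    it = 0
    tiny = np.finfo(float).tiny

    for it in range(1, max_iter + 1):
        z = pinv * r if pinv is not None else r
        rho = np.dot(r, z)  # unconjugated bilinear form
        if abs(rho) < tiny * max(1.0, np.linalg.norm(r) ** 2):
            breakdown = True
            break
        if it == 1:
            p = z.copy()
        else:
            p = z + (rho / rho_prev) * p
        q = shifted_apply(p)
        sigma = np.dot(p, q)
        if abs(sigma) < tiny * max(1.0, np.linalg.norm(p) * np.linalg.norm(q)):
            breakdown = True
            break
        alpha = rho / sigma
        x = x + alpha * p
        r = r - alpha * q
        rho_prev = rho
        res = np.linalg.norm(r) / bnorm
        trace.append(float(res))
        if res < tol:
            break

    true_res = float(np.linalg.norm(b - shifted_apply(x)) / bnorm)
    return SolveReport(
        solution=x,
        iterations=it,
        relative_residual=true_res,
        converged=(true_res <= tol) and not breakdown,
        breakdown=breakdown,
        trace=trace,
    )
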