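"""Restricted likelihood with pluggable log-determinant backends, and REML.

The single-trait restricted likelihood is evaluated in mixed-model-equation
form, dropping additive constants that do not depend on the variance
components:

    -2 log L_r = n log sigma2_e + sum_k [ q_k log sigma2_k + log|K_k| ]
                 + log|C| + y'Py

with C the MME coefficient matrix on the R^-1 = I/sigma2_e scale.  This
equals the V-based definition log|V| + log|X'V^-1 X| + y'Py exactly (the
Henderson/Harville identity), which the test suite checks on dense fixtures.

Backends: ``exact`` computes log|C| (and log|H| = -log|H^-1| where needed)
by LDL' factorization; ``approximate`` uses the Hutchinson contour-quadrature
estimator, with the probe sequence shared across evaluations (common random
numbers) so that Monte Carlo noise largely cancels when likelihoods are
compared along a profile or inside an optimizer.

log|A| is always exact -- it is the sum of log Mendelian sampling variances
and costs a single pedigree pass.

Estimation: ``df_reml_powell`` minimizes -2 log L_r over log-variances with
Powell's derivative-free direction-set method; ``em_reml_reference`` is the
classical expectation-maximization REML (dense, desk scale) used to validate
the derivative-free path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.optimize as opt
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .logdet import ApproxConfig, exact_logdet_ldl, hutchinson_logdet
from .operators import ModelFrame, ainv_build, hinv_operator, logdet_a, mme_operator

__all__ = [
    "VarComps",
    "LikelihoodValue",
    "restricted_m2ll",
    "ypy",
    "likelihood_profile",
    "df_reml_powell",
    "DFREMLResult",
    "em_reml_reference",
    "EMResult",
]


@dataclass(frozen=True)
class VarComps:
    """Variance components of a single-trait model (trait units squared)."""

    variances: dict  # per random effect, keyed by effect name
    residual: float

    def __post_init__(self) -> None:
        if self.residual <= 0:
            raise ValueError("residual variance must be > 0")
        for name, v in self.variances.items():
            if v <= 0:
                raise ValueError(f"variance {name!r} must be > 0")

    @property
    def h2(self) -> float:
        """Heritability: additive variance over total phenotypic variance."""
        total = sum(self.variances.values()) + self.residual
        return self.variances["animal"] / total

    @property
    def total(self) -> float:
        return sum(self.variances.values()) + self.residual

    def as_dict(self) -> dict:
        return {**self.variances, "residual": self.residual}


@dataclass
class LikelihoodValue:
    """-2 log L_r and its components (constants independent of vc dropped)."""

    minus_two_logl: float
    components: dict
    backend: str
    logdet_sd: float = 0.0

    def __float__(self) -> float:
        return self.minus_two_logl


# ---------------------------------------------------------------------------
# likelihood evaluation
# ---------------------------------------------------------------------------


def _logdet_k(frame: ModelFrame, backend: str, config: ApproxConfig):
    """sum_k log|K_k| (vc-independent, cached per frame and backend)."""
    key = f"logdetK_{backend}_{config.seed if backend == 'approximate' else 0}"
    if key in frame._cache:
        return frame._cache[key]
    total, sd = 0.0, 0.0
    for eff in frame.effects:
        if eff.kind == "identity":
            continue
        if eff.kind == "pedigree":
            total += logdet_a(frame.ped)
            continue
        # single-step: log|H| = -log|H^-1|
        hop = hinv_operator(frame.ped, frame.geno, blend_weight=frame.blend_weight)
        if backend == "exact":
            total += -exact_logdet_ldl(hop.explicit_sparse())
        else:
            est = hutchinson_logdet(hop, config)
            total += -est.value
            sd = float(np.hypot(sd, est.sd))
    frame._cache[key] = (total, sd)
    return total, sd


def ypy(frame: ModelFrame, vc: VarComps, tol: float = 1e-10, max_iter: int = 5000) -> float:
    """y'Py via the mixed-model equations.

    Solves C theta = Theta'y / sigma2_e by Jacobi-preconditioned conjugate
    gradients and applies the standard identity
    y'Py = y'R^-1 y - theta_hat' rhs.
    """
    C = mme_operator(frame, vc.as_dict())
    rhs = frame.rhs_base() / vc.residual
    diag = C.diag
    M = spla.LinearOperator(
        (C.n, C.n), matvec=lambda v: v / diag, dtype=float
    )
    A = spla.LinearOperator((C.n, C.n), matvec=C.matvec, dtype=float)
    theta, info = spla.cg(A, rhs, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
    if info != 0:
        res = np.linalg.norm(rhs - C.matvec(theta)) / np.linalg.norm(rhs)
        raise RuntimeError(f"MME conjugate gradients did not converge (residual {res:.2e})")
    return float(frame.y @ frame.y / vc.residual - theta @ rhs)


def restricted_m2ll(
    frame: ModelFrame,
    vc: VarComps,
    backend: str = "exact",
    config: ApproxConfig | None = None,
) -> LikelihoodValue:
    """-2 log L_r up to an additive constant independent of the variances."""
    if backend not in ("exact", "approximate"):
        raise ValueError("backend must be 'exact' or 'approximate'")
    config = config or ApproxConfig()
    n = frame.n_records
    log_r = n * np.log(vc.residual)
    log_g0 = sum(
        eff.n_levels * np.log(vc.variances[eff.name]) for eff in frame.effects
    )
    log_k, sd_k = _logdet_k(frame, backend, config)
    C = mme_operator(frame, vc.as_dict())
    if backend == "exact":
        log_c = exact_logdet_ldl(C.explicit_sparse())
        sd_c = 0.0
    else:
        est = hutchinson_logdet(C, config)
        log_c = est.value
        sd_c = est.sd
    quad = ypy(frame, vc)
    total = log_r + log_g0 + log_k + log_c + quad
    return LikelihoodValue(
        minus_two_logl=float(total),
        components={
            "log_det_r": float(log_r),
            "log_det_g0": float(log_g0),
            "log_det_k": float(log_k),
            "log_det_c": float(log_c),
            "ypy": float(quad),
        },
        backend=backend,
        logdet_sd=float(np.hypot(sd_k, sd_c)),
    )


# ---------------------------------------------------------------------------
# likelihood profile over heritability
# ---------------------------------------------------------------------------


def likelihood_profile(
    frame: ModelFrame,
    h2_grid,
    total_variance: float | None = None,
    mode: str = "profiled",
    backends=("exact", "approximate"),
    config: ApproxConfig | None = None,
) -> pd.DataFrame:
    """-2 log L_r along a heritability grid, per backend.

    At each h2 the variances are sigma2_u = h2 * V, sigma2_e = (1 - h2) * V.
    With ``mode='profiled'`` (default) the overall scale V is profiled out
    analytically -- the curve is then a true profile likelihood in h2 alone;
    ``mode='fixed'`` holds V at ``total_variance`` (default: the sample
    variance of y).  The frame must have the additive effect as its only
    random effect.  Returns a tidy table with an ``argmin`` entry per backend
    in ``DataFrame.attrs``.
    """
    if mode not in ("profiled", "fixed"):
        raise ValueError("mode must be 'profiled' or 'fixed'")
    if [e.name for e in frame.effects] != ["animal"]:
        raise ValueError("profiling supports the plain animal model only")
    h2_grid = np.asarray(list(h2_grid), dtype=float)
    if np.any(h2_grid <= 0) or np.any(h2_grid >= 1):
        raise ValueError("heritability grid must lie in (0, 1)")
    V = float(total_variance) if total_variance is not None else float(np.var(frame.y))
    n_minus_p = frame.n_records - frame.n_fixed
    config = config or ApproxConfig()
    rows = []
    for h2 in h2_grid:
        vc = VarComps({"animal": h2 * V}, (1.0 - h2) * V)
        row = {"h2": float(h2)}
        for backend in backends:
            like = restricted_m2ll(frame, vc, backend=backend, config=config)
            if mode == "profiled":
                q = like.components["ypy"]
                logdets = like.minus_two_logl - q
                s_hat = q / n_minus_p
                row[f"m2ll_{backend}"] = logdets + n_minus_p * (np.log(s_hat) + 1.0)
            else:
                row[f"m2ll_{backend}"] = like.minus_two_logl
            if backend == "approximate":
                row["logdet_sd"] = like.logdet_sd
        rows.append(row)
    df = pd.DataFrame(rows)
    for backend in backends:
        df.attrs[f"argmin_{backend}"] = float(
            df["h2"].iloc[int(df[f"m2ll_{backend}"].idxmin())]
        )
    return df


# ---------------------------------------------------------------------------
# derivative-free REML (Powell)
# ---------------------------------------------------------------------------


@dataclass
class DFREMLResult:
    estimates: VarComps
    minus_two_logl: float
    n_feval: int
    converged: bool
    backend: str
    trace: list = field(default_factory=list)


def df_reml_powell(
    frame: ModelFrame,
    init: VarComps,
    bounds_factor: float = 1e3,
    backend: str = "exact",
    config: ApproxConfig | None = None,
    ftol: float = 1e-4,
    xtol: float = 1e-5,
    max_feval: int = 500,
) -> DFREMLResult:
    """Derivative-free REML: minimize -2 log L_r by Powell's direction-set
    method in log-variance coordinates.

    The log parameterization keeps every variance strictly positive; bounds
    span ``bounds_factor`` above and below the initial values.  With the
    approximate backend the probe sequence is forced to be shared across
    evaluations (common random numbers), without which the optimizer would
    chase Monte Carlo noise.
    """
    config = config or ApproxConfig()
    if backend == "approximate" and not config.reuse_probes:
        config = replace(config, reuse_probes=True)
    names = [e.name for e in frame.effects]
    x0 = np.log([init.variances[n] for n in names] + [init.residual])
    lb = x0 - np.log(bounds_factor)
    ub = x0 + np.log(bounds_factor)
    trace: list[tuple] = []

    def objective(x: np.ndarray) -> float:
        v = np.exp(x)
        vc = VarComps(dict(zip(names, v[:-1])), v[-1])
        val = restricted_m2ll(frame, vc, backend=backend, config=config).minus_two_logl
        trace.append((vc.as_dict(), val))
        return val

    res = opt.minimize(
        objective,
        x0,
        method="Powell",
        bounds=list(zip(lb, ub)),
        options={"xtol": xtol, "ftol": ftol, "maxfev": max_feval},
    )
    v = np.exp(res.x)
    estimates = VarComps(dict(zip(names, v[:-1])), v[-1])
    return DFREMLResult(
        estimates=estimates,
        minus_two_logl=float(res.fun),
        n_feval=int(res.nfev),
        converged=bool(res.success),
        backend=backend,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# EM-REML reference (dense, desk scale)
# ---------------------------------------------------------------------------


@dataclass
class EMResult:
    estimates: VarComps
    rounds: int
    converged: bool


def _kinv_dense(frame: ModelFrame, eff) -> np.ndarray:
    from .operators import _kinv_parts

    kinv_sparse, dense_part = _kinv_parts(frame, eff)
    K = kinv_sparse.toarray()
    if dense_part is not None:
        idx, block = dense_part
        K[np.ix_(idx, idx)] += block
    return K


def em_reml_reference(
    frame: ModelFrame,
    init: VarComps,
    max_rounds: int = 300,
    tol: float = 1e-8,
) -> EMResult:
    """Classical EM-REML with the dense inverse of the coefficient matrix.

    Per round, with lambda_k = sigma2_e / sigma2_k and
    C* = Theta'Theta + blockdiag(0, K_k^-1 lambda_k):

        sigma2_k <- (u_k' K_k^-1 u_k + sigma2_e tr(K_k^-1 C*^{kk})) / q_k
        sigma2_e <- y'(y - Theta theta_hat) / (n - p)

    Iterates until the largest relative parameter change drops below ``tol``.
    Quadratic in the number of equations; intended for validation at desk
    scale.
    """
    base = frame.normal_equations_base().toarray()
    rhs = frame.rhs_base()
    offsets = frame.block_offsets()
    kinvs = {e.name: _kinv_dense(frame, e) for e in frame.effects}
    n, p = frame.n_records, frame.n_fixed
    vc = init
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        C = base.copy()
        for eff in frame.effects:
            lo, hi = offsets[eff.name]
            lam = vc.residual / vc.variances[eff.name]
            C[lo:hi, lo:hi] += kinvs[eff.name] * lam
        try:
            Cinv = np.linalg.inv(C)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("coefficient matrix not invertible in EM round") from exc
        theta = Cinv @ rhs
        new_vars = {}
        for eff in frame.effects:
            lo, hi = offsets[eff.name]
            u = theta[lo:hi]
            kinv = kinvs[eff.name]
            quad = float(u @ (kinv @ u))
            tr = float(np.sum(kinv * Cinv[lo:hi, lo:hi]))
            new_vars[eff.name] = (quad + vc.residual * tr) / eff.n_levels
        sigma_e = float(frame.y @ frame.y - theta @ rhs) / (n - p)
        new = VarComps(new_vars, sigma_e)
        rel = max(
            abs(new.as_dict()[k] - vc.as_dict()[k]) / abs(vc.as_dict()[k])
            for k in new.as_dict()
        )
        vc = new
        if rel < tol:
            converged = True
            break
    return EMResult(estimates=vc, rounds=rounds, converged=converged)
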