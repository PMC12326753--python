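"""Complete elliptic integrals and Jacobi elliptic functions at complex argument.

These are the two special-function primitives behind the conformal map of the
contour quadrature: ``ellipkkp`` returns the complete elliptic integrals of
the first kind K(m) and K'(m) for the parameter m = exp(-2*pi*L), and
``ellipjc`` evaluates the Jacobi elliptic functions sn, cn, dn at complex
argument by a descending Landen transformation.  The parameterization through
L keeps both well behaved when m underflows (large L) or approaches one
(small L), which is exactly the regime ill-conditioned matrices produce.

The algorithms follow the classic ellipkkp/ellipjc routines of Driscoll's
Schwarz-Christoffel Toolbox (AGM for the integrals; Landen recursion with a
Maclaurin-series base case for the functions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EllipticPair", "ellipkkp", "ellipjc"]

_EPS = np.finfo(float).eps


@dataclass(frozen=True)
class EllipticPair:
    """K and K' of the first kind at parameter m = exp(-2*pi*L)."""

    K: float
    Kprime: float
    L: float

    @property
    def m(self) -> float:
        return float(np.exp(-2.0 * np.pi * self.L))


def _agm(a: float, b: float) -> float:
    # quadratic convergence: a handful of iterations reaches machine epsilon;
    # the cap guards against last-bit oscillation around the tolerance
    for _ in range(60):
        if abs(a - b) <= _EPS * abs(a):
            break
        a, b = 0.5 * (a + b), np.sqrt(a * b)
    return 0.5 * (a + b)


def ellipkkp(L: float) -> EllipticPair:
    """Complete elliptic integrals K(m), K'(m) for m = exp(-2*pi*L).

    For L > 10 the modulus is numerically zero and the asymptotic values
    K = pi/2, K' = pi*L + 2*log(2) are exact to machine precision, avoiding
    underflow in exp(-2*pi*L).
    """
    if not np.isfinite(L) or L < 0:
        raise ValueError("L must be a nonnegative real number")
    if L == 0:
        return EllipticPair(K=np.inf, Kprime=np.pi / 2, L=0.0)
    if L > 10.0:
        return EllipticPair(K=np.pi / 2, Kprime=np.pi * L + 2.0 * np.log(2.0), L=float(L))
    m = np.exp(-2.0 * np.pi * L)
    K = np.pi / (2.0 * _agm(1.0, np.sqrt(1.0 - m)))
    Kp = np.pi / (2.0 * _agm(1.0, np.sqrt(m)))
    return EllipticPair(K=float(K), Kprime=float(Kp), L=float(L))


# Maclaurin coefficients of kappa = (1 - sqrt(1-m))/(1 + sqrt(1-m)) in m/4
# (Catalan numbers), used when m is too small for the closed form.
_KAPPA_POLY = np.array([132.0, 42.0, 14.0, 5.0, 2.0, 1.0, 0.0])


def _ellipj_landen(u: np.ndarray, m: float):
    """sn, cn, dn at parameter m by one step of descending Landen recursion."""
    if m < 4.0 * _EPS:
        # degenerate-modulus series: trigonometric limit plus O(m) correction
        sinu, cosu = np.sin(u), np.cos(u)
        sn = sinu + 0.25 * m * (sinu * cosu - u) * cosu
        cn = cosu + 0.25 * m * (-sinu * cosu + u) * sinu
        dn = 1.0 + 0.25 * m * (cosu**2 - sinu**2 - 1.0)
        return sn, cn, dn
    if m > 1e-3:
        kappa = (1.0 - np.sqrt(1.0 - m)) / (1.0 + np.sqrt(1.0 - m))
    else:
        kappa = np.polyval(_KAPPA_POLY, m / 4.0)
    mu = kappa * kappa
    sn1, cn1, dn1 = _ellipj_landen(u / (1.0 + kappa), mu)
    denom = 1.0 + kappa * sn1**2
    sn = (1.0 + kappa) * sn1 / denom
    cn = cn1 * dn1 / denom
    dn = (1.0 - kappa * sn1**2) / denom
    return sn, cn, dn


def ellipjc(u, L: float):
    """Jacobi sn, cn, dn at complex argument ``u``, parameter m = exp(-2*pi*L).

    Arguments are expected inside the fundamental rectangle
    |Re u| <= K, 0 <= Im u <= K'; points above the midline Im u = K'/2 are
    mapped down with the quarter-period identities before the Landen
    recursion, which keeps the recursion numerically stable.
    """
    u = np.asarray(u, dtype=complex)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite argument to ellipjc")
    pair = ellipkkp(L)
    m = np.exp(-2.0 * np.pi * L)
    high = u.imag > pair.Kprime / 2.0
    uu = np.where(high, 1j * pair.Kprime - u, u)
    sn, cn, dn = _ellipj_landen(uu, m)
    if np.any(high):
        sqm = np.sqrt(m)
        snh, cnh, dnh = sn[high], cn[high], dn[high]
        sn = sn.copy(); cn = cn.copy(); dn = dn.copy()
        sn[high] = -1.0 / (sqm * snh)
        cn[high] = 1j * dnh / (sqm * snh)
        dn[high] = 1j * cnh / snh
    return sn, cn, dn
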