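"""Analytic one-center integrals over real spherical Gaussian functions.

All basis functions are one-center (atom-centered) real spherical Gaussians

    phi(r) = N r^l exp(-zeta r^2) S_lm(theta, phi),

with S_lm real spherical harmonics.  For a single center every integral
factorizes into a radial closed form and an angular factor:

* overlap / kinetic / nuclear attraction / p.V p are diagonal in (l, m);
* the axial dipole z couples Delta-l = +-1 at equal real-m label;
* the electron repulsion integral is a finite Laplace (multipole) series

      (ab|cd) = sum_LM 4 pi/(2L+1) <S_a S_b S_LM> <S_c S_d S_LM> R^L(ab; cd)

  with real Gaunt coefficients and radial Slater integrals R^L.  The R^L
  for Gaussian radial pairs reduce to elementary functions (powers, sqrt,
  and a stabilized series for the erfc moment), evaluated vectorized.

Angular factors (real Gaunt coefficients and dipole couplings) are obtained
by Gauss-Legendre x trapezoidal spherical quadrature, which is exact for the
band-limited integrands involved, and cached per (l1, l2, L).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, lpmv

MAX_L = 3  # up to f functions
MAX_LAMBDA = 2 * MAX_L  # highest multipole order in the ERI expansion

__all__ = [
    "radial_norm",
    "overlap_radial",
    "kinetic_radial",
    "nuclear_radial",
    "dipole_radial",
    "pvp_radial",
    "real_gaunt",
    "dipole_angular",
    "slater_rl",
]


# ----------------------------------------------------------------- radial

def _dfact(n: int) -> float:
    """(2n-1)!! with the convention (-1)!! = 1."""
    out = 1.0
    for k in range(1, n + 1):
        out *= 2 * k - 1
    return out


def radial_norm(zeta, l: int):
    """Normalization of r^l exp(-zeta r^2) under int R^2 r^2 dr = 1."""
    zeta = np.asarray(zeta, dtype=float)
    # N^2 = 2 (2 zeta)^(l+3/2) / Gamma(l+3/2)
    return np.sqrt(2.0 * (2.0 * zeta) ** (l + 1.5) / math.gamma(l + 1.5))


def _g_even(s, beta):
    """int_0^inf r^(2s) exp(-beta r^2) dr = Gamma(s+1/2) / (2 beta^(s+1/2)).

    Evaluated in log space so very tight exponent sums at high moment
    order neither overflow nor underflow.
    """
    return 0.5 * np.exp(gammaln(s + 0.5) - (s + 0.5) * np.log(beta))


def _g_odd(m, p):
    """int_0^inf r^(2m+1) exp(-p r^2) dr = m! / (2 p^(m+1))."""
    return math.factorial(m) / (2.0 * p ** (m + 1))


def overlap_radial(a, b, l: int):
    """Unnormalized radial overlap between r^l Gaussians with exponents a, b."""
    return _g_even(l + 1, a + b)


def kinetic_radial(a, b, l: int):
    """Radial kinetic-energy integral; equals S * (2l+3) a b / (a+b)."""
    p = a + b
    return overlap_radial(a, b, l) * (2 * l + 3) * a * b / p


def nuclear_radial(a, b, l: int, Z: float = 1.0):
    """Radial part of <i| -Z/r |j> for equal-l functions."""
    p = a + b
    return -Z * _g_odd(l, p)


def dipole_radial(a, b, l_low: int):
    """Radial <r^l | r | r^(l+1)> moment (unnormalized), l_low the smaller l."""
    p = a + b
    return _g_even(l_low + 2, p)


def pvp_radial(a, b, l: int, Z: float = 1.0):
    """Radial part of <grad i| -Z/r |grad j> (the pVp matrix of DKH).

    From int V [R_i' R_j' + l(l+1) R_i R_j / r^2] r^2 dr with V = -Z/r.
    """
    p = a + b
    out = 4.0 * a * b * _g_odd(l + 1, p) - 2.0 * l * p * _g_odd(l, p)
    if l >= 1:
        out = out + l * (2 * l + 1) * _g_odd(l - 1, p)
    return -Z * out


# ------------------------------------------------------- angular (quadrature)

@lru_cache(maxsize=1)
def _sphere_grid():
    """Gauss-Legendre x trapezoid grid, exact for harmonics up to high order."""
    x, wx = np.polynomial.legendre.leggauss(40)
    nphi = 96
    phi = 2.0 * math.pi * np.arange(nphi) / nphi
    wphi = 2.0 * math.pi / nphi
    X, PHI = np.meshgrid(x, phi, indexing="ij")
    W = wx[:, None] * np.full(nphi, wphi)[None, :]
    return X, PHI, W


@lru_cache(maxsize=64)
def _real_sph_values(l: int):
    """Values of the 2l+1 real spherical harmonics on the cached grid.

    Component order: m = -l..-1 are the sin(|m| phi) combinations, m = 0 the
    zonal harmonic, m = 1..l the cos(m phi) combinations.
    """
    X, PHI, W = _sphere_grid()
    vals = np.empty((2 * l + 1,) + X.shape)
    for m in range(0, l + 1):
        norm = math.sqrt(
            (2 * l + 1)
            / (4.0 * math.pi)
            * math.exp(gammaln(l - m + 1) - gammaln(l + m + 1))
        )
        plm = lpmv(m, l, X)
        if m == 0:
            vals[l] = norm * plm
        else:
            vals[l + m] = math.sqrt(2.0) * norm * plm * np.cos(m * PHI)
            vals[l - m] = math.sqrt(2.0) * norm * plm * np.sin(m * PHI)
    return vals


@lru_cache(maxsize=512)
def real_gaunt(l1: int, l2: int, L: int) -> np.ndarray:
    """Real Gaunt tensor G[m1, m2, M] = int S_l1m1 S_l2m2 S_LM dOmega."""
    _, _, W = _sphere_grid()
    s1 = _real_sph_values(l1)
    s2 = _real_sph_values(l2)
    sL = _real_sph_values(L)
    G = np.einsum("agp,bgp,cgp,gp->abc", s1, s2, sL, W, optimize=True)
    G[np.abs(G) < 1e-14] = 0.0
    return G


@lru_cache(maxsize=64)
def dipole_angular(l1: int, l2: int) -> np.ndarray:
    """Angular factor A[m1, m2] = int S_l1m1 cos(theta) S_l2m2 dOmega."""
    X, _, W = _sphere_grid()
    s1 = _real_sph_values(l1)
    s2 = _real_sph_values(l2)
    A = np.einsum("agp,bgp,gp->ab", s1, s2 * X[None, :, :], W, optimize=True)
    A[np.abs(A) < 1e-14] = 0.0
    return A


# ----------------------------------------------------- radial Slater moments

_BINOM_CENTRAL = [math.comb(2 * j, j) for j in range(400)]


def _j_erfc_odd(m: int, p, q):
    """int_0^inf r^(2m+1) exp(-p r^2) erfc(sqrt(q) r) dr, vectorized.

    Closed form: (m!/(2 p^(m+1))) [1 - sqrt(1-x) S_m(x)], x = p/(p+q) and
    S_m the order-m truncation of (1-x)^(-1/2).  For small x the bracket is
    evaluated through the (convergent) tail series to avoid cancellation.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p, q = np.broadcast_arrays(p, q)
    x = p / (p + q)
    pref = math.factorial(m) / (2.0 * p ** (m + 1))
    out = np.empty_like(x)

    small = x < 0.5
    # direct form where x >= 0.5 (no cancellation there)
    if np.any(~small):
        xs = x[~small]
        s = np.zeros_like(xs)
        for j in range(0, m + 1):
            s += _BINOM_CENTRAL[j] * (xs / 4.0) ** j
        out[~small] = 1.0 - np.sqrt(1.0 - xs) * s
    # tail series where x < 0.5
    if np.any(small):
        xs = x[small]
        term = _BINOM_CENTRAL[m + 1] * (xs / 4.0) ** (m + 1)
        acc = term.copy()
        j = m + 1
        while True:
            j += 1
            term = term * (xs / 4.0) * (_BINOM_CENTRAL[j] / _BINOM_CENTRAL[j - 1])
            acc += term
            if j > m + 300 or np.all(term <= 1e-17 * np.abs(acc) + 1e-300):
                break
        out[small] = np.sqrt(1.0 - xs) * acc
    return pref * out


def _ta_closed(p, q, n1, n2, L: int):
    """Inner-region term by complementing the full inner integral.

    Accurate when q is comparable to p (mass of the inner pair not far
    inside the outer pair); loses digits when q << p.
    """
    pq = p + q
    m = (n1 - L) // 2
    u = (n2 + L) // 2 + 1
    t_a = _g_even(u, q) * _g_odd(m, p)
    corr = math.sqrt(math.pi) / (2.0 * np.sqrt(q)) * _j_erfc_odd(m, p, q)
    for j in range(1, u + 1):
        corr = corr + (2.0 * q) ** (j - 1) / _dfact(j) * _g_even(m + j, pq)
    return t_a - _dfact(u) / (2.0 * q) ** u * corr


def _ta_series(p, q, n1, n2, L: int):
    """Inner-region term by expanding exp(-q r2^2); stable for q << p."""
    nu = n2 + L + 3
    s0 = (n1 + n2 + 4) // 2
    acc = np.zeros_like(p)
    term = np.full_like(p, 1.0)  # (-q)^k / k!
    k = 0
    while True:
        contrib = term / (nu + 2 * k) * _g_even(s0 + k, p)
        acc = acc + contrib
        k += 1
        if k > 300 or np.all(np.abs(contrib) <= 1e-17 * np.abs(acc) + 1e-300):
            break
        term = term * (-q) / k
    return acc


def slater_rl(p, n1, q, n2, L: int):
    """Radial Slater integral for Gaussian pair densities.

    R^L = int int r1^(n1) e^(-p r1^2) r2^(n2) e^(-q r2^2)
                  (r_<^L / r_>^(L+1)) r1^2 r2^2 dr1 dr2

    with n1, n2 nonnegative integers satisfying n1 + L and n2 + L even and
    L <= min(n1, n2) (guaranteed by the Gaunt selection rules).  Vectorized
    over broadcastable p, q arrays.  The kernel is symmetric under
    (p, n1) <-> (q, n2); evaluation always places the tighter pair outside
    and switches to a series expansion for strongly separated exponents,
    which keeps the relative accuracy near 1e-12 over the full dynamic
    range of a well-tempered ladder.
    """
    if (n1 + L) % 2 or (n2 + L) % 2 or L > min(n1, n2):
        raise ValueError(f"invalid multipole combination n1={n1}, n2={n2}, L={L}")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p, q = np.broadcast_arrays(p, q)
    p = p.astype(float, copy=True)
    q = q.astype(float, copy=True)
    out = np.empty_like(p)

    swap = q > p
    for flip in (False, True):
        sel = swap if flip else ~swap
        if not np.any(sel):
            continue
        pp = np.where(flip, q, p)[sel]
        qq = np.where(flip, p, q)[sel]
        na, nb = (n2, n1) if flip else (n1, n2)
        res = _tb_outer(pp, qq, na, nb, L)
        ratio = qq / pp
        series = ratio < 0.35
        if np.any(series):
            res[series] += _ta_series(pp[series], qq[series], na, nb, L)
        if np.any(~series):
            res[~series] += _ta_closed(pp[~series], qq[~series], na, nb, L)
        out[sel] = res
    return out


def _tb_outer(p, q, n1, n2, L: int):
    """Outer-region term (r2 > r1): all-positive elementary sum."""
    pq = p + q
    w = (n2 - L) // 2
    s_b = (n1 + L) // 2 + 1
    t_b = np.zeros_like(pq)
    for j in range(0, w + 1):
        t_b = t_b + q**j / math.factorial(j) * _g_even(s_b + j, pq)
    return t_b * math.factorial(w) / (2.0 * q ** (w + 1))
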