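"""McMurchie-Davidson machinery: Hermite expansion coefficients and the
Hermite R-tensor recursion, generalized to arbitrary distance kernels.

A kernel enters only through its *base derivative sequence*

    base[n] = 2^n (d/dT)^n G0(T),      T = |R|^2,

where G0 is the fundamental (ss|K|ss)-type integral including all prefactors.
The standard Coulomb case base[n] = pref * (-2 rho)^n F_n(rho T) is one
instance; Gaussian-geminal and Gaussian-damped-Coulomb kernels supply their
own sequences. The R recursion itself is kernel independent.
"""

from __future__ import annotations

from math import comb

import numpy as np

from .boys import boys


# ----------------------------------------------------------------------------
# Hermite expansion coefficients E_t^{ij} (one dimension)
# ----------------------------------------------------------------------------

def e1d(la: int, lb: int, p: float, xpa: float, xpb: float,
        kab: float = 1.0) -> np.ndarray:
    """E[i, j, t] for i<=la, j<=lb, t<=i+j; kab is the pair prefactor
    exp(-mu Xab^2) folded into E_0^{00} (pass 1.0 to keep it outside)."""
    E = np.zeros((la + 1, lb + 1, la + lb + 2))
    E[0, 0, 0] = kab
    o2p = 0.5 / p
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                for t in range(i + j + 1):
                    E[i, j, t] = (o2p * (E[i - 1, j, t - 1] if t > 0 else 0.0)
                                  + xpa * E[i - 1, j, t]
                                  + (t + 1) * E[i - 1, j, t + 1])
            else:
                for t in range(i + j + 1):
                    E[i, j, t] = (o2p * (E[i, j - 1, t - 1] if t > 0 else 0.0)
                                  + xpb * E[i, j - 1, t]
                                  + (t + 1) * E[i, j - 1, t + 1])
    return E


# ----------------------------------------------------------------------------
# Kernel base sequences
# ----------------------------------------------------------------------------

def base_2e(kind: str, beta: float | None, p: float, q: float,
            T, L: int) -> np.ndarray:
    """base[n], n=0..L, for a two-electron elementary kernel between Hermite
    Gaussians with exponents p (bra pair) and q (ket pair); T = |P-Q|^2."""
    T = np.asarray(T, dtype=float)
    rho = p * q / (p + q)
    if kind == "coulomb":
        pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
        fn = boys(L, rho * T)
        fac = (-2.0 * rho) ** np.arange(L + 1)
        return pref * fac.reshape((L + 1,) + (1,) * T.ndim) * fn
    if kind == "gauss":
        c = beta * rho / (beta + rho)
        pref = (np.pi ** 2 / (p * q)) ** 1.5 * (rho / (rho + beta)) ** 1.5
        e = pref * np.exp(-c * T)
        fac = (-2.0 * c) ** np.arange(L + 1)
        return fac.reshape((L + 1,) + (1,) * T.ndim) * e[None, ...]
    if kind == "dampcoul":
        a = rho * rho / (rho + beta)
        b = beta * rho / (rho + beta)
        pref = 2.0 * np.pi ** 2.5 / ((p + q) ** 1.5 * (rho + beta))
        return _dampcoul_base(pref, a, b, T, L)
    raise ValueError(f"unknown elementary kernel {kind!r}")


def base_1e(kind: str, beta: float | None, p: float, T, L: int) -> np.ndarray:
    """base[n] for a one-electron (grid-point / nuclear) elementary kernel;
    the point-charge limit q -> infinity of `base_2e`."""
    T = np.asarray(T, dtype=float)
    if kind == "coulomb":
        pref = 2.0 * np.pi / p
        fn = boys(L, p * T)
        fac = (-2.0 * p) ** np.arange(L + 1)
        return pref * fac.reshape((L + 1,) + (1,) * T.ndim) * fn
    if kind == "gauss":
        c = p * beta / (p + beta)
        pref = (np.pi / (p + beta)) ** 1.5
        e = pref * np.exp(-c * T)
        fac = (-2.0 * c) ** np.arange(L + 1)
        return fac.reshape((L + 1,) + (1,) * T.ndim) * e[None, ...]
    if kind == "dampcoul":
        a = p * p / (p + beta)
        b = p * beta / (p + beta)
        pref = 2.0 * np.pi / (p + beta)
        return _dampcoul_base(pref, a, b, T, L)
    raise ValueError(f"unknown elementary kernel {kind!r}")


def _dampcoul_base(pref: float, a: float, b: float, T, L: int) -> np.ndarray:
    """base[n] for K = pref * exp(-bT) F0(aT):
    2^n (d/dT)^n = (-2)^n sum_k C(n,k) b^(n-k) a^k exp(-bT) F_k(aT)."""
    fn = boys(L, a * T)
    ebt = np.exp(-b * T)
    out = np.empty((L + 1,) + np.shape(T))
    for n in range(L + 1):
        acc = np.zeros(np.shape(T))
        for k in range(n + 1):
            acc = acc + comb(n, k) * b ** (n - k) * a ** k * fn[k]
        out[n] = (-2.0) ** n * pref * ebt * acc
    return out


# ----------------------------------------------------------------------------
# Hermite R tensor
# ----------------------------------------------------------------------------

def hermite_r(L: int, X, Y, Z,
              base: np.ndarray) -> dict[tuple[int, int, int], np.ndarray]:
    """R_{tuv} for all t+u+v <= L given the kernel base sequence
    (length >= L+1). X, Y, Z broadcast against base[n]."""
    memo: dict[tuple[int, int, int, int], np.ndarray] = {}

    def rec(n: int, t: int, u: int, v: int):
        if t < 0 or u < 0 or v < 0:
            return 0.0
        key = (n, t, u, v)
        if key in memo:
            return memo[key]
        if t == u == v == 0:
            val = base[n]
        elif t > 0:
            val = (t - 1) * rec(n + 1, t - 2, u, v) + X * rec(n + 1, t - 1, u, v)
        elif u > 0:
            val = (u - 1) * rec(n + 1, t, u - 2, v) + Y * rec(n + 1, t, u - 1, v)
        else:
            val = (v - 1) * rec(n + 1, t, u, v - 2) + Z * rec(n + 1, t, u, v - 1)
        memo[key] = val
        return val

    return {(t, u, v): rec(0, t, u, v)
            for t in range(L + 1)
            for u in range(L + 1 - t)
            for v in range(L + 1 - t - u)}
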