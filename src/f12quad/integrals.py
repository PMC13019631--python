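"""Analytic Gaussian integrals over the F12 kernel family.

Evaluates, for any elementary-kernel decomposition from `kernels`:

* 4c2e  (ab|O|cd)   Mulliken order, mixed basis sets allowed
* 3c2e  (ab|O|R)    orbital pair x density-fitting auxiliary
* 2c2e  (R|O|S)     auxiliary metric
* grid 3c1e 0(g|O|ab)  kernel centered at quadrature points
* overlap / kinetic / nuclear attraction for the RHF reference

plus AO amplitudes on grid points. Everything is dense `numpy`; the
capability bound is d functions (enforced by `basis`).
"""

from __future__ import annotations

import numpy as np

from .basis import BasisSet, Shell
from .kernels import ElementaryTerm, KernelSpec
from .md import base_1e, base_2e, e1d, hermite_r
from .molecule import Molecule

__all__ = [
    "overlap", "kinetic", "nuclear_attraction", "ao_values",
    "eri_4c2e", "eri_3c2e", "eri_2c2e", "grid_3c1e",
]


# ----------------------------------------------------------------------------
# shell-pair Hermite data
# ----------------------------------------------------------------------------

class _PairPrim:
    """Hermite data of one primitive pair: exponent p, center P and the
    per-cartesian-component Hermite table H[comp, t, u, v] with contraction
    coefficients and norms folded in."""

    __slots__ = ("p", "P", "H", "lsum")

    def __init__(self, p: float, P: np.ndarray, H: np.ndarray, lsum: int):
        self.p = p
        self.P = P
        self.H = H
        self.lsum = lsum


def _pair_prims(sa: Shell, sb: Shell | None) -> list[_PairPrim]:
    """All primitive pairs of a shell pair (or a single shell when sb=None,
    which represents an auxiliary 'pair' of one Gaussian)."""
    out: list[_PairPrim] = []
    A = sa.center
    carts_a = sa.cartesians
    if sb is None:
        for ia, a in enumerate(sa.exps):
            E = [e1d(sa.l, 0, a, 0.0, 0.0) for _ in range(3)]
            lsum = sa.l
            ncomp = sa.n_ao
            H = np.zeros((ncomp, lsum + 1, lsum + 1, lsum + 1))
            for ca, (ix, iy, iz) in enumerate(carts_a):
                na = sa.norms[ca, ia]
                for t in range(ix + 1):
                    for u in range(iy + 1):
                        for v in range(iz + 1):
                            H[ca, t, u, v] += (na * E[0][ix, 0, t]
                                               * E[1][iy, 0, u] * E[2][iz, 0, v])
            out.append(_PairPrim(a, A, H, lsum))
        return out

    B = sb.center
    AB = A - B
    carts_b = sb.cartesians
    lsum = sa.l + sb.l
    for ia, a in enumerate(sa.exps):
        for ib, b in enumerate(sb.exps):
            p = a + b
            mu = a * b / p
            kab = np.exp(-mu * AB @ AB)
            if kab < 1e-18:
                continue
            P = (a * A + b * B) / p
            PA, PB = P - A, P - B
            E = [e1d(sa.l, sb.l, p, PA[d], PB[d]) for d in range(3)]
            H = np.zeros((sa.n_ao * sb.n_ao, lsum + 1, lsum + 1, lsum + 1))
            idx = 0
            for ca, (ix, iy, iz) in enumerate(carts_a):
                na = sa.norms[ca, ia]
                for cb, (jx, jy, jz) in enumerate(carts_b):
                    nb = sb.norms[cb, ib]
                    c = kab * na * nb
                    for t in range(ix + jx + 1):
                        et = E[0][ix, jx, t]
                        if et == 0.0:
                            continue
                        for u in range(iy + jy + 1):
                            eu = E[1][iy, jy, u]
                            if eu == 0.0:
                                continue
                            for v in range(iz + jz + 1):
                                H[idx, t, u, v] += c * et * eu * E[2][iz, jz, v]
                    idx += 1
            out.append(_PairPrim(p, P, H, lsum))
    return out


def _terms(op) -> list[ElementaryTerm]:
    if isinstance(op, KernelSpec):
        return op.elementary_terms()
    return list(op)


# ----------------------------------------------------------------------------
# one-electron integrals
# ----------------------------------------------------------------------------

def overlap(b1: BasisSet, b2: BasisSet | None = None) -> np.ndarray:
    b2 = b2 or b1
    S = np.zeros((b1.n_ao, b2.n_ao))
    for sa, oa in zip(b1.shells, b1.ao_offsets):
        for sb, ob in zip(b2.shells, b2.ao_offsets):
            S[oa:oa + sa.n_ao, ob:ob + sb.n_ao] = _overlap_block(sa, sb)
    return S


def _overlap_block(sa: Shell, sb: Shell) -> np.ndarray:
    out = np.zeros((sa.n_ao, sb.n_ao))
    A, B = sa.center, sb.center
    AB = A - B
    for ia, a in enumerate(sa.exps):
        for ib, b in enumerate(sb.exps):
            p = a + b
            kab = np.exp(-a * b / p * (AB @ AB))
            if kab < 1e-18:
                continue
            P = (a * A + b * B) / p
            E = [e1d(sa.l, sb.l, p, P[d] - A[d], P[d] - B[d]) for d in range(3)]
            s = (np.pi / p) ** 1.5
            for ca, (ix, iy, iz) in enumerate(sa.cartesians):
                for cb, (jx, jy, jz) in enumerate(sb.cartesians):
                    out[ca, cb] += (sa.norms[ca, ia] * sb.norms[cb, ib] * kab * s
                                    * E[0][ix, jx, 0] * E[1][iy, jy, 0]
                                    * E[2][iz, jz, 0])
    return out


def kinetic(b1: BasisSet) -> np.ndarray:
    T = np.zeros((b1.n_ao, b1.n_ao))
    for sa, oa in zip(b1.shells, b1.ao_offsets):
        for sb, ob in zip(b1.shells, b1.ao_offsets):
            T[oa:oa + sa.n_ao, ob:ob + sb.n_ao] = _kinetic_block(sa, sb)
    return T


def _kinetic_block(sa: Shell, sb: Shell) -> np.ndarray:
    """-1/2 <a|del^2|b> via angular-momentum shifts on the ket."""
    out = np.zeros((sa.n_ao, sb.n_ao))
    A, B = sa.center, sb.center
    AB = A - B
    for ia, a in enumerate(sa.exps):
        for ib, b in enumerate(sb.exps):
            p = a + b
            kab = np.exp(-a * b / p * (AB @ AB))
            if kab < 1e-18:
                continue
            P = (a * A + b * B) / p
            # ket angular momentum raised by up to 2 in each dimension
            E = [e1d(sa.l, sb.l + 2, p, P[d] - A[d], P[d] - B[d])
                 for d in range(3)]
            s = (np.pi / p) ** 1.5

            def s1(d: int, i: int, j: int) -> float:
                if i < 0 or j < 0:
                    return 0.0
                return E[d][i, j, 0]

            for ca, la in enumerate(sa.cartesians):
                for cb, lb in enumerate(sb.cartesians):
                    term = 0.0
                    for d in range(3):
                        i, j = la[d], lb[d]
                        o1, o2 = (d + 1) % 3, (d + 2) % 3
                        rest = (s1(o1, la[o1], lb[o1]) * s1(o2, la[o2], lb[o2]))
                        td = (b * (2 * j + 1) * s1(d, i, j)
                              - 2.0 * b * b * s1(d, i, j + 2)
                              - 0.5 * j * (j - 1) * s1(d, i, j - 2))
                        term += td * rest
                    out[ca, cb] += (sa.norms[ca, ia] * sb.norms[cb, ib]
                                    * kab * s * term)
    return out


def nuclear_attraction(b1: BasisSet, molecule: Molecule) -> np.ndarray:
    V = np.zeros((b1.n_ao, b1.n_ao))
    centers = molecule.positions
    charges = molecule.charges
    for sa, oa in zip(b1.shells, b1.ao_offsets):
        for sb, ob in zip(b1.shells, b1.ao_offsets):
            if ob < oa:
                continue
            block = np.zeros((sa.n_ao, sb.n_ao))
            for prim in _pair_prims(sa, sb):
                L = prim.lsum
                PC = prim.P[None, :] - centers  # (natom, 3)
                T = np.einsum("ad,ad->a", PC, PC)
                base = base_1e("coulomb", None, prim.p, T, L)
                R = hermite_r(L, PC[:, 0], PC[:, 1], PC[:, 2], base)
                Rarr = np.zeros((L + 1, L + 1, L + 1, len(centers)))
                for (t, u, v), val in R.items():
                    if t + u + v <= L:
                        Rarr[t, u, v] = val
                contrib = np.einsum("ctuv,tuva,a->c", prim.H, Rarr, -charges)
                block += contrib.reshape(sa.n_ao, sb.n_ao)
            V[oa:oa + sa.n_ao, ob:ob + sb.n_ao] = block
            if ob != oa:
                V[ob:ob + sb.n_ao, oa:oa + sa.n_ao] = block.T
    return V


def ao_values(basis: BasisSet, points: np.ndarray) -> np.ndarray:
    """AO amplitudes chi_mu(r_g); returns (n_ao, n_points)."""
    points = np.atleast_2d(points)
    M = points.shape[0]
    out = np.zeros((basis.n_ao, M))
    for sh, off in zip(basis.shells, basis.ao_offsets):
        d = points - sh.center[None, :]
        r2 = np.einsum("gd,gd->g", d, d)
        rad = np.exp(-np.outer(sh.exps, r2))  # (nprim, M)
        for c, (ix, iy, iz) in enumerate(sh.cartesians):
            poly = d[:, 0] ** ix * d[:, 1] ** iy * d[:, 2] ** iz
            out[off + c] = (sh.norms[c] @ rad) * poly
    return out


# ----------------------------------------------------------------------------
# two-electron integrals (generic elementary-kernel decomposition)
# ----------------------------------------------------------------------------

def _quartet(op_terms: list[ElementaryTerm], bra: list[_PairPrim],
             ket: list[_PairPrim], nbra: int, nket: int) -> np.ndarray:
    out = np.zeros((nbra, nket))
    for pb in bra:
        for pk in ket:
            Lb, Lk = pb.lsum, pk.lsum
            L = Lb + Lk
            PQ = pb.P - pk.P
            T = np.array([PQ @ PQ])
            # signed ket Hermite table
            sk = pk.H.copy()
            for t in range(Lk + 1):
                for u in range(Lk + 1):
                    for v in range(Lk + 1):
                        if (t + u + v) % 2:
                            sk[:, t, u, v] *= -1.0
            acc = None
            for kind, beta, coef in op_terms:
                base = base_2e(kind, beta, pb.p, pk.p, T, L)
                if acc is None:
                    acc = coef * base
                else:
                    acc = acc + coef * base
            R = hermite_r(L, PQ[0], PQ[1], PQ[2], acc)
            # R4[t,u,v,x,y,z] = R[t+x, u+y, v+z]
            R4 = np.zeros((Lb + 1,) * 3 + (Lk + 1,) * 3)
            for t in range(Lb + 1):
                for u in range(Lb + 1):
                    for v in range(Lb + 1):
                        for x in range(Lk + 1):
                            for y in range(Lk + 1):
                                for z in range(Lk + 1):
                                    if t + u + v <= Lb and x + y + z <= Lk:
                                        R4[t, u, v, x, y, z] = R[(t + x, u + y, v + z)][0]
            out += np.einsum("ptuv,qxyz,tuvxyz->pq", pb.H, sk, R4)
    return out


def _pairs_of(b1: BasisSet, b2: BasisSet | None):
    """Iterate shell pairs (or single aux shells) with AO offsets."""
    if b2 is None:
        for sh, off in zip(b1.shells, b1.ao_offsets):
            yield (sh, None, off, 0, sh.n_ao, 1)
        return
    for sa, oa in zip(b1.shells, b1.ao_offsets):
        for sb, ob in zip(b2.shells, b2.ao_offsets):
            yield (sa, sb, oa, ob, sa.n_ao, sb.n_ao)


def eri_4c2e(op, b1: BasisSet, b2: BasisSet, b3: BasisSet,
             b4: BasisSet) -> np.ndarray:
    """(ab|O|cd) in Mulliken order; shape (n1, n2, n3, n4).

    Use `mulliken_to_dirac` for the physicist convention <ac|O|bd>.
    """
    terms = _terms(op)
    out = np.zeros((b1.n_ao, b2.n_ao, b3.n_ao, b4.n_ao))
    sym_bra = b1 is b2
    sym_ket = b3 is b4
    sym_quart = sym_bra and sym_ket and b1 is b3

    def pair_list(bx, by, sym):
        items = []
        for i, (sa, oa) in enumerate(zip(bx.shells, bx.ao_offsets)):
            for j, (sb, ob) in enumerate(zip(by.shells, by.ao_offsets)):
                if sym and j < i:
                    continue
                items.append((i, j, sa, sb, oa, ob, _pair_prims(sa, sb)))
        return items

    bras = pair_list(b1, b2, sym_bra)
    kets = bras if sym_quart else pair_list(b3, b4, sym_ket)
    for ibra, (i, j, sa, sb, oa, ob, bra) in enumerate(bras):
        na, nb = sa.n_ao, sb.n_ao
        for iket, (k, l, sc, sd, oc, od, ket) in enumerate(kets):
            if sym_quart and iket < ibra:
                continue
            nc, nd = sc.n_ao, sd.n_ao
            blk = _quartet(terms, bra, ket, na * nb, nc * nd).reshape(
                na, nb, nc, nd)
            out[oa:oa + na, ob:ob + nb, oc:oc + nc, od:od + nd] = blk
            if sym_bra and j != i:
                out[ob:ob + nb, oa:oa + na, oc:oc + nc, od:od + nd] = (
                    blk.transpose(1, 0, 2, 3))
            if sym_ket and l != k:
                out[oa:oa + na, ob:ob + nb, od:od + nd, oc:oc + nc] = (
                    blk.transpose(0, 1, 3, 2))
            if sym_bra and sym_ket and j != i and l != k:
                out[ob:ob + nb, oa:oa + na, od:od + nd, oc:oc + nc] = (
                    blk.transpose(1, 0, 3, 2))
            if sym_quart and iket != ibra:
                out[oc:oc + nc, od:od + nd, oa:oa + na, ob:ob + nb] = (
                    blk.transpose(2, 3, 0, 1))
                if j != i:
                    out[oc:oc + nc, od:od + nd, ob:ob + nb, oa:oa + na] = (
                        blk.transpose(2, 3, 1, 0))
                if l != k:
                    out[od:od + nd, oc:oc + nc, oa:oa + na, ob:ob + nb] = (
                        blk.transpose(3, 2, 0, 1))
                if j != i and l != k:
                    out[od:od + nd, oc:oc + nc, ob:ob + nb, oa:oa + na] = (
                        blk.transpose(3, 2, 1, 0))
    return out


def eri_3c2e(op, b1: BasisSet, b2: BasisSet, aux: BasisSet) -> np.ndarray:
    """(ab|O|R); shape (n1, n2, naux)."""
    terms = _terms(op)
    out = np.zeros((b1.n_ao, b2.n_ao, aux.n_ao))
    ket_cache = [(sr, orr, nr, _pair_prims(sr, None))
                 for sr, _sb, orr, _ob, nr, _nb in _pairs_of(aux, None)]
    for sa, sb, oa, ob, na, nb in _pairs_of(b1, b2):
        bra = _pair_prims(sa, sb)
        for sr, orr, nr, ket in ket_cache:
            block = _quartet(terms, bra, ket, na * nb, nr)
            out[oa:oa + na, ob:ob + nb, orr:orr + nr] = block.reshape(na, nb, nr)
    return out


def eri_2c2e(op, aux1: BasisSet, aux2: BasisSet | None = None) -> np.ndarray:
    """(R|O|S) metric; shape (naux1, naux2)."""
    terms = _terms(op)
    aux2 = aux2 or aux1
    out = np.zeros((aux1.n_ao, aux2.n_ao))
    ket_cache = [(orr, nr, _pair_prims(sr, None))
                 for sr, _s, orr, _o, nr, _n in _pairs_of(aux2, None)]
    for sa, _sb, oa, _ob, na, _nb in _pairs_of(aux1, None):
        bra = _pair_prims(sa, None)
        for orr, nr, ket in ket_cache:
            out[oa:oa + na, orr:orr + nr] = _quartet(terms, bra, ket, na, nr)
    return out


def mulliken_to_dirac(t: np.ndarray) -> np.ndarray:
    """(ac|O|bd) -> <ab|O|cd>: swap axes 1 and 2."""
    return np.ascontiguousarray(t.transpose(0, 2, 1, 3))


# ----------------------------------------------------------------------------
# grid 3c1e integrals
# ----------------------------------------------------------------------------

def grid_3c1e(op, b1: BasisSet, b2: BasisSet, points: np.ndarray,
              pair_skip=None) -> np.ndarray:
    """(g|O|mu nu) with the kernel centered at each point; shape (M, n1, n2).

    ``pair_skip(i_shell_a, i_shell_b)`` may return True to zero a shell pair
    (screening); the caller is responsible for the soundness of the bound.
    """
    terms = _terms(op)
    points = np.atleast_2d(points)
    M = points.shape[0]
    out = np.zeros((M, b1.n_ao, b2.n_ao))
    same = b2 is b1
    for isa, (sa, oa) in enumerate(zip(b1.shells, b1.ao_offsets)):
        for isb, (sb, ob) in enumerate(zip(b2.shells, b2.ao_offsets)):
            if same and isb < isa:
                continue
            if pair_skip is not None and pair_skip(isa, isb):
                continue
            block = np.zeros((sa.n_ao * sb.n_ao, M))
            for prim in _pair_prims(sa, sb):
                L = prim.lsum
                PC = prim.P[None, :] - points  # (M, 3)
                T = np.einsum("gd,gd->g", PC, PC)
                acc = None
                for kind, beta, coef in terms:
                    base = base_1e(kind, beta, prim.p, T, L)
                    acc = coef * base if acc is None else acc + coef * base
                R = hermite_r(L, PC[:, 0], PC[:, 1], PC[:, 2], acc)
                Rarr = np.zeros((L + 1, L + 1, L + 1, M))
                for (t, u, v), val in R.items():
                    if t + u + v <= L:
                        Rarr[t, u, v] = val
                block += np.einsum("ctuv,tuvg->cg", prim.H, Rarr)
            blk = block.reshape(sa.n_ao, sb.n_ao, M).transpose(2, 0, 1)
            out[:, oa:oa + sa.n_ao, ob:ob + sb.n_ao] = blk
            if same and isb != isa:
                out[:, ob:ob + sb.n_ao, oa:oa + sa.n_ao] = blk.transpose(0, 2, 1)
    return out
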