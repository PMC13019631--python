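"""Dense brute-force oracle for the exchange-type intermediates.

An independent code path validating the production engine: exact (non-DF)
MO 4c2e integrals, unscreened fine-grid quadrature for the genuine
three-electron integrals, and plain nested einsum contractions, resolved
per active pair (i, j). It applies the *same* union-space RI insertions as
the production path (so the comparison validates the computation, not the
intrinsic RI error) but shares nothing with the batched/screened/
density-fitted machinery beyond the primitive integral kernels.

Guarded to small systems (<= 40 orbital-basis AOs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrals import ao_values, eri_4c2e, grid_3c1e
from .intermediates import ExchangeIntermediates
from .kernels import KernelSpec
from .nq_engine import OpCounters
from .quadrature import build_grid
from .spaces import OrbitalSpaces

AO_GUARD = 40
ORACLE_GRID = "g7"        # reference protocol: extensive grid, no screening
_CHUNK = 2048


class OracleUnavailableError(RuntimeError):
    pass


def _mo4(t_ao: np.ndarray, C1, C2, C3, C4) -> np.ndarray:
    return np.einsum("mnls,mp,nq,lr,st->pqrt", t_ao, C1, C2, C3, C4,
                     optimize=True)


@dataclass
class DenseTensors:
    """Exact Mulliken MO tensors. mul[op][p,q,r,s] = (pq|op|rs) over p-MOs;
    mixed[op][x,p',y,z] = (x p'|op|y z) with one union-MO index."""
    mul: dict[str, np.ndarray]
    mixed: dict[str, np.ndarray]


def dense_tensors(spaces: OrbitalSpaces, gamma: float, n_fit: int = 6,
                  ops: tuple[str, ...] = ("F", "G", "FG", "F2"),
                  mixed_ops: tuple[str, ...] = ("F", "F2")) -> DenseTensors:
    obs = spaces.obs
    if obs.n_ao > AO_GUARD:
        raise OracleUnavailableError(
            f"dense oracle limited to {AO_GUARD} AOs (got {obs.n_ao})")
    union = spaces.union_basis
    Co = spaces.reference.C
    Cu = spaces.C_union
    mul = {}
    for op in ops:
        t = eri_4c2e(KernelSpec(op, gamma, n_fit), obs, obs, obs, obs)
        mul[op] = _mo4(t, Co, Co, Co, Co)
    mixed = {}
    for op in mixed_ops:
        t = eri_4c2e(KernelSpec(op, gamma, n_fit), obs, union, obs, obs)
        mixed[op] = np.einsum("mMls,mx,Mp,ly,sz->xpyz", t, Co, Cu, Co, Co,
                              optimize=True)
    return DenseTensors(mul=mul, mixed=mixed)


def sixc3e_fine(spaces: OrbitalSpaces, gamma: float, n_fit: int = 6,
                level: str = ORACLE_GRID, need_union: bool = True,
                weight_threshold: float = 0.0) -> dict[str, np.ndarray]:
    """Pair-resolved fine-grid quadrature of every genuine three-electron
    term (and of the k1 / f1 o1 / o1 f1 o1 full-RI insertions of B when
    `need_union`). No screening, no batching beyond memory chunking."""
    sp = spaces
    obs, union = sp.obs, sp.union_basis
    grid = build_grid(sp.molecule, level, weight_threshold,
                      obs if weight_threshold > 0 else None)
    act = sp.mo_slice("act")
    occ = sp.mo_slice("occ")
    C_act = sp.reference.C[:, act]
    C_occ = sp.reference.C[:, occ]
    Cu = sp.C_union
    f_mo, k_mo = sp.f_mo, sp.k_mo
    nocc = sp.n_occ
    na = sp.n_act
    kF = KernelSpec("F", gamma, n_fit)
    kG = KernelSpec("G", gamma, n_fit)

    names = ["sixFG_x", "sixFG_d", "sixFF_x", "sixFF_d",
             "e62_x", "e62_d", "e63_x", "e63_d", "e64_x", "e64_d"]
    acc = {name: np.zeros((na, na)) for name in names}
    for lo in range(0, grid.n_points, _CHUNK):
        pts = grid.points[lo:lo + _CHUNK]
        w = grid.weights[lo:lo + _CHUNK]
        chi = ao_values(obs, pts)
        phi = chi.T @ C_act                       # (m, n_act)

        Fo = grid_3c1e(kF, obs, obs, pts)
        Go = grid_3c1e(kG, obs, obs, pts)
        BW = np.einsum("gmn,mi,nk->gik", Fo, C_act, C_occ, optimize=True)
        BYG = np.einsum("gmn,mk,nj->gkj", Go, C_occ, C_act, optimize=True)
        BYF = np.einsum("gmn,mk,nj->gkj", Fo, C_occ, C_act, optimize=True)
        acc["sixFG_x"] += np.einsum(
            "g,gi,gj,gik,gkj->ij", w, phi, phi, BW, BYG, optimize=True)
        acc["sixFG_d"] += np.einsum(
            "g,gj,gj,gik,gki->ij", w, phi, phi, BW, BYG, optimize=True)
        acc["sixFF_x"] += np.einsum(
            "g,gi,gj,gik,gkj->ij", w, phi, phi, BW, BYF, optimize=True)
        acc["sixFF_d"] += np.einsum(
            "g,gj,gj,gik,gki->ij", w, phi, phi, BW, BYF, optimize=True)
        if need_union:
            Fu = grid_3c1e(kF, obs, union, pts)
            BU = np.einsum("gmN,mi,Np->gip", Fu, C_act, Cu, optimize=True)
            Bocc = BU[:, :, :nocc]
            acc["e62_x"] += np.einsum(
                "g,gi,gj,gip,pq,gjq->ij", w, phi, phi, BU, k_mo, BU,
                optimize=True)
            acc["e62_d"] += np.einsum(
                "g,gj,gj,gip,pq,giq->ij", w, phi, phi, BU, k_mo, BU,
                optimize=True)
            acc["e63_x"] += np.einsum(
                "g,gi,gj,gip,pl,gjl->ij", w, phi, phi, BU, f_mo[:, :nocc],
                Bocc, optimize=True)
            acc["e63_d"] += np.einsum(
                "g,gj,gj,gip,pl,gil->ij", w, phi, phi, BU, f_mo[:, :nocc],
                Bocc, optimize=True)
            acc["e64_x"] += np.einsum(
                "g,gi,gj,gik,kl,gjl->ij", w, phi, phi, Bocc,
                f_mo[:nocc, :nocc], Bocc, optimize=True)
            acc["e64_d"] += np.einsum(
                "g,gj,gj,gik,kl,gil->ij", w, phi, phi, Bocc,
                f_mo[:nocc, :nocc], Bocc, optimize=True)
    return acc


@dataclass
class DenseReference:
    intermediates: ExchangeIntermediates
    #: per-term pair matrices (n_act x n_act)
    pairs: dict[str, np.ndarray] = field(default_factory=dict)
    #: assembled pair matrices of the intermediates themselves
    v_pairs: dict[str, np.ndarray] = field(default_factory=dict)
    x_pairs: dict[str, np.ndarray] = field(default_factory=dict)
    b_pairs: dict[str, np.ndarray] = field(default_factory=dict)


def dense_intermediates(spaces: OrbitalSpaces, gamma: float = 1.3,
                        n_fit: int = 6, grid_level: str = ORACLE_GRID,
                        commutator_level: str = "full",
                        kl_family: str = "occ",
                        tensors: DenseTensors | None = None,
                        six: dict | None = None) -> DenseReference:
    """Pair-resolved V, X, B (both index patterns) by brute force."""
    sp = spaces
    if tensors is None:
        tensors = dense_tensors(sp, gamma, n_fit)
    act = sp.mo_slice("act")
    occ = sp.mo_slice("occ")
    virt = sp.mo_slice("virt")
    kl = occ if kl_family == "occ" else act
    eps = sp.eps[act]
    f_mo, k_mo = sp.f_mo, sp.k_mo
    nU = sp.n_union

    F, G, FF = tensors.mul["F"], tensors.mul["G"], tensors.mul["F2"]
    FG = tensors.mul["FG"]
    M1F = tensors.mixed["F"]
    M1F2 = tensors.mixed["F2"]

    if six is None:
        six = sixc3e_fine(sp, gamma, n_fit, grid_level, need_union=True)

    p: dict[str, np.ndarray] = dict(six)

    def pair_terms(T4, name):
        p[name + "_x"] = np.einsum("ijji->ij", T4[act, act, act, act]).copy()
        p[name + "_d"] = np.einsum("iijj->ij", T4[act, act, act, act]).copy()

    pair_terms(FG, "fg")
    pair_terms(FF, "ff")

    def prod_terms(W4, Y4, sl, name):
        p[name + "_x"] = np.einsum("ikjl,kjli->ij", W4[act, sl, act, sl],
                                   Y4[sl, act, sl, act], optimize=True)
        p[name + "_d"] = np.einsum("ikjl,kilj->ij", W4[act, sl, act, sl],
                                   Y4[sl, act, sl, act], optimize=True)

    prod_terms(F, G, kl, "oo_FG")
    prod_terms(F, G, virt, "vv_FG")
    prod_terms(F, F, kl, "oo_FF")
    prod_terms(F, F, virt, "vv_FF")

    gsq = gamma * gamma
    fk = (f_mo + k_mo)[act, :]
    p["e61_x"] = np.einsum("ip,jpji->ij", fk, M1F2[act, :, act, act],
                           optimize=True)
    p["e61_d"] = np.einsum("ip,ipjj->ij", fk, M1F2[act, :, act, act],
                           optimize=True)

    # U and T groups with exact integrals (scaled-subspace Fock maps)
    nocc, np_ = sp.n_occ, sp.n_p
    occ_ind = np.zeros(nU)
    occ_ind[:nocc] = 1.0
    virt_ind = np.zeros(nU)
    virt_ind[nocc:np_] = 1.0
    M_U = (-1.0 + 2.0 * occ_ind[None, :]
           - occ_ind[:, None] * occ_ind[None, :]) * f_mo
    M_T = ((-2.0 + virt_ind[:, None]) * f_mo)[:, virt]

    A = M1F[act, :, act, kl]                       # (i, p', j, m)
    Rhs = M1F[act, :, kl, act]                     # (j, r', m, i)
    p["U_x"] = np.einsum("ipjm,pr,jrmi->ij", A, M_U, Rhs, optimize=True)
    p["U_d"] = np.einsum("ipjm,pr,irmj->ij", A, M_U, Rhs, optimize=True)
    vsl_u = slice(nocc, np_)
    Atv = M1F[act, :, act, virt]                   # (i, p', j, c)
    Mt_rows = M1F[act, vsl_u, virt, act]           # (j, b, c, i)
    p["T_x"] = np.einsum("ipjc,pb,jbci->ij", Atv, M_T, Mt_rows, optimize=True)
    p["T_d"] = np.einsum("ipjc,pb,ibcj->ij", Atv, M_T, Mt_rows, optimize=True)

    out = ExchangeIntermediates(
        terms={k: float(v.sum()) for k, v in p.items()},
        counters=OpCounters(), mode="dense", commutator_level=commutator_level)
    ref = DenseReference(intermediates=out, pairs=p)
    wsum = eps[:, None] + eps[None, :]
    for pat in ("x", "d"):
        v = (p[f"fg_{pat}"] + p[f"oo_FG_{pat}"] - p[f"vv_FG_{pat}"]
             - 2.0 * p[f"sixFG_{pat}"])
        x = (p[f"ff_{pat}"] + p[f"oo_FF_{pat}"] - p[f"vv_FF_{pat}"]
             - 2.0 * p[f"sixFF_{pat}"])
        b_half = (- p[f"e62_{pat}"] - 2.0 * p[f"e63_{pat}"] + p[f"e64_{pat}"]
                  + p[f"U_{pat}"] + p[f"T_{pat}"])
        if commutator_level == "full":
            b_half = b_half + 0.5 * gsq * p[f"ff_{pat}"] + p[f"e61_{pat}"]
        b = 2.0 * b_half
        ref.v_pairs[pat] = v
        ref.x_pairs[pat] = x
        ref.b_pairs[pat] = b
        if pat == "x":
            out.v_exchange, out.x_exchange = float(v.sum()), float(x.sum())
            out.xw_exchange = float((wsum * x).sum())
            out.b_exchange = float(b.sum())
        else:
            out.v_direct, out.x_direct = float(v.sum()), float(x.sum())
            out.xw_direct = float((wsum * x).sum())
            out.b_direct = float(b.sum())
    return ref


def approximate_projector_v(spaces: OrbitalSpaces, gamma: float = 1.3,
                            n_fit: int = 6) -> dict[str, float]:
    """Exchange-pattern V with the conventional approximate projector
    1 - p1 p2 - o1 p2'' - p1'' o2 (CABS-RI), with exact integrals; returned
    alongside the ingredients for comparison with the exact-projector V."""
    sp = spaces
    obs, union = sp.obs, sp.union_basis
    Co, Cu = sp.reference.C, sp.C_union
    act, occ = sp.mo_slice("act"), sp.mo_slice("occ")
    p = sp.mo_slice("p")
    cab = sp.mo_slice("cabs")
    kF = KernelSpec("F", gamma, n_fit)
    kG = KernelSpec("G", gamma, n_fit)
    mulF = _mo4(eri_4c2e(kF, obs, obs, obs, obs), Co, Co, Co, Co)
    mulG = _mo4(eri_4c2e(kG, obs, obs, obs, obs), Co, Co, Co, Co)
    mixF = np.einsum("mMls,mx,Mp,ly,sz->xpyz",
                     eri_4c2e(kF, obs, union, obs, obs), Co, Cu, Co, Co,
                     optimize=True)
    mixG = np.einsum("mMls,mx,Mp,ly,sz->xpyz",
                     eri_4c2e(kG, obs, union, obs, obs), Co, Cu, Co, Co,
                     optimize=True)
    fg_x = float(np.einsum("ijji->", _mo4(
        eri_4c2e(KernelSpec("FG", gamma, n_fit), obs, obs, obs, obs),
        Co, Co, Co, Co)[act, act, act, act]))
    # - sum_pq <ij|F|pq><pq|G|ji>
    t_pq = float(np.einsum("ipjq,pjqi->", mulF[act, p, act, p],
                           mulG[p, act, p, act], optimize=True))
    # - sum_{k p''} <ij|F|k p''><k p''|G|ji>, plus the mirror with the CABS
    # index on electron 1 (equal after pair summation):
    #   <ij|F|k p''> = (j p''|F|i k) ; <k p''|G|ji> = (i p''|G|k j)
    t_ocv = float(np.einsum("jpik,ipkj->", mixF[act, cab, act, occ],
                            mixG[act, cab, occ, act], optimize=True))
    v_ex = fg_x - t_pq - 2.0 * t_ocv
    return {"v_exchange_approx": v_ex, "fg_x": fg_x, "t_pq": t_pq,
            "t_ocv": t_ocv}
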