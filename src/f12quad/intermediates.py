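"""Assembly of the exchange-type F12 intermediates V, X, B.

The pair-summed intermediates (both index patterns, 'exchange' <ij|..|ji>
and 'direct' <ij|..|ij>) are built from the generic engine paths:

V = FG-term + occ-occ product - virt-virt product - 2 x 6c3e term
X = F2-term + occ-occ product - virt-virt product - 2 x 6c3e term (F kernels)
B = 2 x [ 1/2 gamma^2 F2-term + (f+k) single-RI term - exchange-operator
          6c3e term - 2 x (f o1) 6c3e term + (o1 f o1) 6c3e term
          + U intermediate + T intermediate ]

The B term list realizes the reduced projector table (see `projector`): the
Fock operator enters through the commutator relation (kinetic part becomes
gamma^2 x F2, handled analytically; the (f+k) part via one full-RI
insertion), the k1 / f1 o1 / o1 f1 o1 combinations as density-dressed 6c3e
contractions sharing one evaluation pass, and the remaining products of 4c2e
integrals through the U (occupied) and T (virtual) intermediates whose
union-space contraction is performed first, on scaled grid MOs. The
(g|F|i p'') block is never formed.

All quadrature terms accumulate per-batch partial sums combined with
compensated (fsum) summation, making results independent of grid/aux
batching to round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet
from .integrals import eri_2c2e, eri_3c2e, grid_3c1e
from .kernels import KernelSpec
from .nq_engine import (DfFitBlock, OpCounters, contract_6c3e_ao,
                        mo_transform_3c1e, product_4c2e_df,
                        product_4c2e_nq_df)
from .quadrature import (ConfigurationError, MolecularGrid,
                         ScreeningContext, eval_aos)
from .spaces import OrbitalSpaces

DF_METRIC_DROP = 1e-10


@dataclass
class ExchangeIntermediates:
    """Pair-summed intermediate values (hartree) and per-term breakdown."""
    v_exchange: float = 0.0
    v_direct: float = 0.0
    x_exchange: float = 0.0
    x_direct: float = 0.0
    xw_exchange: float = 0.0   # sum_ij (eps_i + eps_j) X^ij, exchange pattern
    xw_direct: float = 0.0
    b_exchange: float = 0.0
    b_direct: float = 0.0
    terms: dict[str, float] = field(default_factory=dict)
    counters: OpCounters = field(default_factory=OpCounters)
    mode: str = "nq"
    commutator_level: str = "full"


def _fsum(parts: list[float]) -> float:
    return math.fsum(parts)


class IntermediateBuilder:
    """Orchestrates the batchwise evaluation of every V/X/B ingredient."""

    def __init__(self, spaces: OrbitalSpaces, grid: MolecularGrid,
                 df_aux: BasisSet, gamma: float = 1.3, n_fit: int = 6,
                 theta_nq: float = 1e-10, ao_threshold: float = 1e-14,
                 aux_batch: int = 16, mo_sub_batch: int = 16,
                 commutator_level: str = "full", mode: str = "nq",
                 kl_family: str = "occ") -> None:
        if mode not in ("nq", "df_only"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        if commutator_level not in ("full", "none"):
            raise ConfigurationError(
                f"unknown commutator_level {commutator_level!r}")
        if kl_family not in ("occ", "act"):
            raise ConfigurationError(f"kl_family must be occ or act")
        self.sp = spaces
        self.grid = grid
        self.df_aux = df_aux
        self.gamma = gamma
        self.theta_nq = theta_nq
        self.ao_threshold = ao_threshold
        self.aux_batch = aux_batch
        self.mo_sub_batch = mo_sub_batch
        self.commutator_level = commutator_level
        self.mode = mode
        self.kl_family = kl_family
        self.kern = {tag: KernelSpec(tag, gamma, n_fit)
                     for tag in ("F", "G", "FG", "F2")}
        self.counters = OpCounters()
        self._precompute()

    # ------------------------------------------------------------------
    def _metric_inverse(self, Y: np.ndarray) -> np.ndarray:
        """Pseudo-inverse of the operator metric. The Coulomb metric is
        positive definite; the geminal metric is the *negative* of a
        completely monotone kernel's (positive definite) matrix, so the
        defect check is sign-aware: all retained eigenvalues must share one
        sign."""
        w, V = np.linalg.eigh(Y)
        amax = np.abs(w).max()
        sign = 1.0 if abs(w.max()) >= abs(w.min()) else -1.0
        ws = sign * w
        if ws.min() < -1e-8 * amax:
            raise RuntimeError(
                "DF metric indefinite: integral-engine defect")
        keep = ws > DF_METRIC_DROP * amax
        return (V[:, keep] / w[keep]) @ V[:, keep].T

    def _precompute(self) -> None:
        sp = self.sp
        obs, union = sp.obs, sp.union_basis
        C = sp.C_union                      # union AO x union MO
        nobs = obs.n_ao
        self.C_obs = sp.reference.C         # obs AO x p
        occ, act, virt = sp.mo_slice("occ"), sp.mo_slice("act"), sp.mo_slice("virt")
        self.sl = {"occ": occ, "act": act, "virt": virt}
        Co = self.C_obs
        self.C_occ_o = Co[:, occ]
        self.C_act_o = Co[:, act]
        self.C_virt_o = Co[:, virt]
        self.C_kl_o = Co[:, occ if self.kl_family == "occ" else act]
        self.eps_act = sp.eps[act]

        # AO densities over the orbital basis
        self.P_act = self.C_act_o @ self.C_act_o.T
        self.P_kl = self.C_kl_o @ self.C_kl_o.T
        self.P_act_w = (self.C_act_o * self.eps_act) @ self.C_act_o.T

        # middle dressings for the B 6c3e terms, built from MO matrices so the
        # GBC/EBC treatment of f is consistent across all paths
        f, k = sp.f_mo, sp.k_mo
        self.C62 = C @ k @ C.T                                  # Pi k Pi
        self.C63 = self.C_occ_o @ f[occ, :] @ C.T               # (obs AO x union AO)
        self.C64 = self.C_occ_o @ f[occ, occ] @ self.C_occ_o.T
        self.fk_act_u = (f + k)[act, :]                         # (n_act x n_union)

        # scaled-MO matrices for the U and T intermediates: subspace term
        # coefficients folded into one Fock-weighted map (linearity makes the
        # standalone and shared-pass evaluations identical)
        nU = sp.n_union
        nocc = sp.n_occ
        occ_ind = np.zeros(nU)
        occ_ind[:nocc] = 1.0
        virt_ind = np.zeros(nU)
        virt_ind[sp.n_occ:sp.n_p] = 1.0
        cU = (-1.0 + 2.0 * occ_ind[None, :]
              - occ_ind[:, None] * occ_ind[None, :])
        self.M_U = cU * f                                       # (p', r')
        cT = -2.0 + virt_ind[:, None]
        self.M_T = (cT * f)[:, sp.mo_slice("virt")]             # (p', b)

        # ---- density fitting blocks (F kernel; plain operator metric) ----
        YF = eri_2c2e(self.kern["F"], self.df_aux)
        self.YF_inv = self._metric_inverse(YF)
        a3 = eri_3c2e(self.kern["F"], union, obs, self.df_aux)  # (uao,oao,R)
        self.rawF = np.einsum("MnR,Mp,nq->Rpq", a3, C, Co, optimize=True)
        self.fitF = np.einsum("QP,Qab->Pab", self.YF_inv, self.rawF,
                              optimize=True)
        if self.mode == "df_only":
            YG = eri_2c2e(self.kern["G"], self.df_aux)
            self.YG_inv = self._metric_inverse(YG)
            g3 = eri_3c2e(self.kern["G"], union, obs, self.df_aux)
            self.rawG = np.einsum("MnR,Mp,nq->Rpq", g3, C, Co, optimize=True)
            self.fitG = np.einsum("QP,Qab->Pab", self.YG_inv, self.rawG,
                                  optimize=True)

        # screening contexts (pair bounds precomputed per kernel)
        self.scr = {
            ("F", "ou"): ScreeningContext(obs, union, self.kern["F"]),
            ("G", "oo"): ScreeningContext(obs, obs, self.kern["G"]),
            ("FG", "oo"): ScreeningContext(obs, obs, self.kern["FG"]),
            ("F2", "oo"): ScreeningContext(obs, obs, self.kern["F2"]),
        }

    # ------------------------------------------------------------------
    def _mo(self, tensor: np.ndarray, Cl: np.ndarray, Cr: np.ndarray):
        return mo_transform_3c1e(tensor, Cl, Cr, self.mo_sub_batch,
                                 self.counters)

    def _slice_fit(self, rows, cols) -> np.ndarray:
        r = slice(None) if rows == "union" else self.sl[rows]
        return self.fitF[:, r, self.sl[cols]]

    # ------------------------------------------------------------------
    def run(self) -> ExchangeIntermediates:
        parts: dict[str, list[float]] = {}

        def acc(name: str, value: float) -> None:
            parts.setdefault(name, []).append(value)

        sp = self.sp
        obs, union = sp.obs, sp.union_basis
        nobs = obs.n_ao
        th = self.theta_nq
        gsq = self.gamma * self.gamma
        kl = self.sl["occ"] if self.kl_family == "occ" else self.sl["act"]
        C_kl = self.C_kl_o
        fitF_kl_j = self._slice_fit("act", "occ" if self.kl_family == "occ" else "act")
        raw_kl_i = self.rawF[:, kl, self.sl["act"]]
        fit_virt = self._slice_fit("act", "virt")
        raw_virt = self.rawF[:, self.sl["virt"], self.sl["act"]]
        fit_U = self.fitF[:, :, self.sl["act"]]        # (R, p', j)
        raw_U = self.rawF[:, self.sl["act"], kl]       # (R, i, m)
        fit_T = self.fitF[:, self.sl["virt"], self.sl["act"]]  # (R, b, j)
        raw_T = self.rawF[:, self.sl["act"], self.sl["virt"]]  # (R, i, c)
        eps = self.eps_act

        if self.mode == "df_only":
            self._df_only_products(parts, acc)

        for batch in self.grid.batches:
            w = batch.weights
            pts = batch.points
            chi_o = eval_aos(batch, obs, self.ao_threshold)
            chi_u = eval_aos(batch, union, self.ao_threshold)
            if th > 0.0:
                # screening audit count for the report
                for scr in self.scr.values():
                    self.counters.add("screened_shell_pairs",
                                      float((scr.bounds(batch) < th).sum()))

            F_ou = grid_3c1e(self.kern["F"], obs, union, pts,
                             self.scr[("F", "ou")].pair_skip(batch, th))
            F_oo = F_ou[:, :, :nobs]
            G_oo = grid_3c1e(self.kern["G"], obs, obs, pts,
                             self.scr[("G", "oo")].pair_skip(batch, th))
            FG_oo = grid_3c1e(self.kern["FG"], obs, obs, pts,
                              self.scr[("FG", "oo")].pair_skip(batch, th))
            F2_oo = grid_3c1e(self.kern["F2"], obs, obs, pts,
                              self.scr[("F2", "oo")].pair_skip(batch, th))

            phi_act = chi_o.T @ self.C_act_o       # (m, n_act)
            phi_kl = chi_o.T @ C_kl
            phi_virt = chi_o.T @ self.C_virt_o
            phi_u = chi_u.T @ sp.C_union           # (m, n_union)
            phiU = phi_u @ self.M_U                # scaled MOs, U (m, r')
            phiT = phi_u @ self.M_T                # scaled MOs, T (m, b)
            self.counters.add("scaled_mo_union", len(w) * sp.n_union ** 2)

            # MO 3c1e blocks (kl x act); (g|F|j m) etc. come via transposes
            gG = self._mo(G_oo, C_kl, self.C_act_o)
            gGv = self._mo(G_oo, self.C_virt_o, self.C_act_o)
            gF = self._mo(F_oo, C_kl, self.C_act_o)
            gFv = self._mo(F_oo, self.C_virt_o, self.C_act_o)

            # ---------------- V and X: FG / F2 terms ----------------
            for name, blk, A, B2 in (
                    ("term_fg", FG_oo, self.P_act, self.P_act),
                    ("term_f2", F2_oo, self.P_act, self.P_act),
                    ("term_f2w", F2_oo, self.P_act_w, self.P_act)):
                a = A.T @ chi_o
                b = B2.T @ chi_o
                acc(name + "_x", float(np.einsum(
                    "g,lg,gls,sg->", w, a, blk, b)))
                rho = np.einsum("lg,ls,sg->g", chi_o, B2, chi_o)
                tr = np.einsum("gls,ls->g", blk, A)
                acc(name + "_d", float(np.einsum("g,g,g->", w, rho, tr)))
                self.counters.add("alg12_pair", 2 * len(w) * nobs * nobs)

            # ---------------- V and X: 4c2e products (hybrid) ----------------
            if self.mode == "nq":
                for name, grid_blk, fit, raw in (
                        ("term_oo_FG", gG, fitF_kl_j, raw_kl_i),
                        ("term_vv_FG", gGv, fit_virt, raw_virt),
                        ("term_oo_FF", gF, fitF_kl_j, raw_kl_i),
                        ("term_vv_FF", gFv, fit_virt, raw_virt)):
                    phi_r = phi_kl if name in ("term_oo_FG", "term_oo_FF") else phi_virt
                    raw_d = np.ascontiguousarray(raw.transpose(0, 2, 1))
                    acc(name + "_x", product_4c2e_nq_df(
                        grid_blk, DfFitBlock(fit), raw, phi_act, phi_r, w,
                        "exchange", self.aux_batch, counters=self.counters))
                    # direct: both grid MOs contract the fit pairs (i, k)
                    acc(name + "_d", product_4c2e_nq_df(
                        grid_blk, DfFitBlock(fit), raw_d,
                        phi_act, None, w, "direct", self.aux_batch,
                        phi_fit2=phi_r, counters=self.counters))
                    if name in ("term_oo_FF", "term_vv_FF"):
                        acc(name + "w_x", product_4c2e_nq_df(
                            grid_blk, DfFitBlock(fit), raw * eps[None, None, :],
                            phi_act, phi_r, w, "exchange", self.aux_batch,
                            counters=self.counters))
                        acc(name + "w_d", product_4c2e_nq_df(
                            grid_blk, DfFitBlock(fit * eps[None, :, None]),
                            raw_d, phi_act, None, w,
                            "direct", self.aux_batch, phi_fit2=phi_r,
                            counters=self.counters))

            # ---------------- V and X: 6c3e terms ----------------
            for name, Wb, Yb in (("term_six_FG", F_oo, G_oo),
                                 ("term_six_FF", F_oo, F_oo)):
                acc(name + "_x", contract_6c3e_ao(
                    self.P_act, self.P_act, self.P_kl, Wb, Yb, chi_o, w,
                    "exchange", self.counters))
                acc(name + "_d", contract_6c3e_ao(
                    self.P_act, self.P_act, self.P_kl, Wb, Yb, chi_o, w,
                    "direct", self.counters))
                if name == "term_six_FF":
                    # eps-weighted variants: weight on either active slot
                    acc(name + "w_x", contract_6c3e_ao(
                        self.P_act_w, self.P_act, self.P_kl, Wb, Yb, chi_o,
                        w, "exchange", self.counters)
                        + contract_6c3e_ao(
                        self.P_act, self.P_act_w, self.P_kl, Wb, Yb, chi_o,
                        w, "exchange", self.counters))
                    acc(name + "w_d", contract_6c3e_ao(
                        self.P_act_w, self.P_act, self.P_kl, Wb, Yb, chi_o,
                        w, "direct", self.counters)
                        + contract_6c3e_ao(
                        self.P_act, self.P_act_w, self.P_kl, Wb, Yb, chi_o,
                        w, "direct", self.counters))

            # ---------------- B: commutator add-on (f+k) single-RI ----------------
            if self.commutator_level == "full":
                F2mo = self._mo(F2_oo, self.C_act_o, self.C_act_o)
                D = self.fk_act_u @ phi_u.T          # (n_act, m)
                acc("term_fk_ri_x", float(np.einsum(
                    "g,gj,gij,ig->", w, phi_act, F2mo, D)))
                rho_f2 = np.einsum("gjj->g", F2mo)
                acc("term_fk_ri_d", float(np.einsum(
                    "g,g,gi,ig->", w, rho_f2, phi_act, D)))
                self.counters.add("fk_ri_term", len(w) * sp.n_act * sp.n_union)

            # ---------------- B: dressed 6c3e insertions (one shared pass) ----------------
            for name, Wb, Yb, Cmid in (
                    ("term_k_ri", F_ou, F_ou, self.C62),
                    ("term_fo_ri", F_oo, F_ou, self.C63),
                    ("term_ofo", F_oo, F_oo, self.C64)):
                acc(name + "_x", contract_6c3e_ao(
                    self.P_act, self.P_act, Cmid, Wb, Yb, chi_o, w,
                    "exchange", self.counters))
                acc(name + "_d", contract_6c3e_ao(
                    self.P_act, self.P_act, Cmid, Wb, Yb, chi_o, w,
                    "direct", self.counters))

            # ---------------- B: U and T intermediates (hybrid) ----------------
            if self.mode == "nq":
                gFjm = gF.transpose(0, 2, 1)      # (g|F|j m), m in kl family
                gFjc = gFv.transpose(0, 2, 1)     # (g|F|j c)
                acc("term_U_x", product_4c2e_nq_df(
                    gFjm, DfFitBlock(fit_U), raw_U, phiU, phi_act, w,
                    "exchange", self.aux_batch, counters=self.counters))
                acc("term_U_d", product_4c2e_nq_df(
                    gFjm, DfFitBlock(np.ascontiguousarray(
                        fit_U.transpose(0, 2, 1))),
                    raw_U.transpose(0, 2, 1), phi_act, None, w, "direct",
                    self.aux_batch, phi_fit2=phiU, counters=self.counters))
                acc("term_T_x", product_4c2e_nq_df(
                    gFjc, DfFitBlock(fit_T), raw_T, phiT, phi_act, w,
                    "exchange", self.aux_batch, counters=self.counters))
                acc("term_T_d", product_4c2e_nq_df(
                    gFjc, DfFitBlock(np.ascontiguousarray(
                        fit_T.transpose(0, 2, 1))),
                    raw_T.transpose(0, 2, 1), phi_act, None, w, "direct",
                    self.aux_batch, phi_fit2=phiT, counters=self.counters))

        # ------------------------------------------------------------------
        terms = {name: _fsum(vals) for name, vals in parts.items()}
        out = ExchangeIntermediates(terms=terms, counters=self.counters,
                                    mode=self.mode,
                                    commutator_level=self.commutator_level)
        t = terms

        def g(name: str) -> float:
            return t.get(name, 0.0)

        for pat in ("x", "d"):
            v = (g(f"term_fg_{pat}") + g(f"term_oo_FG_{pat}")
                 - g(f"term_vv_FG_{pat}") - 2.0 * g(f"term_six_FG_{pat}"))
            x = (g(f"term_f2_{pat}") + g(f"term_oo_FF_{pat}")
                 - g(f"term_vv_FF_{pat}") - 2.0 * g(f"term_six_FF_{pat}"))
            # eps-weighted X: one-slot weighted evaluations doubled
            xw = (2.0 * g(f"term_f2w_{pat}") + 2.0 * g(f"term_oo_FFw_{pat}")
                  - 2.0 * g(f"term_vv_FFw_{pat}") - 2.0 * g(f"term_six_FFw_{pat}"))
            b_half = (- g(f"term_k_ri_{pat}") - 2.0 * g(f"term_fo_ri_{pat}")
                      + g(f"term_ofo_{pat}") + g(f"term_U_{pat}")
                      + g(f"term_T_{pat}"))
            if self.commutator_level == "full":
                b_half += (0.5 * gsq * g(f"term_f2_{pat}")
                           + g(f"term_fk_ri_{pat}"))
            b = 2.0 * b_half
            if pat == "x":
                out.v_exchange, out.x_exchange = v, x
                out.xw_exchange, out.b_exchange = xw, b
            else:
                out.v_direct, out.x_direct = v, x
                out.xw_direct, out.b_direct = xw, b
        terms["term_del2f_x"] = gsq * g("term_f2_x")
        terms["term_del2f_d"] = gsq * g("term_f2_d")
        return out

    # ------------------------------------------------------------------
    def _df_only_products(self, parts, acc) -> None:
        """O(M^5) DF-only evaluation of every product of two 4c2e integrals
        (the comparator the hybrid path is benchmarked against)."""
        sl = self.sl
        kl = sl["occ"] if self.kl_family == "occ" else sl["act"]
        eps = self.eps_act
        fitF_ik = self.fitF[:, sl["act"], kl]
        rawF_jl = self.rawF[:, sl["act"], kl]
        fitG_kj = self.fitG[:, kl, sl["act"]]
        rawG_li = self.rawG[:, kl, sl["act"]]
        fitF_kj = self.fitF[:, kl, sl["act"]]
        rawF_li = self.rawF[:, kl, sl["act"]]
        fitF_ia = self.fitF[:, sl["act"], sl["virt"]]
        rawF_jb = self.rawF[:, sl["act"], sl["virt"]]
        fitG_aj = self.fitG[:, sl["virt"], sl["act"]]
        rawG_bi = self.rawG[:, sl["virt"], sl["act"]]
        fitF_aj = self.fitF[:, sl["virt"], sl["act"]]
        rawF_bi = self.rawF[:, sl["virt"], sl["act"]]

        specs = [
            ("term_oo_FG", fitF_ik, rawF_jl, fitG_kj, rawG_li, None),
            ("term_vv_FG", fitF_ia, rawF_jb, fitG_aj, rawG_bi, None),
            ("term_oo_FF", fitF_ik, rawF_jl, fitF_kj, rawF_li, None),
            ("term_vv_FF", fitF_ia, rawF_jb, fitF_aj, rawF_bi, None),
            ("term_oo_FFw", fitF_ik * eps[None, :, None], rawF_jl,
             fitF_kj, rawF_li, None),
            ("term_vv_FFw", fitF_ia * eps[None, :, None], rawF_jb,
             fitF_aj, rawF_bi, None),
        ]
        for name, fw, rw, fy, ry, _ in specs:
            acc(name + "_x", product_4c2e_df(
                DfFitBlock(fw), rw, DfFitBlock(fy), ry, "exchange",
                self.counters))
            acc(name + "_d", product_4c2e_df(
                DfFitBlock(fw), rw, DfFitBlock(fy), ry, "direct",
                self.counters))

        # U and T groups entirely via DF.
        # U: sum <ij|F|p'm> M_U[p',r'] <r'm|F|ji>;  T analogously with the
        # DF-side index restricted to virtuals (M_T columns).
        fit_p_i = self.fitF[:, :, sl["act"]]       # (R, p', i/j)
        for name, M, msl, fit_rhs in (
                ("term_U", self.M_U, kl, self.fitF[:, :, sl["act"]]),
                ("term_T", self.M_T, sl["virt"],
                 self.fitF[:, sl["virt"], sl["act"]])):
            raw_jm = self.rawF[:, sl["act"], msl]          # (R, j, m/c)
            raw_mi = self.rawF[:, msl, sl["act"]]          # (R, m/c, i)
            nR, nP_, ni_ = fit_p_i.shape
            nm_ = raw_jm.shape[2]
            # W4[i, p', j, m] = <ij|F|p'm> = (i p'|F|j m)
            W4 = np.einsum("Rpi,Rjm->ipjm", fit_p_i, raw_jm, optimize=True)
            self.counters.add("df_only_w4", nR * nP_ * ni_ * ni_ * nm_)
            # exchange: <r'm|F|ji> = (r'j|F|mi)
            Y4x = np.einsum("Rrj,Rmi->rjmi", fit_rhs, raw_mi, optimize=True)
            self.counters.add("df_only_y4",
                              nR * fit_rhs.shape[1] * ni_ * ni_ * nm_)
            acc(name + "_x", float(np.einsum(
                "ipjm,pr,rjmi->", W4, M, Y4x, optimize=True)))
            # direct: <r'm|F|ij> = (r'i|F|mj)
            Y4d = np.einsum("Rri,Rmj->rimj", fit_rhs, raw_mi, optimize=True)
            self.counters.add("df_only_y4",
                              nR * fit_rhs.shape[1] * ni_ * ni_ * nm_)
            acc(name + "_d", float(np.einsum(
                "ipjm,pr,rimj->", W4, M, Y4d, optimize=True)))
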