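"""Generic contraction paths for exchange-type F12 terms.

Four families of contractions, all parameterized over kernels, density
dressings and index pairings:

* ``contract_6c3e_mo``   three-electron integrals, MO picture (per batch)
* ``contract_6c3e_ao``   three-electron integrals, AO picture with density
                         dressings; both exchange and direct index patterns
* ``product_4c2e_nq_df`` products of two 4c2e integrals via one factor on the
                         quadrature grid and the other density-fitted
* ``product_4c2e_df``    the same products entirely via density fitting (the
                         O(M^5) comparator path)

Every path counts its floating-point contraction work (products of loop
dimensions) in an `OpCounters` so the formal-scaling separation between the
hybrid O(M^4) and DF-only O(M^5) routes can be measured in counts rather
than wall time. Per-batch partial energies are accumulated by the callers
with compensated (fsum) summation so batching never changes results beyond
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quadrature import ConfigurationError

DEFAULT_AUX_BATCH = 16
DEFAULT_MO_SUB_BATCH = 16


class OpCounters(dict):
    """Named operation counters (floating point multiply-add estimates)."""

    def add(self, name: str, n: float) -> None:
        self[name] = self.get(name, 0.0) + float(n)

    @property
    def dominant(self) -> float:
        return max(self.values(), default=0.0)

    @property
    def total(self) -> float:
        return float(sum(self.values()))


@dataclass
class DensityDressing:
    """An AO (or union-AO) matrix with a semantic tag; symmetric tags are
    validated on construction."""
    matrix: np.ndarray
    tag: str = "custom"  # occupied | eps_weighted | ri_projector | fock | exchange | virtual | custom

    _SYMMETRIC = {"occupied", "eps_weighted", "ri_projector", "exchange", "virtual"}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if self.tag in self._SYMMETRIC:
            if m.shape[0] != m.shape[1] or np.abs(m - m.T).max() > 1e-10:
                raise ValueError(f"dressing tagged {self.tag!r} must be symmetric")
        self.matrix = m


@dataclass
class DfFitBlock:
    """Fitted coefficients C[P, a, b] with sum_Q Yinv[P,Q] (ab|O|Q), so that
    (ab|O|cd) ~= sum_P C[P,a,b] raw[P,c,d]."""
    fit: np.ndarray          # (nP, na, nb)
    operator_tag: str = ""


def df_fit_pairs(raw: np.ndarray, metric_inv: np.ndarray,
                 operator_tag: str = "",
                 counters: OpCounters | None = None) -> DfFitBlock:
    """raw[P, a, b] = (ab|O|P)  ->  fitted coefficients (step 1 of the
    stepwise product evaluation)."""
    if raw.shape[0] != metric_inv.shape[1]:
        raise ValueError("metric inverse and 3c2e block dimensions mismatch")
    fit = np.einsum("QP,Qab->Pab", metric_inv, raw)
    if counters is not None:
        counters.add("df_fit_pairs", raw.size * metric_inv.shape[0])
    return DfFitBlock(fit=fit, operator_tag=operator_tag)


# ----------------------------------------------------------------------------
# 6c3e contractions
# ----------------------------------------------------------------------------

def contract_6c3e_mo(W_block: np.ndarray, Y_block: np.ndarray,
                     phi_i: np.ndarray, phi_j: np.ndarray,
                     weights: np.ndarray,
                     counters: OpCounters | None = None) -> float:
    """sum_g w_g [phi_i^g (g|W|ik)] [phi_j^g (g|Y|kj)] summed over i, j, k.

    W_block: (m, ni, nk); Y_block: (m, nk, nj); phi_i: (m, ni); phi_j: (m, nj).
    """
    m, ni, nk = W_block.shape
    if Y_block.shape[0] != m or Y_block.shape[1] != nk:
        raise ValueError("6c3e MO blocks must share the grid batch and k space")
    nj = Y_block.shape[2]
    Wg = np.einsum("gi,gik->gk", phi_i, W_block)
    Yg = np.einsum("gj,gkj->gk", phi_j, Y_block)
    e = float(np.einsum("g,gk,gk->", weights, Wg, Yg))
    if counters is not None:
        counters.add("6c3e_mo_step1", m * ni * nk)
        counters.add("6c3e_mo_step2", m * nj * nk)
        counters.add("6c3e_mo_step3", m * nk)
    return e


def contract_6c3e_ao(A: np.ndarray, B: np.ndarray, C: np.ndarray,
                     W_block: np.ndarray, Y_block: np.ndarray,
                     chi: np.ndarray, weights: np.ndarray,
                     pattern: str = "exchange",
                     counters: OpCounters | None = None) -> float:
    """AO-picture 6c3e contraction over one batch.

    exchange:  sum_g w_g  (A^T chi_g)^T W_g  C  Y_g^T (B^T chi_g)
    direct:    sum_g w_g  [chi_g^T B chi_g] * einsum(A, W_g, C, Y_g)
               with A joining the chi-side indices of W and Y and C joining
               their operator-side indices.

    W_block: (m, nao, d1); Y_block: (m, nao, d2); C: (d1, d2);
    A, B: (nao, nao) dressings; chi: (nao, m).
    """
    m = len(weights)
    nao = chi.shape[0]
    if W_block.shape[:2] != (m, nao) or Y_block.shape[:2] != (m, nao):
        raise ValueError("6c3e AO blocks inconsistent with batch/chi")
    if C.shape != (W_block.shape[2], Y_block.shape[2]):
        raise ValueError("middle dressing C has wrong shape")
    if pattern == "exchange":
        chiA = A.T @ chi          # (nao, m)
        chiB = B.T @ chi
        tW = np.einsum("lg,gla->ga", chiA, W_block)
        tY = np.einsum("sg,gsb->gb", chiB, Y_block)
        e = float(np.einsum("g,ga,ab,gb->", weights, tW, C, tY))
        if counters is not None:
            counters.add("6c3e_ao_dress", 2 * m * nao * nao)
            counters.add("6c3e_ao_w", m * nao * W_block.shape[2])
            counters.add("6c3e_ao_y", m * nao * Y_block.shape[2])
            counters.add("6c3e_ao_mid", m * C.size)
        return e
    if pattern == "direct":
        rho = np.einsum("lg,ls,sg->g", chi, B, chi)
        t1 = np.einsum("ls,gla->gsa", A, W_block)      # join chi-side via A
        e = float(np.einsum("g,g,gsa,ab,gsb->", weights, rho, t1, C, Y_block))
        if counters is not None:
            counters.add("6c3e_ao_rho", m * nao * nao)
            counters.add("6c3e_ao_direct", m * nao * nao * max(C.shape))
        return e
    raise ConfigurationError(f"unknown 6c3e pattern {pattern!r}")


# ----------------------------------------------------------------------------
# products of two 4c2e integrals
# ----------------------------------------------------------------------------

def product_4c2e_nq_df(grid_W: np.ndarray, fit: DfFitBlock, raw: np.ndarray,
                       phi_fit: np.ndarray, phi_raw: np.ndarray,
                       weights: np.ndarray, pattern: str = "exchange",
                       aux_batch: int = DEFAULT_AUX_BATCH,
                       phi_fit2: np.ndarray | None = None,
                       counters: OpCounters | None = None) -> float:
    """Hybrid NQ+DF product of two 4c2e integrals over one grid batch.

    exchange (the stepwise path; fit pairs (a,b), raw pairs (c,d)):
        s2:  A[P,b,g]  = phi_fit[g,a]  fit[P,a,b]
        s3:  Bt[P,g,d] = phi_raw[g,c]  raw[P,c,d]
        s4:  M[g,b,d]  = A[P,b,g] Bt[P,g,d]            (aux-batched)
        s5:  E += w_g grid_W[g,b,d] M[g,b,d]

    direct (both grid MOs contract the fit side; phi_fit2 required):
        c[P,g]  = phi_fit[g,a] phi_fit2[g,b] fit[P,a,b]
        D[g,c,d]= c[P,g] raw[P,c,d]                    (aux-batched)
        E += w_g grid_W[g,d,c] D[g,c,d]
    """
    if aux_batch < 1:
        raise ConfigurationError("aux_batch must be >= 1")
    nP = fit.fit.shape[0]
    m = len(weights)
    e = 0.0
    if pattern == "exchange":
        M = np.zeros((m, fit.fit.shape[2], raw.shape[2]))
        for lo in range(0, nP, aux_batch):
            fc = fit.fit[lo:lo + aux_batch]
            rc = raw[lo:lo + aux_batch]
            A = np.einsum("ga,Pab->Pbg", phi_fit, fc)
            Bt = np.einsum("gc,Pcd->Pgd", phi_raw, rc)
            M += np.einsum("Pbg,Pgd->gbd", A, Bt)
            if counters is not None:
                nPc = fc.shape[0]
                counters.add("nqdf_step2", m * nPc * fc.shape[1] * fc.shape[2])
                counters.add("nqdf_step3", m * nPc * rc.shape[1] * rc.shape[2])
                counters.add("nqdf_step4", m * nPc * fc.shape[2] * rc.shape[2])
        e = float(np.einsum("g,gbd,gbd->", weights, grid_W, M))
        if counters is not None:
            counters.add("nqdf_step5", grid_W.size)
        return e
    if pattern == "direct":
        if phi_fit2 is None:
            raise ConfigurationError("direct pattern needs phi_fit2")
        D = np.zeros((m, raw.shape[1], raw.shape[2]))
        for lo in range(0, nP, aux_batch):
            fc = fit.fit[lo:lo + aux_batch]
            rc = raw[lo:lo + aux_batch]
            c = np.einsum("ga,gb,Pab->Pg", phi_fit, phi_fit2, fc)
            D += np.einsum("Pg,Pcd->gcd", c, rc)
            if counters is not None:
                nPc = fc.shape[0]
                counters.add("nqdf_step2", m * nPc * fc.shape[1] * fc.shape[2])
                counters.add("nqdf_step4", m * nPc * rc.shape[1] * rc.shape[2])
        e = float(np.einsum("g,gdc,gcd->", weights, grid_W, D))
        if counters is not None:
            counters.add("nqdf_step5", grid_W.size)
        return e
    raise ConfigurationError(f"unknown product pattern {pattern!r}")


def product_4c2e_df(fit_W: DfFitBlock, raw_W: np.ndarray,
                    fit_Y: DfFitBlock, raw_Y: np.ndarray,
                    pattern: str = "exchange",
                    counters: OpCounters | None = None) -> float:
    """DF-only product of two 4c2e integrals (the O(M^5) reference path).

    exchange:  <ij|W|kl><kl|Y|ji> = [fitW(ik) rawW(jl)] [fitY(kj) rawY(li)]
    direct:    <ij|W|kl><kl|Y|ij> = [fitW(ik) rawW(jl)] [fitY(ki) rawY(lj)]
    """
    nP = fit_W.fit.shape[0]
    ni, nk = fit_W.fit.shape[1], fit_W.fit.shape[2]
    nj, nl = raw_W.shape[1], raw_W.shape[2]
    W4 = np.einsum("Pik,Pjl->ikjl", fit_W.fit, raw_W)
    if counters is not None:
        counters.add("df_only_w4", nP * ni * nk * nj * nl)
    nR = fit_Y.fit.shape[0]
    if pattern == "exchange":
        Y4 = np.einsum("Rkj,Rli->ikjl", fit_Y.fit, raw_Y)
    elif pattern == "direct":
        Y4 = np.einsum("Rki,Rlj->ikjl", fit_Y.fit, raw_Y)
    else:
        raise ConfigurationError(f"unknown product pattern {pattern!r}")
    if counters is not None:
        counters.add("df_only_y4", nR * ni * nk * nj * nl)
        counters.add("df_only_trace", ni * nk * nj * nl)
    return float(np.einsum("ikjl,ikjl->", W4, Y4))


# ----------------------------------------------------------------------------
# MO transformation of grid 3c1e blocks
# ----------------------------------------------------------------------------

def mo_transform_3c1e(tensor: np.ndarray, C_left: np.ndarray,
                      C_right: np.ndarray,
                      sub_batch: int = DEFAULT_MO_SUB_BATCH,
                      counters: OpCounters | None = None) -> np.ndarray:
    """(g|O|mu nu) -> (g|O|pq), transforming in sub-batches of grid points so
    only one AO sub-block is resident at a time. The result is independent of
    the sub-batch size to round-off."""
    m, n1, n2 = tensor.shape
    if C_left.shape[0] != n1 or C_right.shape[0] != n2:
        raise ValueError("coefficient blocks not conformable with tensor")
    out = np.empty((m, C_left.shape[1], C_right.shape[1]))
    for lo in range(0, m, max(sub_batch, 1)):
        blk = tensor[lo:lo + sub_batch]
        out[lo:lo + sub_batch] = np.einsum(
            "gmn,mp,nq->gpq", blk, C_left, C_right, optimize=True)
        if counters is not None:
            mm = blk.shape[0]
            counters.add("mo_transform", mm * n1 * n2 * C_left.shape[1]
                         + mm * n2 * C_left.shape[1] * C_right.shape[1])
    return out
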