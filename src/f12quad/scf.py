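"""Minimal closed-shell RHF reference with DIIS.

This is deliberately small: systems at desk scale, canonical orbitals only.
The density convention is P_munu = sum_i c_mui c_nui (no factor 2), so that
P S P = P and the closed-shell Fock matrix reads f = h + 2J[P] - K[P].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet
from .integrals import eri_4c2e, kinetic, nuclear_attraction, overlap
from .kernels import KernelSpec
from .molecule import Molecule, UnsupportedSystemError


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, trace: list[float] | None = None):
        super().__init__(msg)
        self.trace = trace or []


class ConditioningError(RuntimeError):
    pass


@dataclass
class ReferenceState:
    molecule: Molecule
    basis: BasisSet
    C: np.ndarray            # AO x MO coefficients
    eps: np.ndarray          # orbital energies (hartree)
    P: np.ndarray            # AO density, P = C_occ C_occ^T
    fock: np.ndarray         # AO Fock matrix
    exchange: np.ndarray     # AO exchange matrix K[P]
    energy: float            # total SCF energy (hartree)
    converged_norm: float    # final ||FPS - SPF||
    overlap: np.ndarray = field(repr=False, default=None)

    @property
    def n_occ(self) -> int:
        return self.molecule.n_occ

    def validate(self, tol_orth: float = 1e-9, tol_idem: float = 1e-8,
                 tol_diag: float = 1e-7) -> None:
        S = self.overlap
        n = self.C.shape[1]
        err_orth = np.abs(self.C.T @ S @ self.C - np.eye(n)).max()
        if err_orth > tol_orth:
            raise ValueError(f"C^T S C deviates from identity by {err_orth:.2e}")
        err_idem = np.abs(self.P @ S @ self.P - self.P).max()
        if err_idem > tol_idem:
            raise ValueError(f"P S P deviates from P by {err_idem:.2e}")
        fmo = self.C.T @ self.fock @ self.C
        err_diag = np.abs(fmo - np.diag(np.diag(fmo))).max()
        if err_diag > tol_diag:
            raise ValueError(
                f"non-canonical reference: off-diagonal MO Fock {err_diag:.2e}")


def _jk(eri: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    J = np.einsum("mnls,ls->mn", eri, P)
    K = np.einsum("mlsn,ls->mn", eri, P)
    return J, K


def compute_reference(molecule: Molecule, obs: BasisSet,
                      conv: float = 1e-9, max_iter: int = 200,
                      s_drop: float = 1e-10) -> ReferenceState:
    """Internal RHF backend. Any provider satisfying the ReferenceState
    invariants may stand in; this one uses the package's own Coulomb
    integrals with DIIS and a commutator-norm convergence criterion."""
    if molecule.multiplicity != 1:
        raise UnsupportedSystemError("RHF requires a singlet")
    nocc = molecule.n_occ
    S = overlap(obs)
    h = kinetic(obs) + nuclear_attraction(obs, molecule)
    eri = eri_4c2e(KernelSpec("G"), obs, obs, obs, obs)

    w, V = np.linalg.eigh(S)
    if w.min() < s_drop * w.max():
        keep = w > s_drop * w.max()
        if w.min() < -1e-10:
            raise ConditioningError("overlap matrix not positive semidefinite")
        V = V[:, keep]
        w = w[keep]
    if w.max() / w.min() > 1e12:
        raise ConditioningError(
            f"near-linear dependence in orbital basis (cond {w.max()/w.min():.1e})")
    X = V / np.sqrt(w)  # S^{-1/2} on the retained subspace

    # core guess
    f = h.copy()
    trace: list[float] = []
    diis_f: list[np.ndarray] = []
    diis_e: list[np.ndarray] = []
    P = np.zeros_like(S)
    energy = 0.0
    for it in range(max_iter):
        fo = X.T @ f @ X
        eps, Co = np.linalg.eigh(fo)
        C = X @ Co
        P = C[:, :nocc] @ C[:, :nocc].T
        J, K = _jk(eri, P)
        f = h + 2.0 * J - K
        energy = float(np.einsum("mn,mn->", P, h + f)) + molecule.nuclear_repulsion()
        err = f @ P @ S - S @ P @ f
        norm = float(np.abs(err).max())
        trace.append(norm)
        if norm < conv:
            break
        # DIIS on the commutator residual
        diis_f.append(f.copy())
        diis_e.append(err.copy())
        if len(diis_f) > 8:
            diis_f.pop(0)
            diis_e.pop(0)
        m = len(diis_f)
        if m > 1:
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.einsum("mn,mn->", diis_e[i], diis_e[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                coef = np.linalg.solve(B, rhs)[:m]
                f = sum(c * fi for c, fi in zip(coef, diis_f))
            except np.linalg.LinAlgError:
                pass
    else:
        raise ConvergenceError(
            f"RHF did not reach {conv:.1e} in {max_iter} iterations", trace)

    fo = X.T @ f @ X
    eps, Co = np.linalg.eigh(fo)
    C = X @ Co
    P = C[:, :nocc] @ C[:, :nocc].T
    J, K = _jk(eri, P)
    f = h + 2.0 * J - K
    energy = float(np.einsum("mn,mn->", P, h + f)) + molecule.nuclear_repulsion()
    ref = ReferenceState(molecule=molecule, basis=obs, C=C, eps=eps, P=P,
                         fock=f, exchange=K, energy=energy,
                         converged_norm=trace[-1], overlap=S)
    ref.validate()
    return ref
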