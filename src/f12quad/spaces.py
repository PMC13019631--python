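"""Orbital-space bookkeeping: CABS construction and the index families used
throughout the F12 intermediates.

Index families (matching the standard CABS-RI conventions):

    i, j        active occupied MOs (occupied minus frozen core)
    k, l, m     occupied MOs
    a, b, c     virtual MOs
    p, q        occupied + virtual ({i} u {a})
    p'', q''    CABS MOs (complement of the HF span in the union basis)
    p', q'      union MOs ({p} u {p''})
    mu          orbital-basis AOs;  mu'  union-basis AOs

The CABS orbitals are built by Loewdin-orthogonalizing the union AO basis
(with small-eigenvalue truncation) and projecting out the HF MO span via an
SVD split at singular value 0.5 — a deterministic, threshold-robust
complement construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet
from .integrals import eri_4c2e, kinetic, nuclear_attraction, overlap
from .kernels import KernelSpec
from .molecule import Molecule
from .scf import ConditioningError, ReferenceState, compute_reference

LOWDIN_DROP = 1e-8
SVD_SPLIT = 0.5


class DegenerateInputError(ValueError):
    pass


class InvalidConfigurationError(ValueError):
    pass


@dataclass
class CabsBlocks:
    union_basis: BasisSet
    S_union: np.ndarray          # union AO overlap S'
    Pi: np.ndarray               # RI projector S'^-1 (pseudo-inverse)
    C_cabs: np.ndarray           # union-AO x n_cabs coefficients
    n_dropped: int               # Loewdin-truncated union vectors

    @property
    def n_cabs(self) -> int:
        return self.C_cabs.shape[1]


def build_cabs(obs: BasisSet, cabs_aux: BasisSet, reference: ReferenceState,
               drop: float = LOWDIN_DROP, cond_limit: float = 1e10) -> CabsBlocks:
    """Orthonormal CABS spanning the union space minus the HF MO span."""
    union = obs.union(cabs_aux)
    S = overlap(union)
    w, V = np.linalg.eigh(S)
    keep = w > drop
    n_dropped = int((~keep).sum())
    w, V = w[keep], V[:, keep]
    if w.max() / w.min() > cond_limit:
        raise ConditioningError(
            f"union overlap condition {w.max()/w.min():.1e} beyond limit "
            f"after truncation")
    X = V / np.sqrt(w)              # S'-orthonormal spanning set
    Pi = X @ X.T                    # pseudo-inverse of S' on retained span

    n_obs = obs.n_ao
    C_all = np.zeros((union.n_ao, reference.C.shape[1]))
    C_all[:n_obs] = reference.C     # HF MOs embedded in the union basis
    V_ov = X.T @ S @ C_all          # overlap of Loewdin vectors with HF span
    U, sig, _ = np.linalg.svd(V_ov, full_matrices=True)
    n_mo = C_all.shape[1]
    sig_full = np.zeros(U.shape[1])
    sig_full[:len(sig)] = sig
    cabs_cols = U[:, sig_full < SVD_SPLIT]
    C_cabs = X @ cabs_cols
    return CabsBlocks(union_basis=union, S_union=S, Pi=Pi, C_cabs=C_cabs,
                      n_dropped=n_dropped)


@dataclass
class OrbitalSpaces:
    molecule: Molecule
    obs: BasisSet
    reference: ReferenceState
    cabs: CabsBlocks
    frozen_core: int
    gbc_ebc: bool

    # populated by assemble_spaces
    C_union: np.ndarray = field(default=None, repr=False)  # (n_uao, n_p')
    eps: np.ndarray = field(default=None, repr=False)
    f_mo: np.ndarray = field(default=None, repr=False)     # union-MO Fock
    k_mo: np.ndarray = field(default=None, repr=False)     # union-MO exchange
    f_ao_union: np.ndarray = field(default=None, repr=False)
    k_ao_union: np.ndarray = field(default=None, repr=False)

    @property
    def union_basis(self) -> BasisSet:
        return self.cabs.union_basis

    @property
    def n_occ(self) -> int:
        return self.molecule.n_occ

    @property
    def n_act(self) -> int:
        return self.n_occ - self.frozen_core

    @property
    def n_virt(self) -> int:
        return self.reference.C.shape[1] - self.n_occ

    @property
    def n_p(self) -> int:
        return self.reference.C.shape[1]

    @property
    def n_cabs(self) -> int:
        return self.cabs.n_cabs

    @property
    def n_union(self) -> int:
        return self.n_p + self.n_cabs

    # -- MO coefficient blocks over the union AO basis ------------------------
    def C_block(self, family: str) -> np.ndarray:
        sl = {"occ": slice(0, self.n_occ),
              "act": slice(self.frozen_core, self.n_occ),
              "virt": slice(self.n_occ, self.n_p),
              "p": slice(0, self.n_p),
              "cabs": slice(self.n_p, self.n_union),
              "union": slice(0, self.n_union)}[family]
        return self.C_union[:, sl]

    def mo_slice(self, family: str) -> slice:
        return {"occ": slice(0, self.n_occ),
                "act": slice(self.frozen_core, self.n_occ),
                "virt": slice(self.n_occ, self.n_p),
                "p": slice(0, self.n_p),
                "cabs": slice(self.n_p, self.n_union),
                "union": slice(0, self.n_union)}[family]

    # -- AO densities over the union AO basis ---------------------------------
    def density(self, family: str, weights: np.ndarray | None = None) -> np.ndarray:
        """P = C W C^T over union AOs for the given family; ``weights`` is an
        optional per-orbital diagonal (e.g. orbital energies)."""
        C = self.C_block(family)
        if weights is None:
            return C @ C.T
        return (C * weights) @ C.T

    def validate(self, tol: float = 1e-8) -> None:
        S = self.cabs.S_union
        C_occ = self.C_block("occ")
        C_cabs = self.C_block("cabs")
        if C_cabs.shape[1]:
            ov = np.abs(C_occ.T @ S @ C_cabs).max()
            if ov > tol:
                raise ValueError(f"occupied-CABS overlap {ov:.2e} exceeds {tol}")
            orth = np.abs(C_cabs.T @ S @ C_cabs - np.eye(self.n_cabs)).max()
            if orth > tol:
                raise ValueError(f"CABS non-orthonormality {orth:.2e}")
        Pi = self.cabs.Pi
        err = np.abs(Pi @ S @ Pi - Pi).max()
        if err > tol:
            raise ValueError(f"RI projector Pi S Pi - Pi = {err:.2e}")


def assemble_spaces(reference: ReferenceState, cabs: CabsBlocks,
                    frozen_core: int = 0, gbc_ebc: bool = True) -> OrbitalSpaces:
    """Build Fock/exchange matrices over the union space and the coefficient
    blocks of all index families."""
    mol = reference.molecule
    if frozen_core < 0 or frozen_core >= mol.n_occ:
        raise InvalidConfigurationError(
            f"frozen_core={frozen_core} with {mol.n_occ} occupied orbitals")
    obs = reference.basis
    union = cabs.union_basis
    n_obs = obs.n_ao

    spaces = OrbitalSpaces(molecule=mol, obs=obs, reference=reference,
                           cabs=cabs, frozen_core=frozen_core, gbc_ebc=gbc_ebc)

    C_union = np.zeros((union.n_ao, spaces.n_p + cabs.n_cabs))
    C_union[:n_obs, :spaces.n_p] = reference.C
    C_union[:, spaces.n_p:] = cabs.C_cabs
    spaces.C_union = C_union
    spaces.eps = reference.eps

    # Fock and exchange over the union AO basis from the SCF density
    h_u = kinetic(union) + nuclear_attraction(union, mol)
    P = reference.P
    eri_j = eri_4c2e(KernelSpec("G"), union, union, obs, obs)
    J_u = np.einsum("MNls,ls->MN", eri_j, P)
    eri_k = eri_4c2e(KernelSpec("G"), union, obs, obs, union)
    K_u = np.einsum("MlsN,ls->MN", eri_k, P)
    f_u = h_u + 2.0 * J_u - K_u
    spaces.f_ao_union = f_u
    spaces.k_ao_union = K_u

    f_mo = C_union.T @ f_u @ C_union
    k_mo = C_union.T @ K_u @ C_union
    if gbc_ebc and cabs.n_cabs:
        f_mo[:spaces.n_p, spaces.n_p:] = 0.0
        f_mo[spaces.n_p:, :spaces.n_p] = 0.0
    spaces.f_mo = f_mo
    spaces.k_mo = k_mo
    spaces.validate()
    return spaces


def make_spaces(molecule: Molecule, obs: BasisSet, cabs_aux: BasisSet,
                frozen_core: int = 0, gbc_ebc: bool = True,
                reference: ReferenceState | None = None) -> OrbitalSpaces:
    if reference is None:
        reference = compute_reference(molecule, obs)
    cabs = build_cabs(obs, cabs_aux, reference)
    return assemble_spaces(reference, cabs, frozen_core=frozen_core,
                           gbc_ebc=gbc_ebc)
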