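"""Molecular geometry container and XYZ input.

Only closed-shell (even-electron, singlet) neutral-or-charged systems are
supported; everything downstream assumes a spin-restricted reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_TO_BOHR, ATOMIC_NUMBER


class FormatError(ValueError):
    """Malformed input document."""


class UnsupportedSystemError(ValueError):
    """System outside the closed-shell singlet domain of the code."""


@dataclass(frozen=True)
class Atom:
    symbol: str
    charge: int
    position: np.ndarray  # (3,) bohr


@dataclass
class Molecule:
    atoms: list[Atom]
    charge: int = 0
    multiplicity: int = 1
    name: str = ""
    _nelec: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if self.multiplicity != 1:
            raise UnsupportedSystemError(
                f"only closed-shell singlets are supported (multiplicity={self.multiplicity})"
            )
        for at in self.atoms:
            if not np.all(np.isfinite(at.position)):
                raise FormatError(f"non-finite position for atom {at.symbol}")
        nelec = sum(at.charge for at in self.atoms) - self.charge
        if nelec <= 0 or nelec % 2 != 0:
            raise UnsupportedSystemError(
                f"electron count {nelec} is not an even positive number"
            )
        self._nelec = nelec

    @property
    def n_electrons(self) -> int:
        return self._nelec

    @property
    def n_occ(self) -> int:
        return self._nelec // 2

    @property
    def positions(self) -> np.ndarray:
        return np.array([at.position for at in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([float(at.charge) for at in self.atoms])

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for a in range(len(self.atoms)):
            for b in range(a):
                r = np.linalg.norm(self.atoms[a].position - self.atoms[b].position)
                e += self.atoms[a].charge * self.atoms[b].charge / r
        return e

    def principal_axes(self) -> np.ndarray:
        """Deterministic orthonormal frame aligned with the charge-weighted
        principal axes; used to orient angular quadrature shells so that the
        final energies are exactly invariant under rigid rotations."""
        pos = self.positions
        q = self.charges
        com = q @ pos / q.sum()
        x = pos - com
        inertia = np.einsum("a,ai,aj->ij", q, x, x)
        # symmetrize and diagonalize; fall back to identity for a single atom
        w, v = np.linalg.eigh(0.5 * (inertia + inertia.T))
        axes = v.T  # rows are axes
        # fix signs deterministically: largest-|component| entry positive
        for i in range(3):
            j = int(np.argmax(np.abs(axes[i])))
            if axes[i, j] < 0:
                axes[i] = -axes[i]
        if np.linalg.det(axes) < 0:
            axes[2] = -axes[2]
        return axes


def load_molecule(xyz_text: str, charge: int = 0, multiplicity: int = 1,
                  name: str = "") -> Molecule:
    """Parse a standard two-header-line XYZ document (coordinates in Angstrom)."""
    lines = xyz_text.splitlines()
    if not lines:
        raise FormatError("empty XYZ document")
    try:
        natom = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"line 1: expected atom count, got {lines[0]!r}") from exc
    body = lines[2:]
    atoms: list[Atom] = []
    for n, line in enumerate(body, start=3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"line {n}: expected 'symbol x y z', got {line!r}")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_NUMBER:
            raise FormatError(f"line {n}: unrecognized element symbol {parts[0]!r}")
        try:
            xyz = np.array([float(p) for p in parts[1:4]]) * ANGSTROM_TO_BOHR
        except ValueError as exc:
            raise FormatError(f"line {n}: bad coordinate in {line!r}") from exc
        atoms.append(Atom(sym, ATOMIC_NUMBER[sym], xyz))
    if len(atoms) != natom:
        raise FormatError(f"header declares {natom} atoms, found {len(atoms)}")
    return Molecule(atoms, charge=charge, multiplicity=multiplicity, name=name)
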