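"""Deterministic test-system generators with bundled even-tempered bases.

The chain generators grow strictly linearly in atom count (and hence in
AOs, electrons and grid points), which is what the formal-scaling probes
measure; the pseudo-glycine chain emulates a peptide-like repeat unit
geometrically, not chemically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSet, fixture_basis
from .constants import ANGSTROM_TO_BOHR
from .molecule import Atom, Molecule
from .quadrature import ConfigurationError

FIXTURE_NAMES = ("he", "h2", "h2o", "linear_hn_chain", "pseudo_glycine_chain")


@dataclass
class FixtureBundle:
    molecule: Molecule
    obs: BasisSet
    cabs_aux: BasisSet
    df_aux: BasisSet


def _bundle(mol: Molecule, prefix: str) -> FixtureBundle:
    return FixtureBundle(
        molecule=mol,
        obs=fixture_basis(mol, f"{prefix}.obs", "orbital"),
        cabs_aux=fixture_basis(mol, f"{prefix}.cabs", "cabs_aux"),
        df_aux=fixture_basis(mol, f"{prefix}.df", "df_aux"),
    )


def he() -> FixtureBundle:
    mol = Molecule([Atom("He", 2, np.zeros(3))], name="he")
    return _bundle(mol, "fix.he")


def h2(distance_angstrom: float = 0.74) -> FixtureBundle:
    d = distance_angstrom * ANGSTROM_TO_BOHR
    mol = Molecule([Atom("H", 1, np.zeros(3)),
                    Atom("H", 1, np.array([0.0, 0.0, d]))], name="h2")
    return _bundle(mol, "fix.h2")


def h2o() -> FixtureBundle:
    a = ANGSTROM_TO_BOHR
    mol = Molecule([
        Atom("O", 8, np.array([0.0, 0.0, 0.1173]) * a),
        Atom("H", 1, np.array([0.0, 0.7572, -0.4692]) * a),
        Atom("H", 1, np.array([0.0, -0.7572, -0.4692]) * a),
    ], name="h2o")
    return _bundle(mol, "fix.h2o")


def linear_hn_chain(n: int, spacing_bohr: float = 1.7) -> FixtureBundle:
    if n < 2 or n % 2:
        raise ConfigurationError("linear_hn_chain needs an even n >= 2")
    atoms = [Atom("H", 1, np.array([0.0, 0.0, i * spacing_bohr]))
             for i in range(n)]
    mol = Molecule(atoms, name=f"h{n}_chain")
    return FixtureBundle(
        molecule=mol,
        obs=fixture_basis(mol, "fix.hchain.obs", "orbital"),
        cabs_aux=fixture_basis(mol, "fix.hchain.cabs", "cabs_aux"),
        df_aux=fixture_basis(mol, "fix.hchain.df", "df_aux"),
    )


#: one glycine-like repeat unit (10 atoms), coordinates in Angstrom
_GLY_UNIT = [
    ("N", (0.00, 0.00, 0.00)), ("H", (-0.50, 0.86, 0.00)),
    ("C", (1.45, 0.00, 0.00)), ("H", (1.80, -0.52, 0.88)),
    ("H", (1.80, -0.52, -0.88)), ("C", (2.00, 1.40, 0.00)),
    ("O", (1.35, 2.42, 0.00)), ("O", (3.35, 1.50, 0.00)),
    ("H", (3.60, 2.43, 0.00)), ("H", (-0.35, -0.95, 0.00)),
]
_GLY_SHIFT = 4.2  # Angstrom, per repeat unit along x


def pseudo_glycine_chain(n: int) -> FixtureBundle:
    if n < 1:
        raise ConfigurationError("pseudo_glycine_chain needs n >= 1")
    from .constants import ATOMIC_NUMBER
    atoms = []
    for u in range(n):
        for sym, (x, y, z) in _GLY_UNIT:
            pos = np.array([x + u * _GLY_SHIFT, y, z]) * ANGSTROM_TO_BOHR
            atoms.append(Atom(sym, ATOMIC_NUMBER[sym], pos))
    mol = Molecule(atoms, name=f"gly{n}_chain")
    return FixtureBundle(
        molecule=mol,
        obs=fixture_basis(mol, "fix.gly.obs", "orbital"),
        cabs_aux=fixture_basis(mol, "fix.gly.cabs", "cabs_aux"),
        df_aux=fixture_basis(mol, "fix.gly.df", "df_aux"),
    )


def generate_fixture(name: str, **params) -> FixtureBundle:
    if name == "he":
        return he()
    if name == "h2":
        return h2(**params)
    if name == "h2o":
        return h2o()
    if name == "linear_hn_chain":
        return linear_hn_chain(**params)
    if name == "pseudo_glycine_chain":
        return pseudo_glycine_chain(**params)
    raise ConfigurationError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
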