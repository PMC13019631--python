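"""Physical constants and element tables. All internal math is in atomic units."""

# Fixed conversion constant (CODATA 2010 value, frozen for reproducibility).
ANGSTROM_TO_BOHR = 1.0 / 0.52917721092
BOHR_TO_ANGSTROM = 0.52917721092

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]

ATOMIC_NUMBER = {sym: z for z, sym in enumerate(ELEMENTS) if z > 0}

# Bragg-Slater covalent radii in bohr (H adjusted upward as is customary for
# molecular quadrature partitioning).
_BRAGG_ANGSTROM = {
    "H": 0.35, "He": 0.35, "Li": 1.45, "Be": 1.05, "B": 0.85, "C": 0.70,
    "N": 0.65, "O": 0.60, "F": 0.50, "Ne": 0.45, "Na": 1.80, "Mg": 1.50,
    "Al": 1.25, "Si": 1.10, "P": 1.00, "S": 1.00, "Cl": 1.00, "Ar": 0.95,
}

BRAGG_RADIUS = {sym: r * ANGSTROM_TO_BOHR for sym, r in _BRAGG_ANGSTROM.items()}
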