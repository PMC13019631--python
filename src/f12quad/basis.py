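"""Gaussian basis sets: shells, normalization, the Gaussian94 text format and
the embedded even-tempered fixture library.

Cartesian Gaussians only, with angular momentum up to d (the documented
capability bound of the integral engine). Every contracted function is
normalized to unit self-overlap; the six cartesian d components are therefore
normalized individually, which leaves the shell's span (all homogeneous
quadratic monomials) rotationally invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .molecule import Molecule, FormatError

L_SYMBOLS = {"S": 0, "P": 1, "D": 2}
L_LETTERS = {v: k for k, v in L_SYMBOLS.items()}

#: cartesian component exponents (i, j, k) per angular momentum
CARTESIANS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}

L_MAX = 2


class CapabilityError(NotImplementedError):
    """Requested feature beyond the implemented engine capabilities."""


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(alpha: float, lmn: tuple[int, int, int]) -> float:
    """Normalization constant of a primitive cartesian Gaussian."""
    i, j, k = lmn
    l = i + j + k
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = np.sqrt(_double_factorial(2 * i - 1)
                  * _double_factorial(2 * j - 1)
                  * _double_factorial(2 * k - 1))
    return num / den


def _contracted_self_overlap(exps: np.ndarray, coefs: np.ndarray,
                             lmn: tuple[int, int, int]) -> float:
    """<phi|phi> for a contracted cartesian Gaussian with primitive-normalized
    coefficients (analytic one-center overlap)."""
    i, j, k = lmn
    l = i + j + k
    fact = (_double_factorial(2 * i - 1) * _double_factorial(2 * j - 1)
            * _double_factorial(2 * k - 1))
    s = 0.0
    for a, ca in zip(exps, coefs):
        na = primitive_norm(a, lmn)
        for b, cb in zip(exps, coefs):
            nb = primitive_norm(b, lmn)
            p = a + b
            s += (ca * cb * na * nb * fact
                  * (np.pi / p) ** 1.5 / (2.0 * p) ** l)
    return s


@dataclass
class Shell:
    """One contracted shell on a fixed center.

    ``norms[c, p]`` holds, for cartesian component ``c`` and primitive ``p``,
    the full coefficient  contraction * primitive norm * contraction norm  so
    that the AO is  sum_p norms[c,p] * x^i y^j z^k exp(-exps[p] r^2).
    """
    center_index: int
    center: np.ndarray  # (3,)
    l: int
    exps: np.ndarray
    coefs: np.ndarray
    norms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.l > L_MAX:
            raise CapabilityError(
                f"angular momentum l={self.l} not implemented (max is d)")
        self.exps = np.asarray(self.exps, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float)
        if np.any(self.exps <= 0):
            raise ValueError("primitive exponents must be positive")
        carts = CARTESIANS[self.l]
        norms = np.empty((len(carts), len(self.exps)))
        for c, lmn in enumerate(carts):
            pn = np.array([primitive_norm(a, lmn) for a in self.exps])
            s = _contracted_self_overlap(self.exps, self.coefs, lmn)
            norms[c] = self.coefs * pn / np.sqrt(s)
        self.norms = norms

    @property
    def n_ao(self) -> int:
        return len(CARTESIANS[self.l])

    @property
    def cartesians(self) -> list[tuple[int, int, int]]:
        return CARTESIANS[self.l]


@dataclass
class BasisSet:
    """A basis instantiated on a molecule: an ordered list of shells."""
    shells: list[Shell]
    role: str = "orbital"  # orbital | cabs_aux | df_aux
    name: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("orbital", "cabs_aux", "df_aux"):
            raise ValueError(f"unknown basis role {self.role!r}")
        offs = []
        n = 0
        for sh in self.shells:
            offs.append(n)
            n += sh.n_ao
        self._offsets = offs
        self._n_ao = n

    @property
    def n_ao(self) -> int:
        return self._n_ao

    @property
    def ao_offsets(self) -> list[int]:
        return self._offsets

    def ao_centers(self) -> np.ndarray:
        out = np.empty((self.n_ao, 3))
        for sh, off in zip(self.shells, self._offsets):
            out[off:off + sh.n_ao] = sh.center
        return out

    def union(self, other: "BasisSet", name: str = "") -> "BasisSet":
        """Concatenated basis {mu} + {mu''}; AO order: self first."""
        return BasisSet(list(self.shells) + list(other.shells),
                        role="orbital", name=name or f"{self.name}+{other.name}")


# ----------------------------------------------------------------------------
# element -> shell-spec definitions and molecule binding
# ----------------------------------------------------------------------------

BasisDefinition = dict[str, list[tuple[str, list[float], list[float] | None]]]


def build_basis(molecule: Molecule, definition: BasisDefinition,
                role: str = "orbital", name: str = "") -> BasisSet:
    shells: list[Shell] = []
    for idx, atom in enumerate(molecule.atoms):
        if atom.symbol not in definition:
            raise FormatError(
                f"basis definition {name!r} lacks element {atom.symbol}")
        for lsym, exps, coefs in definition[atom.symbol]:
            lsym = lsym.upper()
            if lsym not in L_SYMBOLS:
                raise CapabilityError(f"unsupported shell type {lsym!r}")
            if coefs is None:
                coefs = [1.0] * len(exps)
            if len(coefs) != len(exps):
                raise FormatError(
                    f"shell {lsym} on {atom.symbol}: {len(exps)} exponents vs "
                    f"{len(coefs)} coefficients")
            shells.append(Shell(idx, atom.position, L_SYMBOLS[lsym],
                                np.array(exps), np.array(coefs)))
    return BasisSet(shells, role=role, name=name)


def parse_gaussian94(text: str) -> BasisDefinition:
    """Parse a Gaussian94-style basis set document (one block per element)."""
    definition: BasisDefinition = {}
    lines = [ln.split("!")[0].rstrip() for ln in text.splitlines()]
    i = 0
    n = len(lines)

    def skip_blank_and_stars(i: int) -> int:
        while i < n and (not lines[i].strip() or lines[i].strip() == "****"):
            i += 1
        return i

    i = skip_blank_and_stars(i)
    while i < n:
        head = lines[i].split()
        if not head:
            i += 1
            continue
        element = head[0].capitalize()
        i += 1
        entries: list[tuple[str, list[float], list[float] | None]] = []
        while i < n and lines[i].strip() != "****":
            parts = lines[i].split()
            if len(parts) < 2:
                raise FormatError(f"line {i + 1}: expected shell header, got {lines[i]!r}")
            lsym = parts[0].upper()
            if lsym == "SP":
                raise CapabilityError("SP shells are not supported; split into S and P")
            try:
                nprim = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"line {i + 1}: bad primitive count") from exc
            i += 1
            exps, coefs = [], []
            for _ in range(nprim):
                if i >= n:
                    raise FormatError("unexpected end of basis document")
                prim = lines[i].replace("D", "E").replace("d", "e").split()
                if len(prim) < 2:
                    raise FormatError(f"line {i + 1}: expected 'exponent coefficient'")
                exps.append(float(prim[0]))
                coefs.append(float(prim[1]))
                i += 1
            entries.append((lsym, exps, coefs))
        definition[element] = entries
        i = skip_blank_and_stars(i)
    if not definition:
        raise FormatError("no element blocks found in basis document")
    return definition


def format_gaussian94(definition: BasisDefinition) -> str:
    out = ["****"]
    for element, entries in definition.items():
        out.append(f"{element}     0")
        for lsym, exps, coefs in entries:
            if coefs is None:
                coefs = [1.0] * len(exps)
            out.append(f"{lsym}   {len(exps)}   1.00")
            for e, c in zip(exps, coefs):
                out.append(f"   {e: .10E}   {c: .10E}")
        out.append("****")
    return "\n".join(out) + "\n"


# ----------------------------------------------------------------------------
# Embedded fixture library (small even-tempered sets; no downloads needed)
# ----------------------------------------------------------------------------

def _et(a0: float, ratio: float, k: int) -> list[float]:
    return [a0 * ratio ** i for i in range(k)]


def _uncontracted(lsym: str, exps: list[float]):
    return [(lsym, [e], None) for e in exps]


FIXTURE_LIBRARY: dict[str, BasisDefinition] = {
    # --- hydrogen dimer ------------------------------------------------------
    "fix.h2.obs": {
        "H": _uncontracted("S", [5.0, 1.0, 0.25]) + [("P", [0.9], None)],
    },
    "fix.h2.cabs": {
        "H": [("S", [2.2], None), ("P", [2.8], None), ("P", [0.45], None)],
    },
    "fix.h2.df": {
        "H": _uncontracted("S", _et(0.13, 2.3, 7))
        + _uncontracted("P", _et(0.25, 2.7, 6))
        + _uncontracted("D", [0.3, 0.85, 2.4, 6.8]),
    },
    # --- helium --------------------------------------------------------------
    "fix.he.obs": {
        "He": _uncontracted("S", [38.0, 5.8, 1.24, 0.3]) + [("P", [1.1], None)],
    },
    "fix.he.min": {  # single contracted s: occupied space == full basis
        "He": [("S", [5.77, 1.24], [0.3, 0.8])],
    },
    "fix.he.cabs": {
        "He": [("S", [12.0], None), ("S", [0.55], None),
               ("P", [3.2], None), ("P", [0.6], None), ("D", [1.5], None)],
    },
    "fix.he.df": {
        "He": _uncontracted("S", _et(0.25, 2.6, 8))
        + _uncontracted("P", _et(0.35, 2.8, 6))
        + _uncontracted("D", [0.45, 1.3, 3.6]),
    },
    # --- water ---------------------------------------------------------------
    "fix.h2o.obs": {
        "O": _uncontracted("S", [180.0, 27.0, 4.0, 0.6])
        + _uncontracted("P", [6.0, 1.3, 0.28]),
        "H": _uncontracted("S", [1.8, 0.3]),
    },
    "fix.h2o.cabs": {
        "O": [("S", [1.5], None), ("P", [0.55], None), ("D", [1.2], None)],
        "H": [("S", [0.75], None), ("P", [1.1], None)],
    },
    "fix.h2o.df": {
        "O": _uncontracted("S", _et(0.2, 3.1, 7))
        + _uncontracted("P", [0.24, 0.83, 2.9, 10.0])
        + _uncontracted("D", [0.8, 2.4]),
        "H": _uncontracted("S", [0.19, 0.66, 2.3, 8.0])
        + _uncontracted("P", [0.4, 1.4]),
    },
    # --- hydrogen chains (scaling probes) ------------------------------------
    "fix.hchain.obs": {
        "H": _uncontracted("S", [1.4, 0.28]),
    },
    "fix.hchain.cabs": {
        "H": [("P", [1.0], None)],
    },
    "fix.hchain.df": {
        "H": _uncontracted("S", [0.6, 2.8]) + [("P", [0.9], None)],
    },
    # --- pseudo-glycine chains (minimal, geometry probes only) ---------------
    "fix.gly.obs": {
        "C": _uncontracted("S", [12.0, 0.8]) + [("P", [0.9], None)],
        "N": _uncontracted("S", [16.0, 1.0]) + [("P", [1.1], None)],
        "O": _uncontracted("S", [20.0, 1.2]) + [("P", [1.3], None)],
        "H": [("S", [1.1], None)],
    },
    "fix.gly.cabs": {
        "C": [("P", [2.2], None)], "N": [("P", [2.6], None)],
        "O": [("P", [3.0], None)], "H": [("P", [1.2], None)],
    },
    "fix.gly.df": {
        "C": _uncontracted("S", [1.6, 6.0]) + [("P", [1.2], None)],
        "N": _uncontracted("S", [2.0, 7.0]) + [("P", [1.4], None)],
        "O": _uncontracted("S", [2.4, 8.0]) + [("P", [1.6], None)],
        "H": _uncontracted("S", [0.7, 2.2]),
    },
}


def fixture_basis(molecule: Molecule, library_name: str, role: str) -> BasisSet:
    if library_name not in FIXTURE_LIBRARY:
        raise KeyError(f"unknown fixture basis {library_name!r}")
    return build_basis(molecule, FIXTURE_LIBRARY[library_name], role=role,
                       name=library_name)
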