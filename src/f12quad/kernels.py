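"""Two-electron operator kernels of the F12 working equations.

The operator family, as functions of the interelectronic (or electron-to-
grid-point) distance r:

    F      -exp(-gamma r) / gamma         Slater-type geminal
    G      1 / r                          Coulomb
    FG     -exp(-gamma r) / (gamma r)     geminal times Coulomb
    F2     exp(-2 gamma r) / gamma^2      squared geminal
    DEL2F  exp(-2 gamma r)                (grad F . grad F); == gamma^2 * F2

The geminal carries the conventional negative sign: F(r) = -1/gamma + r -
gamma r^2/2 + ... near coalescence, so the fixed amplitudes 3/8 and 1/8
reproduce the s- and p-wave cusp conditions with a *positive* coefficient.
Only quantities linear in F (the V intermediate and its FG ingredient) are
sensitive to this sign; X and B are quadratic in F.

Each kernel decomposes into *elementary* terms the integral engine knows how
to evaluate in closed form:

    ("coulomb", None, c)   ->  c / r
    ("gauss", beta, c)     ->  c * exp(-beta r^2)
    ("dampcoul", beta, c)  ->  c * exp(-beta r^2) / r

F and F2 use separate STG-nG fits of exp(-gamma r) and exp(-2 gamma r)
(fitting the squared exponential directly is more accurate than squaring the
fit). FG reuses the exp(-gamma r) fit with each Gaussian term multiplied by
the exact 1/r, preserving the Coulomb singularity. DEL2F shares F2's
expansion scaled by gamma^2, which makes the tensor identity
DEL2F = gamma^2 * F2 exact to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .stg import StgExpansion, fit_stg

OPERATOR_TAGS = ("F", "G", "FG", "F2", "DEL2F")

ElementaryTerm = tuple[str, float | None, float]


@lru_cache(maxsize=32)
def _cached_fit(zeta: float, n: int, domain: tuple[float, float]) -> StgExpansion:
    return fit_stg(zeta, n, domain)


@dataclass(frozen=True)
class KernelSpec:
    """An operator tag bound to a correlation exponent and STG fit order."""
    tag: str
    gamma: float = 1.3
    n_fit: int = 6
    fit_domain: tuple[float, float] = (1e-3, 10.0)

    def __post_init__(self) -> None:
        if self.tag not in OPERATOR_TAGS:
            raise ValueError(f"unknown operator tag {self.tag!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    # -- closed-form r-dependence --------------------------------------------
    def kernel_value(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        g = self.gamma
        if self.tag == "F":
            return -np.exp(-g * r) / g
        if self.tag == "G":
            return 1.0 / r
        if self.tag == "FG":
            return -np.exp(-g * r) / (g * r)
        if self.tag == "F2":
            return np.exp(-2 * g * r) / (g * g)
        return np.exp(-2 * g * r)  # DEL2F

    # -- STG expansions -------------------------------------------------------
    @property
    def expansion(self) -> StgExpansion | None:
        if self.tag in ("F", "FG"):
            return _cached_fit(self.gamma, self.n_fit, self.fit_domain)
        if self.tag in ("F2", "DEL2F"):
            return _cached_fit(2.0 * self.gamma, self.n_fit, self.fit_domain)
        return None

    def elementary_terms(self) -> list[ElementaryTerm]:
        g = self.gamma
        if self.tag == "G":
            return [("coulomb", None, 1.0)]
        exp_ = self.expansion
        assert exp_ is not None
        if self.tag == "F":
            return [("gauss", float(b), -float(c) / g)
                    for c, b in zip(exp_.coefs, exp_.betas)]
        if self.tag == "FG":
            return [("dampcoul", float(b), -float(c) / g)
                    for c, b in zip(exp_.coefs, exp_.betas)]
        scale = 1.0 if self.tag == "DEL2F" else 1.0 / (g * g)
        return [("gauss", float(b), float(c) * scale)
                for c, b in zip(exp_.coefs, exp_.betas)]

    def radial_envelope(self, r) -> np.ndarray:
        """Monotone decaying upper envelope of |kernel| used by screening."""
        r = np.maximum(np.asarray(r, dtype=float), 1e-10)
        if self.tag == "G":
            return 1.0 / r
        return np.abs(self.kernel_value(r))
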