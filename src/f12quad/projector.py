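"""Operator/projector algebra for the B intermediate.

The strong-orthogonality projector Q12 = (1-o1)(1-o2)(1-v1 v2) sandwiching
the one-electron Fock operator f1 expands into 25 operator/projector
products. Idempotency, cross-electron commutation, the annihilation rules
o v = v o = 0 and o f v = v f o = 0, and cancellation reduce this to an
11-term list, and combining transpose-related pairs (the T-hat bookkeeping)
yields the final 8-entry evaluation list

    Q f1 Q = f1 - f1 o2 + T(-f1 o1 + f1 o1 o2 - f1 v1 v2)
             + o1 f1 o1 - o1 f1 o1 o2 + v1 f1 v1 v2,   T(X) = X + X^T.

The reduction is *data*, not run-time symbol manipulation; its correctness
is enforced by a brute-force matrix oracle on random finite model spaces
(see the test suite), which also adjudicates the dressing choices of the
full-RI insertions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np

Term = tuple[float, tuple[str, ...]]
FinalTerm = tuple[float, tuple[str, ...], bool]  # (coeff, ops, apply_transpose)

_PROJ_FACTORS: list[tuple[float, tuple[str, ...]]] = [
    (1.0, ()),
    (-1.0, ("o1",)),
    (-1.0, ("o2",)),
    (1.0, ("o1", "o2")),
    (-1.0, ("v1", "v2")),
]

#: the 5 x 5 raw expansion (terms that vanish by o v = 0 / o f v = 0 keep a
#: zero coefficient so the full combination table remains visible)
RAW_TABLE: list[Term] = []
for _cl, _l in _PROJ_FACTORS:
    for _cr, _r in _PROJ_FACTORS:
        RAW_TABLE.append((_cl * _cr, _l + ("f1",) + _r))

#: reduced 11-term list (canonical operator strings with net coefficients)
REDUCED_TABLE: list[Term] = [
    (+1.0, ("f1",)),
    (-1.0, ("f1", "o1")),
    (-1.0, ("o1", "f1")),
    (-1.0, ("f1", "o2")),
    (+1.0, ("f1", "o1", "o2")),
    (+1.0, ("o1", "o2", "f1")),
    (-1.0, ("f1", "v1", "v2")),
    (-1.0, ("v1", "v2", "f1")),
    (+1.0, ("o1", "f1", "o1")),
    (-1.0, ("o1", "f1", "o1", "o2")),
    (+1.0, ("v1", "f1", "v1", "v2")),
]

#: final list with transpose markers (T doubles via X + X^T)
FINAL_TABLE: list[FinalTerm] = [
    (+1.0, ("f1",), False),
    (-1.0, ("f1", "o2"), False),
    (-1.0, ("f1", "o1"), True),
    (+1.0, ("f1", "o1", "o2"), True),
    (-1.0, ("f1", "v1", "v2"), True),
    (+1.0, ("o1", "f1", "o1"), False),
    (-1.0, ("o1", "f1", "o1", "o2"), False),
    (+1.0, ("v1", "f1", "v1", "v2"), False),
]


@dataclass
class ProjectorTermTable:
    raw: list[Term] = field(default_factory=lambda: list(RAW_TABLE))
    reduced: list[Term] = field(default_factory=lambda: list(REDUCED_TABLE))
    final: list[FinalTerm] = field(default_factory=lambda: list(FINAL_TABLE))

    # -- matrix-model evaluation ---------------------------------------------
    @staticmethod
    def _op(sym: str, f: np.ndarray, o: np.ndarray, v: np.ndarray) -> np.ndarray:
        d = f.shape[0]
        eye = np.eye(d)
        if sym == "f1":
            return np.kron(f, eye)
        if sym == "o1":
            return np.kron(o, eye)
        if sym == "o2":
            return np.kron(eye, o)
        if sym == "v1":
            return np.kron(v, eye)
        if sym == "v2":
            return np.kron(eye, v)
        raise KeyError(sym)

    def _eval_ops(self, ops: tuple[str, ...], f, o, v) -> np.ndarray:
        d2 = f.shape[0] ** 2
        mats = [self._op(s, f, o, v) for s in ops]
        return reduce(np.matmul, mats, np.eye(d2))

    def evaluate_raw(self, f, o, v) -> np.ndarray:
        return sum(c * self._eval_ops(ops, f, o, v) for c, ops in self.raw)

    def evaluate_reduced(self, f, o, v) -> np.ndarray:
        return sum(c * self._eval_ops(ops, f, o, v) for c, ops in self.reduced)

    def evaluate_final(self, f, o, v) -> np.ndarray:
        out = np.zeros((f.shape[0] ** 2,) * 2)
        for c, ops, transpose in self.final:
            m = self._eval_ops(ops, f, o, v)
            out += c * (m + m.T if transpose else m)
        return out

    @staticmethod
    def qfq_direct(f, o, v) -> np.ndarray:
        """Brute-force Q12 f1 Q12 on the model space (the defining oracle)."""
        d = f.shape[0]
        eye = np.eye(d)
        eye2 = np.eye(d * d)
        q = ((eye2 - np.kron(o, eye)) @ (eye2 - np.kron(eye, o))
             @ (eye2 - np.kron(v, v)))
        return q @ np.kron(f, eye) @ q


def reduce_qfq() -> ProjectorTermTable:
    """The operator table of the B-intermediate reduction (static data)."""
    return ProjectorTermTable()


def random_model_space(rng: np.random.Generator, dim: int = 8,
                       n_occ: int = 2, n_virt: int = 3):
    """Random Hermitian f with orthogonal projectors o, v satisfying
    o v = v o = 0 and the Brillouin-type conditions o f v = v f o = 0."""
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    occ = q[:, :n_occ]
    vir = q[:, n_occ:n_occ + n_virt]
    o = occ @ occ.T
    v = vir @ vir.T
    f = rng.standard_normal((dim, dim))
    f = 0.5 * (f + f.T)
    # enforce o f v = v f o = 0 by deleting those blocks
    f = f - o @ f @ v - v @ f @ o
    return f, o, v
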