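"""Triangular fuzzy numbers: algebra, membership, ordering, defuzzification.

A triangular fuzzy number (TFN) is an ordered triple ``(alpha, beta, gamma)``
with ``alpha <= beta <= gamma``.  Its membership function is zero outside
``[alpha, gamma]``, rises linearly to 1 at the modal value ``beta`` and falls
linearly back to zero.  TFNs carry every fuzzy quantity in this package:
linguistic ratings, criterion weights and aggregate risk indices.

Arithmetic follows the componentwise conventions standard in fuzzy FMEA and
fuzzy MCDM work: addition and multiplication act component by component, and
multiplication is restricted to non-negative supports (every linguistic scale
shipped here is non-negative).  Componentwise subtraction — needed only inside
the VIKOR compromise ranking — can disorder a triple; :func:`tfn_subtract`
therefore supports an explicit re-sorting repair mode.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import NegativeSupportError, UnknownMethodError

__all__ = [
    "TriangularFuzzyNumber",
    "TFN",
    "DefuzzMethod",
    "tfn_add",
    "tfn_subtract",
    "tfn_multiply",
    "tfn_scale",
    "tfn_membership",
    "defuzzify",
    "tfn_compare",
    "sort_key",
    "fuzzy_max",
    "fuzzy_min",
    "parse_tfn",
]


class DefuzzMethod(str, Enum):
    """Named defuzzification rules.

    ``centroid_mean``  (alpha+beta+gamma)/3 — the centroid of the triangle.
    ``graded_mean``    (alpha+4*beta+gamma)/6 — graded mean integration.
    ``likert_mean``    same formula as graded_mean; kept as a distinct name
                       for call sites that defuzzify Likert opinion triples.
    """

    CENTROID_MEAN = "centroid_mean"
    GRADED_MEAN = "graded_mean"
    LIKERT_MEAN = "likert_mean"


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """An ordered triple ``alpha <= beta <= gamma``.

    Parameters
    ----------
    alpha : float
        Left (pessimistic) support bound.
    beta : float
        Modal value, membership 1.
    gamma : float
        Right (optimistic) support bound.

    Raises
    ------
    ValueError
        If the triple is not ordered.  Use :meth:`from_triple` with
        ``repair="sort"`` to re-sort a disordered triple instead; silent
        reordering in the constructor would hide data errors.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.alpha <= self.beta <= self.gamma):
            raise ValueError(
                f"TFN components must satisfy alpha <= beta <= gamma, "
                f"got ({self.alpha}, {self.beta}, {self.gamma}); "
                f"pass repair='sort' to from_triple() to re-sort explicitly"
            )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_triple(
        cls, triple: Sequence[float], repair: str | None = None
    ) -> "TriangularFuzzyNumber":
        """Build a TFN from any length-3 sequence.

        ``repair="sort"`` sorts a disordered triple instead of raising.
        """
        a, b, c = (float(v) for v in triple)
        if repair == "sort":
            a, b, c = sorted((a, b, c))
        elif repair is not None:
            raise ValueError(f"unknown repair mode {repair!r}")
        return cls(a, b, c)

    @classmethod
    def crisp(cls, value: float) -> "TriangularFuzzyNumber":
        """Degenerate TFN representing a crisp number."""
        v = float(value)
        return cls(v, v, v)

    # -- serialization -----------------------------------------------------

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def to_json(self) -> list[float]:
        return [self.alpha, self.beta, self.gamma]

    def __str__(self) -> str:
        def fmt(v: float) -> str:
            return f"{int(v)}" if float(v).is_integer() else f"{v}"

        return f"({fmt(self.alpha)},{fmt(self.beta)},{fmt(self.gamma)})"

    # -- algebra -----------------------------------------------------------

    def __add__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return tfn_add(self, other)

    def __mul__(self, other):
        if isinstance(other, TriangularFuzzyNumber):
            return tfn_multiply(self, other)
        return tfn_scale(self, other)

    __rmul__ = __mul__

    def membership(self, x: float) -> float:
        return tfn_membership(self, x)

    def defuzzify(self, method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN) -> float:
        return defuzzify(self, method)

    @property
    def is_crisp(self) -> bool:
        return self.alpha == self.gamma


TFN = TriangularFuzzyNumber


def tfn_add(a: TFN, b: TFN) -> TFN:
    """Componentwise sum of two TFNs."""
    return TFN(a.alpha + b.alpha, a.beta + b.beta, a.gamma + b.gamma)


def tfn_subtract(a: TFN, b: TFN, repair: bool = False) -> TFN:
    """Componentwise difference ``a - b``.

    Componentwise subtraction of ordered triples is not order-preserving in
    general; with ``repair=True`` the result is re-sorted.  Without repair a
    disordered result raises ``ValueError``.  Note the triangle centroid
    (mean of components) is invariant under the re-sort, so late
    defuzzification by the centroid rule is unaffected by repair.
    """
    triple = (a.alpha - b.alpha, a.beta - b.beta, a.gamma - b.gamma)
    return TFN.from_triple(triple, repair="sort" if repair else None)


def tfn_multiply(a: TFN, b: TFN) -> TFN:
    """Componentwise product; defined for non-negative supports only."""
    for t in (a, b):
        if t.alpha < 0:
            raise NegativeSupportError(
                f"tfn_multiply requires non-negative supports, got {t}"
            )
    return TFN(a.alpha * b.alpha, a.beta * b.beta, a.gamma * b.gamma)


def tfn_scale(a: TFN, k: float) -> TFN:
    """Scale every component by a non-negative crisp factor ``k``."""
    k = float(k)
    if k < 0:
        raise NegativeSupportError(f"tfn_scale requires k >= 0, got {k}")
    return TFN(k * a.alpha, k * a.beta, k * a.gamma)


def tfn_reciprocal(a: TFN) -> TFN:
    """Fuzzy reciprocal ``1/a = (1/gamma, 1/beta, 1/alpha)`` for positive supports."""
    if a.alpha <= 0:
        raise NegativeSupportError(f"tfn_reciprocal requires a strictly positive support, got {a}")
    return TFN(1.0 / a.gamma, 1.0 / a.beta, 1.0 / a.alpha)


def tfn_membership(a: TFN, x: float) -> float:
    """Piecewise-linear triangular membership degree of ``x`` in ``a``.

    Degenerate legs (``alpha == beta`` or ``beta == gamma``) return 1 at the
    shared point so crisp TFNs behave as indicator functions.
    """
    x = float(x)
    if x < a.alpha or x > a.gamma:
        return 0.0
    if x == a.beta:
        return 1.0
    if x < a.beta:
        return (x - a.alpha) / (a.beta - a.alpha)
    return (a.gamma - x) / (a.gamma - a.beta)


def defuzzify(a: TFN, method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN) -> float:
    """Map a TFN to a crisp value in ``[alpha, gamma]``."""
    try:
        method = DefuzzMethod(method)
    except ValueError as exc:
        valid = ", ".join(m.value for m in DefuzzMethod)
        raise UnknownMethodError(f"unknown defuzzification method {method!r}; valid: {valid}") from exc
    if method is DefuzzMethod.CENTROID_MEAN:
        return (a.alpha + a.beta + a.gamma) / 3.0
    # graded mean integration; the Likert variant shares the formula
    return (a.alpha + 4.0 * a.beta + a.gamma) / 6.0


def sort_key(a: TFN, method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN):
    """Total-order key: defuzzified value, ties broken by beta, alpha, gamma."""
    return (defuzzify(a, method), a.beta, a.alpha, a.gamma)


def tfn_compare(a: TFN, b: TFN, method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN) -> int:
    """Return -1/0/+1 comparing ``a`` to ``b`` under the package's total order."""
    ka, kb = sort_key(a, method), sort_key(b, method)
    return (ka > kb) - (ka < kb)


def fuzzy_max(tfns: Iterable[TFN], method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN) -> TFN:
    """The greatest TFN under the package's total order."""
    return max(tfns, key=lambda t: sort_key(t, method))


def fuzzy_min(tfns: Iterable[TFN], method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN) -> TFN:
    return min(tfns, key=lambda t: sort_key(t, method))


_TFN_LITERAL = re.compile(
    r"^\s*\(\s*([-+0-9.eE]+)\s*,\s*([-+0-9.eE]+)\s*,\s*([-+0-9.eE]+)\s*\)\s*$"
)


def parse_tfn(text: str | Sequence[float]) -> TFN:
    """Parse a TFN literal: the string ``"(a,b,c)"`` or a JSON-style ``[a,b,c]``."""
    if isinstance(text, TriangularFuzzyNumber):
        return text
    if not isinstance(text, str):
        return TFN.from_triple(text)
    m = _TFN_LITERAL.match(text)
    if not m:
        raise ValueError(f"not a TFN literal: {text!r} (expected '(a,b,c)')")
    return TFN(float(m.group(1)), float(m.group(2)), float(m.group(3)))


def is_symmetric(a: TFN, tol: float = 1e-12) -> bool:
    """True when the TFN is symmetric about its mode (legs of equal length)."""
    return math.isclose(a.gamma - a.beta, a.beta - a.alpha, abs_tol=tol)
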