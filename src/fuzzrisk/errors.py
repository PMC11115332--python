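"""Exception hierarchy for fuzzrisk.

Every error raised by the library derives from :class:`FuzzRiskError` so
callers (and the CLI) can distinguish domain errors from programming bugs.
"""


class FuzzRiskError(Exception):
    """Base class for all fuzzrisk domain errors."""


class NegativeSupportError(FuzzRiskError):
    """Arithmetic requested on a negative support where only non-negative is defined."""


class UnknownMethodError(FuzzRiskError):
    """Defuzzification method name not recognised."""


class UnknownLabelError(FuzzRiskError):
    """Linguistic label not present in a scale; message lists valid labels."""


class MissingRatingError(FuzzRiskError):
    """A (failure mode, factor) pair has no expert rating."""


class RangeError(FuzzRiskError):
    """A crisp value lies outside its admissible range."""


class OutOfUniverseError(FuzzRiskError):
    """Crisp input outside a fuzzy variable's universe of discourse."""


class NoRuleFiredError(FuzzRiskError):
    """All rule firing strengths are zero — the rule base does not cover the input."""


class ZeroColumnError(FuzzRiskError):
    """A normalization denominator (column sum) is zero."""


class DegenerateCriterionError(FuzzRiskError):
    """Every criterion is constant across alternatives; compromise ranking undefined."""


class ZeroEntryError(FuzzRiskError):
    """Weighted-product aggregation hit a zero-valued normalized entry."""


class MismatchedAlternativesError(FuzzRiskError):
    """Two rankings/results do not cover the same alternative set."""


class DegenerateMatrixError(FuzzRiskError):
    """All rows of an index matrix are identical; ideal distances vanish."""


class UnknownFixtureError(FuzzRiskError):
    """Requested fixture name is not in the registry."""


class UnsupportedFormatError(FuzzRiskError):
    """Requested report format is not supported."""
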