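"""Mamdani max–min fuzzy inference for F-RPN.

Pipeline: fuzzify crisp O/S/D inputs against their linguistic terms, evaluate
if-then rules (min for AND, max for OR), clip each rule's consequent term at
its firing strength (min implication), aggregate clipped sets by pointwise
max over a discretised output universe, and defuzzify by the discrete
centroid sum(x*mu)/sum(mu).

The rule base behind the published transplant case is not available, so
:func:`default_rule_base` generates a complete, monotone base: the consequent
of each input-term combination is the output category nearest the mean of the
normalised ordinal positions of the three antecedent terms.  Users can supply
their own base as JSON.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import NoRuleFiredError, OutOfUniverseError
from .fmea import LinguisticScale
from .fuzzy import TFN, DefuzzMethod, defuzzify, tfn_membership

__all__ = [
    "Connective",
    "FuzzyVariable",
    "FuzzyRule",
    "RuleBase",
    "fuzzify",
    "infer",
    "default_rule_base",
    "load_rule_base",
    "save_rule_base",
]


class Connective(str, Enum):
    AND = "AND"  # min
    OR = "OR"  # max


@dataclass(frozen=True)
class FuzzyVariable:
    """A named variable over a closed real universe with linguistic terms."""

    name: str
    lo: float
    hi: float
    terms: LinguisticScale
    resolution: int = 1001

    def __post_init__(self) -> None:
        if self.hi <= self.lo:
            raise ValueError(f"variable {self.name!r}: empty universe [{self.lo}, {self.hi}]")
        if self.resolution < 100:
            raise ValueError(f"variable {self.name!r}: grid resolution must be >= 100")
        for label, t in self.terms.entries:
            if t.alpha < self.lo - 1e-12 or t.gamma > self.hi + 1e-12:
                raise ValueError(
                    f"term {label!r} support {t} outside universe [{self.lo}, {self.hi}]"
                )

    def grid(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.resolution)

    def contains(self, x: float) -> bool:
        return self.lo - 1e-12 <= x <= self.hi + 1e-12


def fuzzify(var: FuzzyVariable, x: float) -> dict[str, float]:
    """Membership degree of crisp ``x`` in every term of ``var``."""
    if not var.contains(x):
        raise OutOfUniverseError(
            f"{x} outside universe [{var.lo}, {var.hi}] of variable {var.name!r}"
        )
    return {label: tfn_membership(t, x) for label, t in var.terms.entries}


@dataclass(frozen=True)
class FuzzyRule:
    """IF <antecedents> THEN <consequent term of the output variable>."""

    antecedents: Mapping[str, str]  # variable name -> term label
    consequent: str
    connective: Connective = Connective.AND

    def key(self) -> tuple:
        return tuple(sorted(self.antecedents.items()))


@dataclass
class RuleBase:
    rules: list[FuzzyRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rule base must be non-empty")
        seen = set()
        for r in self.rules:
            k = r.key()
            if k in seen:
                raise ValueError(f"duplicate antecedent set {dict(r.antecedents)}")
            seen.add(k)

    def validate_against(self, variables: Mapping[str, FuzzyVariable], output: FuzzyVariable) -> None:
        for r in self.rules:
            for var_name, term in r.antecedents.items():
                if var_name not in variables:
                    raise ValueError(f"rule references unknown variable {var_name!r}")
                variables[var_name].terms.index_of(term)
            output.terms.index_of(r.consequent)

    def covers(self, variables: Mapping[str, FuzzyVariable]) -> bool:
        """True when every combination of input terms is matched by a rule."""
        names = sorted(variables)
        combos = itertools.product(*(variables[n].terms.labels for n in names))
        keys = {r.key() for r in self.rules}
        return all(tuple(zip(names, combo)) in keys for combo in combos)


def infer(
    rule_base: RuleBase,
    inputs: Mapping[str, float | TFN],
    variables: Mapping[str, FuzzyVariable],
    output: FuzzyVariable,
) -> float:
    """Crisp Mamdani output for ``inputs`` (crisp reals or TFNs).

    TFN inputs are fuzzified at their defuzzified (centroid) value, matching
    a workflow where the expert panel is aggregated before inference.
    """
    degrees: dict[str, dict[str, float]] = {}
    for name, var in variables.items():
        if name not in inputs:
            raise ValueError(f"missing input for variable {name!r}")
        x = inputs[name]
        if isinstance(x, TFN):
            x = defuzzify(x, DefuzzMethod.CENTROID_MEAN)
        degrees[name] = fuzzify(var, float(x))

    grid = output.grid()
    aggregate = np.zeros_like(grid)
    any_fired = False
    out_terms = dict(output.terms.entries)
    for rule in rule_base.rules:
        antecedent_degrees = [degrees[v][t] for v, t in rule.antecedents.items()]
        strength = (
            min(antecedent_degrees) if rule.connective is Connective.AND else max(antecedent_degrees)
        )
        if strength <= 0.0:
            continue
        any_fired = True
        mu = np.minimum(_membership_grid(out_terms[rule.consequent], grid), strength)
        aggregate = np.maximum(aggregate, mu)
    if not any_fired:
        raise NoRuleFiredError("no rule fired; the rule base does not cover this input")
    total = aggregate.sum()
    return float((grid * aggregate).sum() / total)


def _membership_grid(term: TFN, grid: np.ndarray) -> np.ndarray:
    """Vectorised triangular membership; degenerate legs peak at the shared point."""
    a, b, c = term.as_tuple()
    up = np.clip((grid - a) / (b - a), 0.0, 1.0) if b > a else (grid >= b).astype(float)
    down = np.clip((c - grid) / (c - b), 0.0, 1.0) if c > b else (grid <= b).astype(float)
    mu = np.minimum(up, down)
    return np.where((grid >= a) & (grid <= c), mu, 0.0)


def default_rule_base(
    variables: Mapping[str, FuzzyVariable], output: FuzzyVariable
) -> RuleBase:
    """Complete monotone rule base over all input-term combinations.

    For each combination, the consequent index is ``round(mean(p_i) * (k-1))``
    where ``p_i`` is each antecedent term's ordinal position normalised to
    [0, 1] and ``k`` the number of output terms.  Extremes map to extremes:
    all-top antecedents yield the top output category, all-bottom the bottom.
    """
    names = sorted(variables)
    n_out = len(output.terms)
    rules = []
    for combo in itertools.product(*(range(len(variables[n].terms)) for n in names)):
        positions = [
            idx / (len(variables[n].terms) - 1) if len(variables[n].terms) > 1 else 0.5
            for n, idx in zip(names, combo)
        ]
        out_idx = round(sum(positions) / len(positions) * (n_out - 1))
        rules.append(
            FuzzyRule(
                antecedents={n: variables[n].terms.labels[i] for n, i in zip(names, combo)},
                consequent=output.terms.labels[out_idx],
            )
        )
    return RuleBase(rules)


def load_rule_base(path: str | Path) -> RuleBase:
    """Read rule-base JSON: ``{"rules": [{"if": {...}, "op": "AND", "then": "VH"}]}``."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    rules = [
        FuzzyRule(
            antecedents=dict(r["if"]),
            consequent=r["then"],
            connective=Connective(r.get("op", "AND")),
        )
        for r in raw["rules"]
    ]
    return RuleBase(rules)


def save_rule_base(rule_base: RuleBase, path: str | Path) -> None:
    payload = {
        "schema_version": 1,
        "rules": [
            {"if": dict(r.antecedents), "op": r.connective.value, "then": r.consequent}
            for r in rule_base.rules
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def default_variables(
    scales: Mapping[str, LinguisticScale], resolution: int = 1001
) -> tuple[dict[str, FuzzyVariable], FuzzyVariable]:
    """Standard O/S/D input variables on [1, 10] and RPN output on [0, 1]."""
    inputs = {
        "occurrence": FuzzyVariable("occurrence", 1, 10, scales["occurrence"], resolution),
        "severity": FuzzyVariable("severity", 1, 10, scales["severity"], resolution),
        "detection": FuzzyVariable("detection", 1, 10, scales["detection"], resolution),
    }
    output = FuzzyVariable("rpn", 0, 1, scales["rpn_output"], resolution)
    return inputs, output
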