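"""Fuzzy multi-criteria rankers: F-ARAS, F-VIKOR and F-WASPAS.

All three operate on a :class:`FuzzyDecisionMatrix` — alternatives (failure
modes) in rows, criteria in columns, every cell a triangular fuzzy number —
and produce a crisp benefit-style index per alternative:

* **F-ARAS** appends a hypothetical ideal row, sum-normalises each column,
  applies weights, and reports the utility degree ``K_i = S_i / S_0`` of each
  alternative relative to the ideal (``K in (0, 1]``, higher is better).
* **F-VIKOR** measures group utility ``S_i`` and individual regret ``R_i``
  against the fuzzy best/worst values per criterion, merges them into the
  compromise index ``Q_i`` with trade-off weight ``v`` (lower is better), and
  checks the acceptable-advantage and acceptable-stability conditions.
* **F-WASPAS** mixes a weighted-sum and a weighted-product score,
  ``K'_i = lam*WSM + (1-lam)*WPM``, after max-normalising each column.

Fuzzy-arithmetic conventions that the underlying formulas leave open
(division by a fuzzy column sum, subtraction that disorders a triple, fuzzy
weights inside max/power operations) are resolved as follows: sums and
maxima/minima of TFNs use the package's defuzzified total order; divisions
use crisp (defuzzified) denominators; componentwise subtractions are
re-sorted when disordered (the centroid is invariant to the re-sort);
weights are defuzzified wherever they enter a max or an exponent.  These
choices keep every ranking exact for crisp inputs.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .errors import (
    DegenerateCriterionError,
    ZeroColumnError,
    ZeroEntryError,
)
from .fmea import FACTORS, LinguisticScale, RiskRegister, aggregate_experts, default_scales
from .fuzzy import (
    TFN,
    DefuzzMethod,
    defuzzify,
    fuzzy_max,
    fuzzy_min,
    parse_tfn,
    tfn_add,
    tfn_multiply,
    tfn_reciprocal,
    tfn_scale,
    tfn_subtract,
)
from .ranking import competition_ranks

__all__ = [
    "Criterion",
    "FuzzyDecisionMatrix",
    "ArasResult",
    "VikorResult",
    "WaspasResult",
    "aras_rank",
    "vikor_rank",
    "waspas_rank",
    "build_matrix_from_register",
]

BENEFIT = "benefit"
COST = "cost"


@dataclass(frozen=True)
class Criterion:
    """A decision criterion with a direction and a crisp or fuzzy weight."""

    name: str
    direction: str = BENEFIT
    weight: float | TFN = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (BENEFIT, COST):
            raise ValueError(f"criterion direction must be 'benefit' or 'cost', got {self.direction!r}")

    def crisp_weight(self, method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN) -> float:
        w = self.weight
        return defuzzify(w, method) if isinstance(w, TFN) else float(w)


@dataclass
class FuzzyDecisionMatrix:
    """Complete alternatives-by-criteria matrix of TFN performance scores."""

    alternatives: list[str]
    criteria: list[Criterion]
    entries: dict[tuple[str, str], TFN]  # (alternative, criterion name) -> TFN

    def __post_init__(self) -> None:
        if len(set(self.alternatives)) != len(self.alternatives):
            raise ValueError("alternative ids must be unique")
        for a in self.alternatives:
            for c in self.criteria:
                if (a, c.name) not in self.entries:
                    raise ValueError(f"missing entry for ({a!r}, {c.name!r})")
        crisp = [c.weight for c in self.criteria if not isinstance(c.weight, TFN)]
        if len(crisp) == len(self.criteria):
            total = sum(float(w) for w in crisp)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"crisp criterion weights must sum to 1, got {total}")
        else:
            total = sum(c.crisp_weight() for c in self.criteria)
            if abs(total - 1.0) > 0.05:
                warnings.warn(
                    f"defuzzified criterion weights sum to {total:.3f}, expected ~1",
                    stacklevel=2,
                )

    def column(self, name: str) -> list[TFN]:
        return [self.entries[(a, name)] for a in self.alternatives]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        criteria: Sequence[Criterion] | None = None,
        scales: Mapping[str, LinguisticScale] | None = None,
    ) -> "FuzzyDecisionMatrix":
        """Read ``fm_id`` + one column per criterion; cells are TFN literals or labels."""
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            names = [c for c in reader.fieldnames or [] if c != "fm_id"]
            rows = list(reader)
        if criteria is None:
            criteria = [Criterion(n, BENEFIT, 1.0 / len(names)) for n in names]
        scales = dict(scales or {})
        alternatives, entries = [], {}
        for row in rows:
            a = row["fm_id"].strip()
            alternatives.append(a)
            for c in criteria:
                cell = row[c.name].strip()
                if cell.startswith("("):
                    entries[(a, c.name)] = parse_tfn(cell)
                else:
                    entries[(a, c.name)] = scales[c.name].lookup(cell)
        return cls(alternatives, list(criteria), entries)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fm_id", *(c.name for c in self.criteria)])
            for a in self.alternatives:
                writer.writerow([a, *(str(self.entries[(a, c.name)]) for c in self.criteria)])


def load_criteria_config(path: str | Path) -> tuple[list[Criterion], dict]:
    """Criteria config JSON: directions, weights, and method settings."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    criteria = [
        Criterion(
            c["name"],
            c.get("direction", BENEFIT),
            parse_tfn(c["weight"]) if isinstance(c.get("weight"), (list, str)) else float(c.get("weight", 1.0)),
        )
        for c in raw.get("criteria", [])
    ]
    settings = {k: v for k, v in raw.items() if k != "criteria"}
    return criteria, settings


# ---------------------------------------------------------------------------
# shared helpers


def _benefit_view(m: FuzzyDecisionMatrix) -> dict[str, list[TFN]]:
    """Columns with cost criteria replaced by fuzzy reciprocals (benefit-oriented)."""
    view = {}
    for c in m.criteria:
        col = m.column(c.name)
        view[c.name] = [tfn_reciprocal(t) for t in col] if c.direction == COST else col
    return view


def _weighted(t: TFN, weight: float | TFN) -> TFN:
    if isinstance(weight, TFN):
        return tfn_multiply(t, weight)
    return tfn_scale(t, weight)


# ---------------------------------------------------------------------------
# F-ARAS


@dataclass
class ArasResult:
    alternatives: list[str]
    s_fuzzy: dict[str, TFN]
    s_crisp: dict[str, float]
    k: dict[str, float]
    rank: dict[str, int]
    s0: float

    def ranking(self) -> list[str]:
        return sorted(self.alternatives, key=lambda a: (self.rank[a], self.alternatives.index(a)))


def aras_rank(
    m: FuzzyDecisionMatrix, method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN
) -> ArasResult:
    """Additive ratio assessment: utility degree K_i relative to an appended ideal row."""
    cols = _benefit_view(m)
    # ideal row: fuzzy max of each (benefit-oriented) column
    ideal = {name: fuzzy_max(col, method) for name, col in cols.items()}
    s_fuzzy: dict[str, TFN] = {}
    rows = ["__ideal__", *m.alternatives]
    for c in m.criteria:
        col = [ideal[c.name], *cols[c.name]]
        colsum = sum(defuzzify(t, method) for t in col)
        if colsum == 0:
            raise ZeroColumnError(f"column {c.name!r} sums to zero; cannot normalise")
        for row_id, t in zip(rows, col):
            normalised = TFN(t.alpha / colsum, t.beta / colsum, t.gamma / colsum)
            term = _weighted(normalised, c.weight)
            s_fuzzy[row_id] = tfn_add(s_fuzzy.get(row_id, TFN.crisp(0.0)), term)
    s_crisp = {r: defuzzify(s_fuzzy[r], method) for r in rows}
    s0 = s_crisp["__ideal__"]
    k = {a: s_crisp[a] / s0 for a in m.alternatives}
    ranks = competition_ranks([k[a] for a in m.alternatives], descending=True)
    return ArasResult(
        alternatives=list(m.alternatives),
        s_fuzzy={a: s_fuzzy[a] for a in m.alternatives},
        s_crisp={a: s_crisp[a] for a in m.alternatives},
        k=k,
        rank=dict(zip(m.alternatives, ranks)),
        s0=s0,
    )


# ---------------------------------------------------------------------------
# F-VIKOR


@dataclass
class VikorResult:
    alternatives: list[str]
    s: dict[str, float]
    r: dict[str, float]
    q: dict[str, float]
    rank: dict[str, int]  # by Q, ascending (lower Q = better)
    rank_s: dict[str, int]
    rank_r: dict[str, int]
    v: float
    condition1_met: bool
    condition2_met: bool
    compromise_set: list[str]

    def ranking(self) -> list[str]:
        return sorted(self.alternatives, key=lambda a: (self.rank[a], self.alternatives.index(a)))


def vikor_rank(
    m: FuzzyDecisionMatrix,
    v: float = 0.5,
    method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN,
) -> VikorResult:
    """Compromise ranking by group utility S, individual regret R and index Q.

    Constant criteria (fuzzy best equals fuzzy worst) contribute zero to S
    and R with a warning; if every criterion is constant the ranking is
    undefined and :class:`DegenerateCriterionError` is raised.
    """
    if len(m.alternatives) < 2:
        raise ValueError("VIKOR needs at least two alternatives")
    terms: dict[str, list[TFN]] = {a: [] for a in m.alternatives}
    n_active = 0
    for c in m.criteria:
        col = m.column(c.name)
        if c.direction == BENEFIT:
            f_best, f_worst = fuzzy_max(col, method), fuzzy_min(col, method)
        else:
            f_best, f_worst = fuzzy_min(col, method), fuzzy_max(col, method)
        den = defuzzify(f_best, method) - defuzzify(f_worst, method)
        if den == 0:
            warnings.warn(
                f"criterion {c.name!r} is constant across alternatives; it contributes 0",
                stacklevel=2,
            )
            continue
        n_active += 1
        w = c.crisp_weight(method)  # weights enter a max below: defuzzify first
        for a, x in zip(m.alternatives, col):
            diff = tfn_subtract(f_best, x, repair=True)
            ratio = TFN.from_triple(
                (diff.alpha / den, diff.beta / den, diff.gamma / den), repair="sort"
            )
            terms[a].append(tfn_scale(ratio, w))
    if n_active == 0:
        raise DegenerateCriterionError("all criteria are constant; VIKOR ranking undefined")

    s_fuzzy = {a: _fuzzy_sum(ts) for a, ts in terms.items()}
    r_fuzzy = {a: fuzzy_max(ts, method) for a, ts in terms.items()}
    s_star = fuzzy_min(s_fuzzy.values(), method)
    s_minus = fuzzy_max(s_fuzzy.values(), method)
    r_star = fuzzy_min(r_fuzzy.values(), method)
    r_minus = fuzzy_max(r_fuzzy.values(), method)
    den_s = defuzzify(s_minus, method) - defuzzify(s_star, method)
    den_r = defuzzify(r_minus, method) - defuzzify(r_star, method)

    q_fuzzy: dict[str, TFN] = {}
    for a in m.alternatives:
        parts = []
        if den_s != 0:
            ds = tfn_subtract(s_fuzzy[a], s_star, repair=True)
            parts.append(
                tfn_scale(
                    TFN.from_triple((ds.alpha / den_s, ds.beta / den_s, ds.gamma / den_s), repair="sort"),
                    v,
                )
            )
        if den_r != 0:
            dr = tfn_subtract(r_fuzzy[a], r_star, repair=True)
            parts.append(
                tfn_scale(
                    TFN.from_triple((dr.alpha / den_r, dr.beta / den_r, dr.gamma / den_r), repair="sort"),
                    1.0 - v,
                )
            )
        q_fuzzy[a] = _fuzzy_sum(parts) if parts else TFN.crisp(0.0)

    s = {a: defuzzify(s_fuzzy[a], method) for a in m.alternatives}
    r = {a: defuzzify(r_fuzzy[a], method) for a in m.alternatives}
    q = {a: defuzzify(q_fuzzy[a], method) for a in m.alternatives}
    alts = m.alternatives
    rank_q = dict(zip(alts, competition_ranks([q[a] for a in alts], descending=False)))
    rank_s = dict(zip(alts, competition_ranks([s[a] for a in alts], descending=False)))
    rank_r = dict(zip(alts, competition_ranks([r[a] for a in alts], descending=False)))

    by_q = sorted(alts, key=lambda a: (q[a], alts.index(a)))
    mcount = len(alts)
    threshold = 1.0 / (mcount - 1)
    cond1 = q[by_q[1]] - q[by_q[0]] >= threshold
    cond2 = rank_s[by_q[0]] == 1 and rank_r[by_q[0]] == 1
    if cond1 and cond2:
        compromise = [by_q[0]]
    elif not cond1:
        # extend with every alternative within the advantage threshold of the best
        compromise = [a for a in by_q if q[a] - q[by_q[0]] < threshold]
    else:  # cond1 holds, cond2 fails
        compromise = by_q[:2]
    return VikorResult(
        alternatives=list(alts),
        s=s,
        r=r,
        q=q,
        rank=rank_q,
        rank_s=rank_s,
        rank_r=rank_r,
        v=v,
        condition1_met=cond1,
        condition2_met=cond2,
        compromise_set=compromise,
    )


def _fuzzy_sum(tfns) -> TFN:
    acc = TFN.crisp(0.0)
    for t in tfns:
        acc = tfn_add(acc, t)
    return acc


# ---------------------------------------------------------------------------
# F-WASPAS


@dataclass
class WaspasResult:
    alternatives: list[str]
    q_wsm: dict[str, float]
    p_wpm: dict[str, float]
    k_prime: dict[str, float]
    rank: dict[str, int]
    lam: float

    def ranking(self) -> list[str]:
        return sorted(self.alternatives, key=lambda a: (self.rank[a], self.alternatives.index(a)))


def waspas_rank(
    m: FuzzyDecisionMatrix,
    lam: float | str = 0.5,
    method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN,
) -> WaspasResult:
    """Weighted aggregated sum-product assessment ``K' = lam*WSM + (1-lam)*WPM``.

    ``lam="auto"`` uses the data-driven mixing weight
    ``lam = sum(P_i) / (sum(Q_i) + sum(P_i))``.
    """
    cols = _benefit_view(m)
    wsm_fuzzy = {a: TFN.crisp(0.0) for a in m.alternatives}
    wpm_fuzzy = {a: TFN.crisp(1.0) for a in m.alternatives}
    for c in m.criteria:
        col = cols[c.name]
        cmax = fuzzy_max(col, method)
        w_crisp = c.crisp_weight(method)  # the WPM exponent must be crisp
        for a, x in zip(m.alternatives, col):
            normalised = TFN.from_triple(
                (x.alpha / cmax.alpha, x.beta / cmax.beta, x.gamma / cmax.gamma),
                repair="sort",
            )
            wsm_fuzzy[a] = tfn_add(wsm_fuzzy[a], _weighted(normalised, c.weight))
            if normalised.alpha <= 0:
                raise ZeroEntryError(
                    f"normalised entry for ({a!r}, {c.name!r}) has a zero component; "
                    f"weighted-product aggregation undefined"
                )
            powered = TFN(
                normalised.alpha**w_crisp, normalised.beta**w_crisp, normalised.gamma**w_crisp
            )
            wpm_fuzzy[a] = tfn_multiply(wpm_fuzzy[a], powered)
    q = {a: defuzzify(wsm_fuzzy[a], method) for a in m.alternatives}
    p = {a: defuzzify(wpm_fuzzy[a], method) for a in m.alternatives}
    if lam == "auto":
        lam_val = sum(p.values()) / (sum(q.values()) + sum(p.values()))
    else:
        lam_val = float(lam)
        if not 0.0 <= lam_val <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {lam_val}")
    k_prime = {a: lam_val * q[a] + (1.0 - lam_val) * p[a] for a in m.alternatives}
    ranks = competition_ranks([k_prime[a] for a in m.alternatives], descending=True)
    return WaspasResult(
        alternatives=list(m.alternatives),
        q_wsm=q,
        p_wpm=p,
        k_prime=k_prime,
        rank=dict(zip(m.alternatives, ranks)),
        lam=lam_val,
    )


# ---------------------------------------------------------------------------
# register -> matrix


def build_matrix_from_register(
    register: RiskRegister,
    scales: Mapping[str, LinguisticScale] | None = None,
    weights: Mapping[str, float] | None = None,
) -> FuzzyDecisionMatrix:
    """Expert-aggregated O/S/D decision matrix.

    All three factors are benefit criteria when ranking risk — the scales
    are oriented so a higher TFN means more frequent, more severe, or harder
    to detect — with equal weights 1/3 by default.  Only failure modes with
    complete ratings enter the matrix.
    """
    scales = dict(scales or default_scales())
    weights = dict(weights or {f: 1.0 / 3.0 for f in FACTORS})
    criteria = [Criterion(f, BENEFIT, weights[f]) for f in FACTORS]
    fm_ids = register.rated_fm_ids()
    if not fm_ids:
        raise ValueError("register has no completely rated failure modes")
    entries = {}
    for fm_id in fm_ids:
        for f in FACTORS:
            entries[(fm_id, f)] = aggregate_experts(register, fm_id, f, scales.get(f))
    return FuzzyDecisionMatrix(fm_ids, criteria, entries)
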