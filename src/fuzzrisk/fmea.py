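"""Risk register, linguistic scales, expert aggregation and (fuzzy) RPN.

Failure Modes and Effects Analysis (FMEA) scores each failure mode on three
factors — Occurrence (O), Severity (S) and Detection (D) — and prioritises by
the Risk Priority Number RPN = O*S*D.  The fuzzy variant rates each factor
with a linguistic label mapped to a triangular fuzzy number, averages the
expert panel, and multiplies the three TFNs componentwise into a fuzzy RPN
(F-RPN), defuzzified for ranking.

The default linguistic scales ship as package data: 9-level occurrence and
severity ladders on [1, 10], a 5-level detection ladder on [1, 10] (oriented
so that a *harder to detect* failure scores higher), and a 5-level output
vocabulary (VL..VH) on [0, 1].  All scales are user-overridable via JSON.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import MissingRatingError, RangeError, UnknownLabelError
from .fuzzy import TFN, DefuzzMethod, defuzzify, parse_tfn, tfn_multiply, tfn_scale
from .ranking import competition_ranks

__all__ = [
    "LinguisticScale",
    "FailureMode",
    "RiskRegister",
    "FrpnResult",
    "FACTORS",
    "default_scales",
    "load_scales",
    "lookup_label",
    "aggregate_experts",
    "traditional_rpn",
    "fuzzy_rpn",
    "rank_by_frpn",
]

FACTORS = ("occurrence", "severity", "detection")


@dataclass(frozen=True)
class LinguisticScale:
    """Named, ordered mapping from linguistic labels to TFNs.

    Entries must be unique by label (case-insensitively) and ordered by
    non-decreasing defuzzified value.  ``aliases`` maps alternative
    spellings/abbreviations onto canonical labels.
    """

    name: str
    entries: tuple[tuple[str, TFN], ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [lab.casefold() for lab, _ in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError(f"scale {self.name!r} has duplicate labels")
        vals = [defuzzify(t) for _, t in self.entries]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(
                f"scale {self.name!r} entries must be ordered by non-decreasing defuzzified value"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, label: str) -> TFN:
        return lookup_label(self, label)

    def index_of(self, label: str) -> int:
        """Ordinal position (0 = least severe/likely) of a label."""
        canon = self._canonical(label)
        for i, (lab, _) in enumerate(self.entries):
            if lab.casefold() == canon:
                return i
        raise UnknownLabelError(self._unknown_message(label))

    def nearest_label(self, crisp: float, method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN) -> str:
        """Label whose TFN defuzzifies nearest to ``crisp``; ties go to the higher category."""
        best: tuple[float, int] | None = None
        for i, (_, t) in enumerate(self.entries):
            d = abs(defuzzify(t, method) - crisp)
            if best is None or d < best[0] or (d == best[0] and i > best[1]):
                best = (d, i)
        assert best is not None
        return self.entries[best[1]][0]

    # -- internals ---------------------------------------------------------

    def _canonical(self, label: str) -> str:
        fold = label.strip().casefold()
        alias_map = {k.casefold(): v for k, v in self.aliases.items()}
        if fold in alias_map:
            fold = alias_map[fold].casefold()
        return fold

    def _unknown_message(self, label: str) -> str:
        return (
            f"unknown label {label!r} on scale {self.name!r}; "
            f"valid labels: {', '.join(self.labels)}"
        )

    @classmethod
    def from_json_obj(cls, name: str, obj) -> "LinguisticScale":
        """Accept either a bare entry list or ``{"entries": [...], "aliases": {...}}``."""
        if isinstance(obj, list):
            entries, aliases = obj, {}
        else:
            entries, aliases = obj["entries"], obj.get("aliases", {})
        pairs = tuple((e["label"], parse_tfn(e["tfn"])) for e in entries)
        return cls(name=name, entries=pairs, aliases=dict(aliases))


def lookup_label(scale: LinguisticScale, label: str) -> TFN:
    """The scale's TFN for ``label`` (case-insensitive, alias-aware)."""
    canon = scale._canonical(label)
    for lab, t in scale.entries:
        if lab.casefold() == canon:
            return t
    raise UnknownLabelError(scale._unknown_message(label))


def load_scales(path: str | Path) -> dict[str, LinguisticScale]:
    """Load a scale registry from a JSON file."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {name: LinguisticScale.from_json_obj(name, obj) for name, obj in raw.items()}


def default_scales() -> dict[str, LinguisticScale]:
    """The packaged default scale registry (occurrence/severity/detection/rpn_output)."""
    ref = resources.files("fuzzrisk").joinpath("data/paper/scales.json")
    raw = json.loads(ref.read_text(encoding="utf-8"))
    return {name: LinguisticScale.from_json_obj(name, obj) for name, obj in raw.items()}


@dataclass(frozen=True)
class FailureMode:
    """One row of the risk register: an identified post-failure scenario."""

    fm_id: str
    description: str = ""
    cause: str = ""
    effect: str = ""


@dataclass
class RiskRegister:
    """Failure modes with per-expert linguistic (or TFN) O/S/D ratings.

    ``ratings`` maps ``(fm_id, factor, expert_id)`` to either a scale label
    or a TFN.  Expert weights default to uniform and must sum to 1.
    """

    failure_modes: list[FailureMode]
    ratings: dict[tuple[str, str, str], str | TFN]
    expert_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [fm.fm_id for fm in self.failure_modes]
        if len(set(ids)) != len(ids):
            raise ValueError("fm_id values must be unique within a register")
        experts = sorted({e for (_, _, e) in self.ratings})
        if not self.expert_weights:
            w = 1.0 / len(experts) if experts else 0.0
            self.expert_weights = {e: w for e in experts}
        total = sum(self.expert_weights.values())
        if experts and abs(total - 1.0) > 1e-9:
            raise ValueError(f"expert weights must sum to 1, got {total}")
        if any(w < 0 for w in self.expert_weights.values()):
            raise ValueError("expert weights must be non-negative")

    @property
    def fm_ids(self) -> list[str]:
        return [fm.fm_id for fm in self.failure_modes]

    def experts_for(self, fm_id: str, factor: str) -> list[str]:
        return sorted({e for (f, fac, e) in self.ratings if f == fm_id and fac == factor})

    def rated_fm_ids(self) -> list[str]:
        """Failure modes having at least one rating for every factor."""
        return [
            fm.fm_id
            for fm in self.failure_modes
            if all(self.experts_for(fm.fm_id, fac) for fac in FACTORS)
        ]

    # -- CSV I/O -----------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        ratings_path: str | Path,
        metadata_path: str | Path | None = None,
        expert_weights: Mapping[str, float] | None = None,
    ) -> "RiskRegister":
        """Read ratings CSV ``fm_id,expert_id,occurrence,severity,detection``.

        Cells hold scale labels or TFN literals ``(a,b,c)``; empty cells are
        treated as missing ratings.  Optional metadata CSV:
        ``fm_id,description,cause,effect``.
        """
        ratings: dict[tuple[str, str, str], str | TFN] = {}
        order: list[str] = []
        with open(ratings_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                fm_id = row["fm_id"].strip()
                if fm_id not in order:
                    order.append(fm_id)
                expert = row.get("expert_id", "expert1").strip() or "expert1"
                for factor in FACTORS:
                    cell = (row.get(factor) or "").strip()
                    if not cell:
                        continue
                    value: str | TFN
                    value = parse_tfn(cell) if cell.startswith("(") else cell
                    ratings[(fm_id, factor, expert)] = value
        meta: dict[str, FailureMode] = {}
        if metadata_path is not None:
            with open(metadata_path, newline="", encoding="utf-8") as fh:
                for row in csv.DictReader(fh):
                    fm = FailureMode(
                        fm_id=row["fm_id"].strip(),
                        description=(row.get("description") or "").strip(),
                        cause=(row.get("cause") or "").strip(),
                        effect=(row.get("effect") or "").strip(),
                    )
                    meta[fm.fm_id] = fm
                    if fm.fm_id not in order:
                        order.append(fm.fm_id)
        failure_modes = [meta.get(fm_id, FailureMode(fm_id)) for fm_id in order]
        return cls(failure_modes, ratings, dict(expert_weights or {}))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fm_id", "expert_id", *FACTORS])
            experts = sorted({e for (_, _, e) in self.ratings})
            for fm in self.failure_modes:
                for expert in experts:
                    cells = []
                    for factor in FACTORS:
                        v = self.ratings.get((fm.fm_id, factor, expert), "")
                        cells.append(str(v))
                    if any(cells):
                        writer.writerow([fm.fm_id, expert, *cells])


def _rating_tfn(value: str | TFN, scale: LinguisticScale | None) -> TFN:
    if isinstance(value, TFN):
        return value
    if scale is None:
        raise UnknownLabelError(f"label {value!r} given but no scale supplied")
    return lookup_label(scale, value)


def aggregate_experts(
    register: RiskRegister,
    fm_id: str,
    factor: str,
    scale: LinguisticScale | None = None,
) -> TFN:
    """Expert-weight-weighted componentwise mean of the panel's TFN ratings.

    Weights are renormalized over the experts who actually rated the pair,
    so a missing single expert does not silently shrink the mean.
    """
    experts = register.experts_for(fm_id, factor)
    if not experts:
        raise MissingRatingError(f"no rating for ({fm_id!r}, {factor!r})")
    weights = [register.expert_weights.get(e, 0.0) for e in experts]
    total = sum(weights)
    if total <= 0:
        weights = [1.0] * len(experts)
        total = float(len(experts))
    acc = TFN.crisp(0.0)
    for e, w in zip(experts, weights):
        t = _rating_tfn(register.ratings[(fm_id, factor, e)], scale)
        acc = acc + tfn_scale(t, w / total)
    return acc


def traditional_rpn(o: int, s: int, d: int) -> int:
    """Crisp RPN = O*S*D on 1–10 integer scales (range 1–1000)."""
    for name, v in (("occurrence", o), ("severity", s), ("detection", d)):
        if not (isinstance(v, int) and 1 <= v <= 10):
            raise RangeError(f"{name} must be an integer in 1..10, got {v!r}")
    return o * s * d


@dataclass(frozen=True)
class FrpnResult:
    """Fuzzy RPN of one failure mode.

    ``crisp`` is the defuzzified F-RPN on the natural (product) scale;
    ``crisp_normalized`` maps it onto [0, 1] by the scale maximum (1000 for
    the default 1–10 ladders) for comparison with the output vocabulary;
    ``label`` is the output category whose defuzzified value is nearest.
    """

    fm_id: str
    frpn: TFN
    crisp: float
    crisp_normalized: float
    label: str
    rank: int | None = None


def fuzzy_rpn(
    o: TFN,
    s: TFN,
    d: TFN,
    fm_id: str = "",
    output_scale: LinguisticScale | None = None,
    method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN,
    normalizer: float = 1000.0,
) -> FrpnResult:
    """Componentwise triple product F-RPN = S*O*D with crisp value and label."""
    frpn = tfn_multiply(tfn_multiply(s, o), d)
    crisp = defuzzify(frpn, method)
    crisp_norm = crisp / normalizer
    if output_scale is None:
        output_scale = default_scales()["rpn_output"]
    label = output_scale.nearest_label(crisp_norm, method)
    return FrpnResult(fm_id, frpn, crisp, crisp_norm, label)


def rank_by_frpn(results: Iterable[FrpnResult]) -> list[FrpnResult]:
    """Descending crisp F-RPN with competition ranks; stable by input order."""
    items = list(results)
    if not items:
        raise ValueError("rank_by_frpn needs at least one result")
    ranks = competition_ranks([r.crisp for r in items], descending=True)
    ranked = [
        (pos, FrpnResult(r.fm_id, r.frpn, r.crisp, r.crisp_normalized, r.label, rank))
        for pos, (r, rank) in enumerate(zip(items, ranks))
    ]
    ranked.sort(key=lambda pr: (pr[1].rank, pr[0]))
    return [r for _, r in ranked]


def score_register(
    register: RiskRegister,
    scales: Mapping[str, LinguisticScale] | None = None,
    method: DefuzzMethod | str = DefuzzMethod.CENTROID_MEAN,
) -> list[FrpnResult]:
    """Aggregate experts and compute ranked multiplicative F-RPNs for a register."""
    scales = dict(scales or default_scales())
    results = []
    for fm_id in register.rated_fm_ids():
        o = aggregate_experts(register, fm_id, "occurrence", scales.get("occurrence"))
        s = aggregate_experts(register, fm_id, "severity", scales.get("severity"))
        d = aggregate_experts(register, fm_id, "detection", scales.get("detection"))
        results.append(
            fuzzy_rpn(o, s, d, fm_id=fm_id, output_scale=scales.get("rpn_output"), method=method)
        )
    return rank_by_frpn(results)
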