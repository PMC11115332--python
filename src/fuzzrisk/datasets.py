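"""Packaged worked-example fixtures, a synthetic register generator, and
rank-agreement metrics.

The fixtures transcribe the published organ-transplant case study that this
package reproduces: the 20-failure-mode risk register (linguistic O/S/D
grades are available for the first ten modes; the remainder were published
only in supplementary material and are left explicitly missing), the
20 x 3 per-method benefit-index matrix, the expected hybrid-stage output,
and one validation expert's optimistic/neutral/pessimistic Likert triples.

The synthetic generator produces seeded risk registers with an optional
*dominance chain*: the first ``k`` failure modes receive componentwise
strictly ordered linguistic grades, so their true risk order is known by
construction and every ranker in the package can be checked against it.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MismatchedAlternativesError, UnknownFixtureError
from .fmea import (
    FACTORS,
    FailureMode,
    LinguisticScale,
    RiskRegister,
    default_scales,
)
from .fuzzy import TFN, DefuzzMethod, defuzzify
from .hybrid import MethodIndexMatrix

__all__ = [
    "load_fixture",
    "SyntheticSpec",
    "generate_register",
    "defuzzify_expert_panel",
    "AgreementReport",
    "rank_agreement",
    "tally_causes",
    "HybridExpected",
]


def _data(name: str) -> str:
    return resources.files("fuzzrisk").joinpath(f"data/paper/{name}").read_text(encoding="utf-8")


@dataclass
class HybridExpected:
    """Published hybrid-stage output: per-mode psi+/psi-/UUI/rank plus column sums."""

    table: pd.DataFrame
    sum_psi_plus: float
    sum_psi_minus: float


def _load_register() -> RiskRegister:
    rows = list(csv.DictReader(_data("failure_modes.csv").splitlines()))
    modes = [
        FailureMode(
            r["fm_id"],
            r.get("description", ""),
            r.get("cause", ""),
            r.get("effect", ""),
        )
        for r in rows
    ]
    ratings: dict[tuple[str, str, str], str | TFN] = {}
    for r in rows:
        for factor in FACTORS:
            cell = (r.get(factor) or "").strip()
            if cell:
                ratings[(r["fm_id"], factor, "panel")] = cell
    return RiskRegister(modes, ratings, {"panel": 1.0})


def _load_outputs() -> pd.DataFrame:
    frame = pd.read_csv(
        pd.io.common.StringIO(_data("failure_modes.csv")), index_col="fm_id"
    )
    return frame[["output_label", "output_crisp"]].dropna()


def _load_hybrid_expected() -> HybridExpected:
    frame = pd.read_csv(pd.io.common.StringIO(_data("hybrid_expected.csv")), index_col="fm_id")
    sums = frame.loc["SUM"]
    table = frame.drop(index="SUM")
    table = table.assign(rank=table["rank"].astype(int))
    return HybridExpected(
        table=table,
        sum_psi_plus=float(sums["psi_plus"]),
        sum_psi_minus=float(sums["psi_minus"]),
    )


def _load_expert_panel() -> dict[tuple[str, str], tuple[int, int, int]]:
    triples: dict[tuple[str, str], tuple[int, int, int]] = {}
    for r in csv.DictReader(_data("expert_panel.csv").splitlines()):
        triples[(r["expert"], r["fm_id"])] = (
            int(r["optimistic"]),
            int(r["neutral"]),
            int(r["pessimistic"]),
        )
    return triples


def _load_likert() -> dict[str, int]:
    return dict(json.loads(_data("likert.json"))["levels"])


_FIXTURES = {
    "scales": default_scales,
    "transplant_register": _load_register,
    "table6": _load_register,
    "transplant_outputs": _load_outputs,
    "table6_outputs": _load_outputs,
    "method_indices": lambda: MethodIndexMatrix(
        pd.read_csv(pd.io.common.StringIO(_data("method_indices.csv")), index_col="fm_id")
    ),
    "table7": lambda: MethodIndexMatrix(
        pd.read_csv(pd.io.common.StringIO(_data("method_indices.csv")), index_col="fm_id")
    ),
    "hybrid_expected": _load_hybrid_expected,
    "table8_expected": _load_hybrid_expected,
    "expert_panel": _load_expert_panel,
    "table11": _load_expert_panel,
    "likert": _load_likert,
    "table5_likert": _load_likert,
}


def load_fixture(name: str):
    """Load a packaged fixture by name (descriptive names and table aliases)."""
    try:
        loader = _FIXTURES[name]
    except KeyError as exc:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(_FIXTURES))}"
        ) from exc
    return loader()


# ---------------------------------------------------------------------------
# synthetic registers


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic register generator.

    Defaults mirror the case-study conditions: 20 failure modes rated by a
    five-expert panel.  ``dominance_fraction`` controls how many modes are
    forced into a strict componentwise dominance chain (0 = none); ``noise``
    is the magnitude of per-expert categorical jitter around each mode's
    true grade, in scale steps.
    """

    n_failure_modes: int = 20
    n_experts: int = 5
    scales: Mapping[str, LinguisticScale] | None = None
    dominance_fraction: float = 0.0
    noise: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_failure_modes < 2:
            raise ValueError("need at least 2 failure modes")
        if not 0.0 <= self.dominance_fraction <= 1.0:
            raise ValueError("dominance_fraction must lie in [0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")

    @property
    def n_chain(self) -> int:
        return round(self.dominance_fraction * self.n_failure_modes)

    def chain_ids(self) -> list[str]:
        """Ids of the dominance-chain modes, most risky first (ground truth)."""
        return [f"FM{i + 1}" for i in range(self.n_chain)]


def generate_register(spec: SyntheticSpec) -> RiskRegister:
    """Seeded synthetic risk register with an optional known dominance chain.

    Chain modes receive strictly ordered grades (FM1 most risky); a chain
    longer than 9 cannot stay strict on 9-level ladders and is rejected.
    Remaining modes draw uniform grades.  Each expert's reported label is the
    mode's true grade jittered by up to ``noise`` scale steps.
    """
    scales = dict(spec.scales or default_scales())
    factor_scales = {f: scales[f] for f in FACTORS}
    k = spec.n_chain
    if k > 9:
        raise ValueError("dominance chain longer than 9 cannot stay strict on 9-level scales")
    rng = np.random.default_rng(spec.seed)
    fm_ids = [f"FM{i + 1}" for i in range(spec.n_failure_modes)]
    experts = [f"expert{i + 1}" for i in range(spec.n_experts)]

    true_idx: dict[tuple[str, str], int] = {}
    for j, fm_id in enumerate(fm_ids):
        for f, scale in factor_scales.items():
            top = len(scale) - 1
            if j < k:
                frac = (k - 1 - j) / (k - 1) if k > 1 else 1.0
                true_idx[(fm_id, f)] = round(frac * top)
            else:
                true_idx[(fm_id, f)] = int(rng.integers(0, top + 1))

    ratings: dict[tuple[str, str, str], str | TFN] = {}
    for fm_id in fm_ids:
        for f, scale in factor_scales.items():
            top = len(scale) - 1
            for e in experts:
                jitter = int(rng.integers(-spec.noise, spec.noise + 1)) if spec.noise else 0
                idx = min(max(true_idx[(fm_id, f)] + jitter, 0), top)
                ratings[(fm_id, f, e)] = scale.labels[idx]

    modes = [FailureMode(fm_id, description=f"synthetic failure mode {fm_id}") for fm_id in fm_ids]
    return RiskRegister(modes, ratings)


# ---------------------------------------------------------------------------
# expert validation


def defuzzify_expert_panel(
    triples: Mapping[tuple[str, str], Sequence[float]]
) -> dict[tuple[str, str], float]:
    """Defuzzify (optimistic, neutral, pessimistic) Likert triples.

    Each triple is read as a TFN and mapped to (alpha + 4*beta + gamma) / 6.
    Unordered triples are sorted with a warning (they are stored as printed).
    """
    out: dict[tuple[str, str], float] = {}
    for key, triple in triples.items():
        a, b, c = (float(v) for v in triple)
        if not a <= b <= c:
            warnings.warn(f"triple {triple} for {key} is unordered; sorting", stacklevel=2)
            a, b, c = sorted((a, b, c))
        out[key] = defuzzify(TFN(a, b, c), DefuzzMethod.LIKERT_MEAN)
    return out


@dataclass
class AgreementReport:
    """Rank agreement between a method's ordering and a reference ordering."""

    spearman_rho: float
    kendall_tau: float
    top_k_overlap: float
    mean_abs_rank_diff: float
    k: int = 5


def rank_agreement(
    method_ranking: Sequence[str],
    reference_ranking: Sequence[str],
    k: int = 5,
) -> AgreementReport:
    """Spearman/Kendall correlation, top-k overlap and mean |rank difference|.

    Both arguments are orderings (best first) over the same alternative set.
    """
    if set(method_ranking) != set(reference_ranking):
        raise MismatchedAlternativesError(
            f"rankings cover different alternatives: "
            f"{sorted(set(method_ranking) ^ set(reference_ranking))}"
        )
    if len(set(method_ranking)) != len(method_ranking):
        raise ValueError("rankings must not contain duplicates")
    ids = list(method_ranking)
    pos_m = {a: i for i, a in enumerate(method_ranking)}
    pos_r = {a: i for i, a in enumerate(reference_ranking)}
    xm = [pos_m[a] for a in ids]
    xr = [pos_r[a] for a in ids]
    rho = float(stats.spearmanr(xm, xr).statistic)
    tau = float(stats.kendalltau(xm, xr).statistic)
    kk = min(k, len(ids))
    overlap = len(set(method_ranking[:kk]) & set(reference_ranking[:kk])) / kk
    mad = float(np.mean([abs(pos_m[a] - pos_r[a]) for a in ids]))
    return AgreementReport(rho, tau, overlap, mad, k=kk)


def tally_causes(modes: Sequence[FailureMode]) -> pd.Series:
    """Count failure modes per root cause (empty causes are dropped)."""
    causes = [fm.cause for fm in modes if fm.cause]
    return pd.Series(causes, dtype="object").value_counts()
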