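"""Hybrid rank aggregation via distances to ideal index vectors.

Different MCDM rankers apply different logic and frequently disagree; the
hybrid stage merges them.  Inputs are per-method *benefit* indices in [0, 1]
(ARAS ``K_i``, VIKOR transformed to ``1 - Q_i``, WASPAS ``K'_i``).  For each
method column the per-column maximum (eta+) and minimum (eta-) over the
failure modes define positive/negative ideal vectors; each row's Euclidean
distances to them, ``psi+`` and ``psi-``, are normalised by their column
sums and differenced into the Ultimate Utility Index

    UUI_c = psi-_c / sum(psi-) - psi+_c / sum(psi+),   -1 <= UUI <= 1.

Higher UUI means closer to the per-method maxima and farther from the
minima, i.e. higher risk priority.  By construction the UUIs of all rows sum
to zero.  Any number (>= 1) of method columns is accepted; the default is
the three above.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateMatrixError, MismatchedAlternativesError, RangeError
from .mcdm import ArasResult, VikorResult, WaspasResult
from .ranking import competition_ranks

__all__ = [
    "MethodIndexMatrix",
    "HybridResult",
    "to_benefit_indices",
    "ideal_vectors",
    "ideal_distances",
    "ultimate_utility",
]

DEFAULT_COLUMNS = ("aras_k", "vikor_1mq", "waspas_k")
_BOUND_TOL = 1e-9


@dataclass
class MethodIndexMatrix:
    """Failure modes x method benefit indices, all values in [0, 1]."""

    frame: pd.DataFrame  # index: fm_id, columns: method names

    def __post_init__(self) -> None:
        f = self.frame
        if f.shape[0] < 2 or f.shape[1] < 1:
            raise ValueError(f"index matrix needs >=2 rows and >=1 column, got {f.shape}")
        vals = f.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("index matrix contains missing values")
        if (vals < -_BOUND_TOL).any() or (vals > 1.0 + _BOUND_TOL).any():
            bad = vals[(vals < -_BOUND_TOL) | (vals > 1.0 + _BOUND_TOL)]
            raise RangeError(f"benefit indices must lie in [0, 1]; offending values: {bad}")
        # clip values within numerical tolerance of the bounds
        self.frame = f.clip(lower=0.0, upper=1.0).astype(float)

    @property
    def fm_ids(self) -> list[str]:
        return list(self.frame.index)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MethodIndexMatrix":
        frame = pd.read_csv(path, index_col="fm_id")
        return cls(frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="fm_id")


def to_benefit_indices(
    aras: ArasResult, vikor: VikorResult, waspas: WaspasResult
) -> MethodIndexMatrix:
    """Assemble the hybrid input: columns ``K_i``, ``1 - Q_i``, ``K'_i``."""
    ids = list(aras.alternatives)
    for other in (vikor.alternatives, waspas.alternatives):
        if set(other) != set(ids):
            raise MismatchedAlternativesError(
                f"method results cover different alternatives: {sorted(set(ids) ^ set(other))}"
            )
    frame = pd.DataFrame(
        {
            "aras_k": [aras.k[a] for a in ids],
            "vikor_1mq": [1.0 - vikor.q[a] for a in ids],
            "waspas_k": [waspas.k_prime[a] for a in ids],
        },
        index=pd.Index(ids, name="fm_id"),
    )
    return MethodIndexMatrix(frame)


def ideal_vectors(m: MethodIndexMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-column maximum (eta+) and minimum (eta-) over all failure modes."""
    return m.frame.max(axis=0), m.frame.min(axis=0)


def ideal_distances(m: MethodIndexMatrix) -> pd.DataFrame:
    """Euclidean distances of every row to the positive/negative ideal vectors."""
    eta_plus, eta_minus = ideal_vectors(m)
    vals = m.frame.to_numpy(dtype=float)
    psi_plus = np.sqrt(((vals - eta_plus.to_numpy()) ** 2).sum(axis=1))
    psi_minus = np.sqrt(((vals - eta_minus.to_numpy()) ** 2).sum(axis=1))
    return pd.DataFrame({"psi_plus": psi_plus, "psi_minus": psi_minus}, index=m.frame.index)


@dataclass
class HybridResult:
    """Per-failure-mode psi+/psi-, UUI and rank, plus the ideal vectors and sums."""

    table: pd.DataFrame  # columns: psi_plus, psi_minus, uui, rank
    eta_plus: pd.Series
    eta_minus: pd.Series
    sum_psi_plus: float
    sum_psi_minus: float

    def ranking(self) -> list[str]:
        return list(self.table.sort_values("rank", kind="stable").index)


def ultimate_utility(m: MethodIndexMatrix) -> HybridResult:
    """Compute psi+/psi-, UUI and descending-UUI competition ranks."""
    dist = ideal_distances(m)
    sum_plus = float(dist["psi_plus"].sum())
    sum_minus = float(dist["psi_minus"].sum())
    if sum_plus == 0.0 or sum_minus == 0.0:
        raise DegenerateMatrixError(
            "all rows of the index matrix are identical; ideal distances vanish"
        )
    uui = dist["psi_minus"] / sum_minus - dist["psi_plus"] / sum_plus
    ranks = competition_ranks(uui.to_list(), descending=True)
    table = dist.assign(uui=uui, rank=ranks)
    eta_plus, eta_minus = ideal_vectors(m)
    return HybridResult(
        table=table,
        eta_plus=eta_plus,
        eta_minus=eta_minus,
        sum_psi_plus=sum_plus,
        sum_psi_minus=sum_minus,
    )
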