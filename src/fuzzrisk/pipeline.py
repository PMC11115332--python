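"""End-to-end orchestration: register -> F-RPN -> MCDM rankers -> hybrid -> report.

The pipeline is deterministic given its configuration; every stage logs its
input/output dimensions to the ``fuzzrisk`` logger (stderr under the CLI) so
machine-readable output never mixes with diagnostics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import UnsupportedFormatError
from .fmea import FACTORS, RiskRegister, default_scales, load_scales, score_register
from .fuzzy import DefuzzMethod
from .hybrid import to_benefit_indices, ultimate_utility
from .mamdani import default_rule_base, default_variables, infer, load_rule_base
from .mcdm import aras_rank, build_matrix_from_register, vikor_rank, waspas_rank

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_report"]

log = logging.getLogger("fuzzrisk")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Settings for the full pipeline; defaults reproduce the reference setup:

    equal O/S/D weights, VIKOR trade-off v=0.5, WASPAS mixing lambda=0.5,
    centroid defuzzification, 1001-point Mamdani grid.
    """

    scales_path: str | None = None
    rules_path: str | None = None
    defuzz_method: str = DefuzzMethod.CENTROID_MEAN.value
    vikor_v: float = 0.5
    waspas_lambda: float | str = 0.5
    weights: Mapping[str, float] = field(
        default_factory=lambda: {f: 1.0 / 3.0 for f in FACTORS}
    )
    grid_resolution: int = 1001
    run_mamdani: bool = False
    precision: int = 6
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw.pop("schema_version", None)
        return cls(**raw)


@dataclass
class RunReport:
    """One row per failure mode with every score and rank the pipeline produced."""

    table: pd.DataFrame
    config: PipelineConfig

    def rank_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("rank_")]


def run_pipeline(config: PipelineConfig, register: RiskRegister | str | Path) -> RunReport:
    """Execute scoring, the three rankers and the hybrid stage on a register."""
    if not isinstance(register, RiskRegister):
        register = RiskRegister.from_csv(register)
    scales = load_scales(config.scales_path) if config.scales_path else default_scales()
    method = DefuzzMethod(config.defuzz_method)

    fm_ids = register.rated_fm_ids()
    if not fm_ids:
        raise ValueError("register has no completely rated failure modes")
    log.info("register: %d failure modes, %d rated", len(register.failure_modes), len(fm_ids))

    frpn = {r.fm_id: r for r in score_register(register, scales, method)}
    log.info("f-rpn stage: %d results", len(frpn))

    matrix = build_matrix_from_register(register, scales, config.weights)
    aras = aras_rank(matrix, method)
    vikor = vikor_rank(matrix, config.vikor_v, method)
    waspas = waspas_rank(matrix, config.waspas_lambda, method)
    log.info("mcdm stage: matrix %d x %d", len(matrix.alternatives), len(matrix.criteria))

    indices = to_benefit_indices(aras, vikor, waspas)
    hybrid = ultimate_utility(indices)
    log.info("hybrid stage: %d rows", len(hybrid.table))

    rows = []
    for fm_id in fm_ids:
        row = {
            "fm_id": fm_id,
            "frpn_crisp": frpn[fm_id].crisp,
            "frpn_normalized": frpn[fm_id].crisp_normalized,
            "frpn_label": frpn[fm_id].label,
            "rank_frpn": frpn[fm_id].rank,
            "aras_k": aras.k[fm_id],
            "rank_aras": aras.rank[fm_id],
            "vikor_q": vikor.q[fm_id],
            "vikor_1mq": 1.0 - vikor.q[fm_id],
            "rank_vikor": vikor.rank[fm_id],
            "waspas_k": waspas.k_prime[fm_id],
            "rank_waspas": waspas.rank[fm_id],
            "psi_plus": hybrid.table.loc[fm_id, "psi_plus"],
            "psi_minus": hybrid.table.loc[fm_id, "psi_minus"],
            "uui": hybrid.table.loc[fm_id, "uui"],
            "rank_hybrid": int(hybrid.table.loc[fm_id, "rank"]),
        }
        rows.append(row)
    table = pd.DataFrame(rows).set_index("fm_id")

    if config.run_mamdani:
        variables, output = default_variables(scales, config.grid_resolution)
        rules = (
            load_rule_base(config.rules_path)
            if config.rules_path
            else default_rule_base(variables, output)
        )
        from .fmea import aggregate_experts  # local import to avoid cycle at module load

        mamdani_scores = {}
        for fm_id in fm_ids:
            inputs = {
                f: aggregate_experts(register, fm_id, f, scales.get(f)) for f in FACTORS
            }
            mamdani_scores[fm_id] = infer(rules, inputs, variables, output)
        table["mamdani_rpn"] = pd.Series(mamdani_scores)
        log.info("mamdani stage: %d rules", len(rules.rules))

    return RunReport(table=table, config=config)


def render_report(report: RunReport, fmt: str = "csv", path: str | Path | None = None) -> str:
    """Render a report as csv, json or markdown at the configured precision."""
    p = report.config.precision
    table = report.table.round(p)
    if fmt == "csv":
        text = table.to_csv(index_label="fm_id")
    elif fmt == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "precision": p,
            "rows": json.loads(table.to_json(orient="index")),
        }
        text = json.dumps(payload, indent=1)
    elif fmt == "markdown":
        header = ["fm_id", *table.columns]
        lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
        for fm_id, row in table.iterrows():
            lines.append("| " + " | ".join([str(fm_id), *(str(v) for v in row)]) + " |")
        lines.append("")
        lines.append("Top 5 per method:")
        for col in report.rank_columns():
            top = table.sort_values(col, kind="stable").head(5).index
            label = col.removeprefix("rank_")
            lines.append(f"- {label}: " + " > ".join(top))
        text = "\n".join(lines) + "\n"
    else:
        raise UnsupportedFormatError(f"unsupported report format {fmt!r}")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
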