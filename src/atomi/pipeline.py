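"""End-to-end orchestration of the two-stage target-deconvolution run.

Stage 1 (chaperone assay) yields differential gene-level hits; the stage-2
gene universe is the union of those hits with a user-supplied extension list
(kinases known to be relevant but absent from the assay library). Stage 2
scores the siRNA screen on that universe for each available combination arm;
if both arms are present, consensus hits and a network node table are
exported. Every stage writes its artifacts under the output directory and
the run report records counts, QC exclusions and parameters.

The stages remain independently invocable through their own modules; this
orchestrator only wires their default composition.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .exceptions import AtomiError, ConfigurationError
from .lumier import (
    DEFAULT_NON_SYNERGIZERS,
    DEFAULT_SYNERGIZERS,
    DEFAULT_THRESHOLD,
    HitMode,
    read_lumier_table,
    run_lumier,
    write_lumier_outputs,
)
from .simulate import DEFAULT_SEED
from .sirna import (
    ARM_DRUG,
    ARM_GENETIC,
    consensus_hits,
    export_network_table,
    read_screen_table,
    score_screen,
)

logger = logging.getLogger(__name__)


class AtomiConfig(BaseModel):
    """Configuration of a full two-stage run (JSON-serializable)."""

    lumier_input: str
    screen_input_drug: str | None = None
    screen_input_genetic: str | None = None
    synergizers: list[str] = Field(default_factory=lambda: sorted(DEFAULT_SYNERGIZERS))
    non_synergizers: list[str] = Field(
        default_factory=lambda: sorted(DEFAULT_NON_SYNERGIZERS)
    )
    threshold: float = DEFAULT_THRESHOLD
    hit_mode: str = "all"
    extension_genes: list[str] = Field(default_factory=list)
    anchor: str = "vehicle"
    min_synergy: float = 0.0
    seed: int = DEFAULT_SEED
    out_dir: str = "atomi_out"


class RunReport(BaseModel):
    """Machine-readable summary of one pipeline run."""

    version: str = __version__
    seed: int = DEFAULT_SEED
    parameters: dict[str, Any] = Field(default_factory=dict)
    n_lumier_records: int = 0
    stage1_hit_count: int = 0
    stage1_hits: list[str] = Field(default_factory=list)
    extension_genes: list[str] = Field(default_factory=list)
    stage2_gene_count: int = 0
    stage2_universe: list[str] = Field(default_factory=list)
    screens: dict[str, dict[str, Any]] = Field(default_factory=dict)
    consensus_genes: list[str] = Field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


def run_atomi(cfg: AtomiConfig) -> RunReport:
    """Execute the full pipeline per ``cfg``; returns the run report.

    On a stage failure the partial outputs written so far are retained and
    the report (with ``failed_stage`` set) is still written before the
    exception propagates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        seed=cfg.seed,
        parameters=cfg.model_dump(),
        extension_genes=sorted(set(cfg.extension_genes)),
    )
    try:
        _run_stages(cfg, out, report)
    except AtomiError:
        report.to_json(out / "report.json")
        (out / "FAILED").write_text(f"failed at stage: {report.failed_stage}\n")
        raise
    report.to_json(out / "report.json")
    return report


def _run_stages(cfg: AtomiConfig, out: Path, report: RunReport) -> None:
    report.failed_stage = "stage1_lumier"
    logger.info("stage 1: chaperone-assay differential binding (%s)", cfg.lumier_input)
    lum_df = read_lumier_table(cfg.lumier_input)
    report.n_lumier_records = len(lum_df)
    stage1 = run_lumier(
        lum_df,
        threshold=cfg.threshold,
        synergizers=cfg.synergizers,
        non_synergizers=cfg.non_synergizers,
        hit_mode=HitMode(cfg.hit_mode),
    )
    write_lumier_outputs(stage1, out / "stage1")
    report.stage1_hits = sorted(stage1.gene_hits)
    report.stage1_hit_count = len(stage1.gene_hits)

    universe = sorted(stage1.gene_hits | set(cfg.extension_genes))
    report.stage2_universe = universe
    report.stage2_gene_count = len(universe)
    logger.info(
        "stage 2 universe: %d stage-1 hits + %d extension genes -> %d genes",
        len(stage1.gene_hits),
        len(set(cfg.extension_genes)),
        len(universe),
    )

    screen_inputs = {
        ARM_DRUG: cfg.screen_input_drug,
        ARM_GENETIC: cfg.screen_input_genetic,
    }
    scores: dict[str, pd.DataFrame] = {}
    (out / "stage2").mkdir(exist_ok=True)
    for arm, path in screen_inputs.items():
        if path is None:
            continue
        report.failed_stage = f"stage2_{arm.lower()}"
        logger.info("stage 2: scoring %s-arm screen (%s)", arm, path)
        wells = read_screen_table(path)
        table, screport = score_screen(
            wells, arm, anchor=cfg.anchor, genes=universe
        )
        table.to_csv(out / "stage2" / f"gene_scores_{arm.lower()}.csv", index=False)
        scores[arm] = table
        report.screens[arm] = {
            "n_wells": screport.n_wells,
            "n_genes_scored": len(table),
            "rejected_plates": screport.rejected_plates,
            "excluded_genes": screport.excluded_genes,
            "single_drug_effect": screport.single_drug_effect,
        }

    if len(scores) == 2:
        report.failed_stage = "consensus"
        genes, merged = consensus_hits(
            scores[ARM_DRUG], scores[ARM_GENETIC], min_synergy=cfg.min_synergy
        )
        cdir = out / "consensus"
        cdir.mkdir(exist_ok=True)
        merged.to_csv(cdir / "consensus.csv", index=False)
        export_network_table(merged, cdir / "node_table.tsv")
        report.consensus_genes = sorted(genes)
        logger.info("consensus: %d genes synergize in both arms", len(genes))
    report.failed_stage = None
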