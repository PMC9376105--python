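"""siRNA viability-screen scoring: percent inhibition, GARP and HSA synergy.

The screen knocks down each candidate kinase with three independent siRNAs in
a vehicle arm and a combination arm (either a pharmacological PP2A-activator
treatment or a genetic PME-1 co-depletion). Each plate carries non-targeting
negative controls (scrambled and commercial non-silencing siRNAs) and a
universally lethal positive control, which anchor the viability scale:

    % inhibition = 100 * (avg_neg - avg_sample) / (avg_neg - avg_pos)

so 0 means "like the negative controls" and 100 means "like the death
control". Per gene and arm, the Gene Activity Ranking Profile (GARP) score is
the mean of the two highest siRNA inhibition values, damping single-siRNA
off-target artefacts. Synergy is scored under the Highest Single Agent (HSA)
model: observed combination inhibition minus the larger single-agent effect.

By default all wells are normalized against the vehicle-arm controls
(``anchor='vehicle'``), which puts knockdown-alone, drug-alone and combination
effects on one common percent scale — the operand set the HSA model requires.
``anchor='arm'`` instead normalizes each well against its own plate and arm's
controls, expressing combination-arm scores relative to the drug-alone
baseline; it is provided for comparison but its operands are not
scale-commensurate, so HSA scores under it should be interpreted with care.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AtomiError,
    ConfigurationError,
    FormatError,
    IncompleteGeneError,
    MissingControlError,
    PlateQCError,
)

logger = logging.getLogger(__name__)

NEG_CONTROLS = ("NEG_SCRAMBLED", "NEG_ALLSTARS")
POS_CONTROL = "POS_DEATH"
CONTROL_LABELS = frozenset(NEG_CONTROLS) | {POS_CONTROL}

ARM_VEHICLE = "VEHICLE"
ARM_DRUG = "DRUG"
ARM_GENETIC = "GENETIC"
ARMS = (ARM_VEHICLE, ARM_DRUG, ARM_GENETIC)

SCREEN_COLUMNS = ["plate_id", "well_id", "target", "sirna_id", "arm", "viability"]

Anchor = Literal["vehicle", "arm"]


@dataclass(frozen=True)
class PlateControls:
    """Summary of one plate/arm's control wells.

    ``average_neg`` pools both negative-control siRNA types; the invariant
    ``average_neg > average_pos`` (the death control must kill) is the plate's
    QC gate.
    """

    average_neg: float
    average_pos: float
    n_neg: int
    n_pos: int

    def __post_init__(self) -> None:
        if not self.average_neg > self.average_pos:
            raise PlateQCError(
                f"negative-control mean ({self.average_neg:.3g}) must exceed "
                f"positive-control mean ({self.average_pos:.3g})"
            )


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format siRNA screen table (CSV/TSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return validate_screen_table(pd.read_csv(path, sep=sep))


def validate_screen_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema and well-level invariants of a screen table."""
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"screen table missing columns: {missing}")
    df = df.copy()
    df["viability"] = pd.to_numeric(df["viability"], errors="raise")
    if (df["viability"] < 0).any():
        row = df.loc[(df["viability"] < 0).idxmax()]
        raise FormatError(
            f"negative viability at plate {row['plate_id']} well {row['well_id']}"
        )
    bad_arm = ~df["arm"].isin(ARMS)
    if bad_arm.any():
        raise FormatError(
            f"unknown treatment arm(s): {sorted(df.loc[bad_arm, 'arm'].unique())}"
        )
    df["sirna_id"] = pd.to_numeric(df["sirna_id"], errors="raise").astype(int)
    is_ctrl = df["target"].isin(CONTROL_LABELS)
    if (df.loc[is_ctrl, "sirna_id"] != 0).any():
        raise FormatError("control wells must have sirna_id = 0")
    gene_bad = ~df.loc[~is_ctrl, "sirna_id"].isin([1, 2, 3])
    if gene_bad.any():
        row = df.loc[~is_ctrl].loc[gene_bad.idxmax()]
        raise FormatError(
            f"gene well with sirna_id outside 1-3: target {row['target']} "
            f"plate {row['plate_id']} well {row['well_id']}"
        )
    return df


def plate_controls(wells: pd.DataFrame, *, plate_id: str | None = None) -> PlateControls:
    """Control summaries for one plate (one treatment arm's wells).

    Raises :class:`MissingControlError` if either control class is absent and
    :class:`PlateQCError` if the controls are inverted.
    """
    if plate_id is not None:
        wells = wells[wells["plate_id"] == plate_id]
    label = plate_id if plate_id is not None else "/".join(
        map(str, wells["plate_id"].unique())
    )
    neg = wells.loc[wells["target"].isin(NEG_CONTROLS), "viability"]
    pos = wells.loc[wells["target"] == POS_CONTROL, "viability"]
    if neg.empty:
        raise MissingControlError(f"plate {label}: no negative-control wells")
    if pos.empty:
        raise MissingControlError(f"plate {label}: no positive-control wells")
    try:
        return PlateControls(
            average_neg=float(neg.mean()),
            average_pos=float(pos.mean()),
            n_neg=int(neg.size),
            n_pos=int(pos.size),
        )
    except PlateQCError as e:
        raise PlateQCError(f"plate {label}: {e}") from None


def percent_inhibition(average_sample: float, controls: PlateControls) -> float:
    """Control-anchored percent inhibition of a sample viability mean.

    Exactly ``100 * (avg_neg - sample) / (avg_neg - avg_pos)``: 0 at the
    negative controls, 100 at the death control. Values outside [0, 100] are
    real signal (growth stimulation, or stronger-than-death toxicity) and are
    never clipped.
    """
    return float(
        100.0
        * (controls.average_neg - average_sample)
        / (controls.average_neg - controls.average_pos)
    )


def garp(inhibitions: Sequence[float]) -> float:
    """Gene Activity Ranking Profile score: mean of the two highest of three values.

    Requires exactly three finite per-siRNA inhibition values; permutation
    invariant, and negative inhibition participates like any other value.
    """
    vals = np.asarray(list(inhibitions), dtype=float)
    if vals.size != 3:
        raise IncompleteGeneError(
            f"GARP needs exactly three siRNA inhibition values, got {vals.size}"
        )
    if not np.isfinite(vals).all():
        raise IncompleteGeneError(f"non-finite inhibition value in {vals.tolist()}")
    return float(np.mean(np.sort(vals)[-2:]))


def hsa_synergy(combo: float, single_a: float, single_b: float) -> float:
    """Highest Single Agent excess: combination minus the larger single effect.

    Positive = synergy, zero at the HSA null (combination equals the best
    single agent), negative = antagonism. Symmetric in the single agents.
    """
    return float(combo - max(single_a, single_b))


# ---------------------------------------------------------------------------
# screen-level scoring


@dataclass
class ScreenReport:
    """QC bookkeeping for one score_screen run."""

    arm: str
    anchor: str
    n_wells: int = 0
    rejected_plates: list[str] = field(default_factory=list)
    excluded_genes: list[str] = field(default_factory=list)
    single_drug_effect: float = float("nan")


def _anchor_controls(
    df: pd.DataFrame,
) -> tuple[PlateControls, dict[tuple[str, str], PlateControls], list[str]]:
    """Vehicle-pooled controls, per-(plate, arm) controls, and rejected plates."""
    rejected: list[str] = []
    per_group: dict[tuple[str, str], PlateControls] = {}
    for (plate, arm), grp in df.groupby(["plate_id", "arm"], sort=False):
        if not grp["target"].isin(CONTROL_LABELS).any():
            continue
        try:
            per_group[(plate, arm)] = plate_controls(grp, plate_id=plate)
        except PlateQCError as e:
            logger.warning("rejecting plate %s (%s arm): %s", plate, arm, e)
            rejected.append(str(plate))
        except MissingControlError as e:
            logger.warning("plate %s (%s arm) lacks controls: %s", plate, arm, e)
    vehicle = df[df["arm"] == ARM_VEHICLE]
    try:
        pooled_vehicle = plate_controls(vehicle[~vehicle["plate_id"].isin(rejected)])
    except (MissingControlError, AtomiError) as e:
        raise MissingControlError(f"no usable vehicle-arm controls: {e}") from None
    return pooled_vehicle, per_group, rejected


def score_screen(
    wells: pd.DataFrame,
    arm: str,
    *,
    anchor: Anchor = "vehicle",
    genes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, ScreenReport]:
    """Score a full screen table against one combination arm.

    Per gene: percent inhibition per siRNA in the vehicle arm and in ``arm``,
    GARP per arm, and HSA synergy with operands

    * combination effect  = GARP under ``arm``
    * single gene effect  = GARP under vehicle
    * single drug effect  = percent inhibition of the negative-control siRNA
      wells under ``arm``, always measured against the vehicle anchor (it is
      identically zero against its own arm's controls).

    Returns the gene table sorted by descending synergy (rank 1 = most
    synergistic) plus a QC report. Genes lacking a full siRNA triplet in
    either arm, or whose wells sit only on QC-rejected plates, are excluded
    and listed in the report.
    """
    if arm not in (ARM_DRUG, ARM_GENETIC):
        raise ConfigurationError(f"arm must be DRUG or GENETIC, got {arm!r}")
    if anchor not in ("vehicle", "arm"):
        raise ConfigurationError(f"anchor must be 'vehicle' or 'arm', got {anchor!r}")
    df = validate_screen_table(wells)
    report = ScreenReport(arm=arm, anchor=anchor, n_wells=len(df))

    pooled_vehicle, per_group, rejected = _anchor_controls(df)
    report.rejected_plates = rejected
    df = df[~df["plate_id"].isin(rejected)]

    def controls_for(plate: str, well_arm: str) -> PlateControls:
        if anchor == "arm":
            ctrl = per_group.get((plate, well_arm))
            if ctrl is None:
                raise MissingControlError(
                    f"plate {plate} ({well_arm} arm) has no usable controls "
                    "for arm-anchored normalization"
                )
            return ctrl
        # vehicle anchor: prefer the same plate's vehicle controls, else pooled
        return per_group.get((plate, ARM_VEHICLE), pooled_vehicle)

    # single-agent effect of the combination treatment: negative-control siRNA
    # wells under the arm, on the vehicle-anchored percent scale
    ctrl_arm = df[(df["arm"] == arm) & df["target"].isin(NEG_CONTROLS)]
    if ctrl_arm.empty:
        raise MissingControlError(
            f"no negative-control wells under the {arm} arm to measure the "
            "single-agent treatment effect"
        )
    vehicle_ctrl_of = {
        p: per_group.get((p, ARM_VEHICLE), pooled_vehicle)
        for p in ctrl_arm["plate_id"].unique()
    }
    single_drug = float(
        np.mean(
            [
                percent_inhibition(v, vehicle_ctrl_of[p])
                for p, v in zip(ctrl_arm["plate_id"], ctrl_arm["viability"])
            ]
        )
    )
    report.single_drug_effect = single_drug

    gene_df = df[~df["target"].isin(CONTROL_LABELS)]
    if genes is not None:
        universe = set(genes)
        absent = sorted(universe - set(gene_df["target"].unique()))
        if absent:
            logger.warning("%d requested genes absent from screen: %s", len(absent), absent)
        gene_df = gene_df[gene_df["target"].isin(universe)]

    # per-well percent inhibition, then mean per (gene, arm, siRNA)
    pct = np.array(
        [
            percent_inhibition(v, controls_for(p, a))
            for p, a, v in zip(
                gene_df["plate_id"], gene_df["arm"], gene_df["viability"]
            )
        ]
    )
    per_sirna = (
        gene_df.assign(pct=pct)
        .groupby(["target", "arm", "sirna_id"], sort=True)["pct"]
        .mean()
    )

    rows = []
    for gene in sorted(gene_df["target"].unique()):
        try:
            trip = {
                a: per_sirna.loc[gene, a] for a in (ARM_VEHICLE, arm)
            }
            garps = {a: garp(trip[a].to_numpy()) for a in trip}
        except (KeyError, IncompleteGeneError):
            logger.warning("gene %s lacks a complete siRNA triplet in both arms", gene)
            report.excluded_genes.append(gene)
            continue
        synergy = hsa_synergy(garps[arm], garps[ARM_VEHICLE], single_drug)
        rows.append(
            {
                "gene": gene,
                "garp_vehicle": garps[ARM_VEHICLE],
                "garp_arm": garps[arm],
                "single_drug_effect": single_drug,
                "synergy": synergy,
            }
        )
    if not rows:
        raise IncompleteGeneError("no gene passed QC; nothing to score")
    table = pd.DataFrame(rows).sort_values(
        ["synergy", "gene"], ascending=[False, True], ignore_index=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table, report


# ---------------------------------------------------------------------------
# dose-response matrix HSA


@dataclass(frozen=True)
class DoseMatrix:
    """A two-drug dose–response matrix of percent inhibition.

    Row/column 0 correspond to zero dose of each drug, so ``response[i][0]``
    and ``response[0][j]`` are the single-agent responses and
    ``response[0][0]`` is untreated (0 within tolerance).
    """

    drug_a_doses: tuple[float, ...]
    drug_b_doses: tuple[float, ...]
    response: np.ndarray

    def __post_init__(self) -> None:
        resp = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "response", resp)
        a, b = np.asarray(self.drug_a_doses), np.asarray(self.drug_b_doses)
        if resp.shape != (a.size, b.size):
            raise FormatError(
                f"response shape {resp.shape} does not match dose lists "
                f"({a.size} x {b.size})"
            )
        for name, doses in (("drug_a", a), ("drug_b", b)):
            if doses.size < 2 or doses[0] != 0 or np.any(np.diff(doses) <= 0):
                raise FormatError(
                    f"{name} doses must be strictly increasing and start at 0, "
                    f"got {doses.tolist()}"
                )
        if abs(resp[0, 0]) > 1e-6:
            raise FormatError(
                f"response at zero dose of both drugs must be 0, got {resp[0, 0]}"
            )


def matrix_hsa(m: DoseMatrix) -> tuple[pd.DataFrame, float]:
    """Per-cell HSA excess over a dose–response matrix, plus its mean.

    For every inner cell (both doses non-zero) the excess is the observed
    response minus the larger of the two single-agent responses at the same
    doses; the scalar summary is the mean excess over all inner cells.
    """
    resp = m.response
    single_a = resp[1:, [0]]  # column vector: drug A alone at each dose
    single_b = resp[[0], 1:]  # row vector: drug B alone at each dose
    excess = resp[1:, 1:] - np.maximum(single_a, single_b)
    table = pd.DataFrame(
        excess, index=list(m.drug_a_doses[1:]), columns=list(m.drug_b_doses[1:])
    )
    table.index.name = "dose_a"
    table.columns.name = "dose_b"
    return table, float(excess.mean())


def read_dose_matrix(path: str | Path) -> DoseMatrix:
    """Read a dose–response matrix CSV: first column = drug A doses, header = drug B doses."""
    df = pd.read_csv(path, index_col=0)
    try:
        a = tuple(float(x) for x in df.index)
        b = tuple(float(x) for x in df.columns)
    except ValueError as e:
        raise FormatError(f"dose labels must be numeric: {e}") from None
    return DoseMatrix(a, b, df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# consensus across the pharmacological and genetic arms


def consensus_hits(
    scores_drug: pd.DataFrame,
    scores_genetic: pd.DataFrame,
    min_synergy: float = 0.0,
) -> tuple[set[str], pd.DataFrame]:
    """Genes synergizing in both the drug and the genetic PP2A-reactivation arms.

    Inner-joins the two gene tables; genes present in only one table are
    logged. Returns the consensus gene set (synergy strictly above
    ``min_synergy`` in both arms) and the merged table with both scores.
    """
    merged = scores_drug[["gene", "synergy"]].merge(
        scores_genetic[["gene", "synergy"]],
        on="gene",
        suffixes=("_drug", "_genetic"),
    )
    if merged.empty:
        raise ConfigurationError("the two screens share no genes; cannot form consensus")
    only_drug = set(scores_drug["gene"]) - set(merged["gene"])
    only_gen = set(scores_genetic["gene"]) - set(merged["gene"])
    if only_drug or only_gen:
        logger.warning(
            "genes outside the shared universe — drug-only: %s; genetic-only: %s",
            sorted(only_drug),
            sorted(only_gen),
        )
    merged["consensus"] = (merged["synergy_drug"] > min_synergy) & (
        merged["synergy_genetic"] > min_synergy
    )
    merged = merged.sort_values(
        ["consensus", "synergy_drug"], ascending=[False, False], ignore_index=True
    )
    return set(merged.loc[merged["consensus"], "gene"]), merged


def export_network_table(
    merged: pd.DataFrame, path: str | Path | None = None
) -> pd.DataFrame:
    """Node attribute table (gene, both synergy scores, consensus flag) for network tools.

    The TSV imports directly into Cytoscape-style software as node attributes
    for an interaction-network view of the hit kinases.
    """
    if merged.empty:
        raise ConfigurationError("cannot export an empty node table")
    cols = ["gene", "synergy_drug", "synergy_genetic", "consensus"]
    missing = [c for c in cols if c not in merged.columns]
    if missing:
        raise FormatError(f"merged consensus table missing columns: {missing}")
    table = merged[cols].copy()
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
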