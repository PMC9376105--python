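"""Differential kinase-binding calls from chaperone-interaction (LUMIER/BACON) data.

The assay quantifies the interaction between a FLAG-tagged bait kinase and the
Renilla-luciferase-tagged co-chaperone Cdc37. Inhibitor binding thermodynamically
stabilizes the kinase and *weakens* the kinase–Cdc37 interaction, so a drop in
normalized interaction signal relative to vehicle (DMSO) indicates that the
compound engages the kinase.

The analysis path is:

1. :func:`bacon_normalize` — divide the interaction (prey) luminescence by the
   bait-abundance (FLAG ELISA) luminescence, controlling for bait expression.
2. :func:`binding_profile` — per bait x compound, log2 fold change of the mean
   normalized score versus the bait's DMSO mean.
3. :func:`call_interactions` — threshold the log2 fold changes (default −1.0,
   i.e. a 50% reduction in chaperone binding).
4. :func:`differential_hits` — baits that interact with the synergizing
   compounds but with none of the non-synergizing ones.
5. :func:`collapse_to_gene` — collapse mutant baits (``GENE_MUTANT``) onto
   their gene symbol.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    FormatError,
    MissingReferenceError,
)

logger = logging.getLogger(__name__)

#: Reserved compound label for the vehicle arm.
VEHICLE_LABEL = "DMSO"

#: Default log2 fold-change threshold: −1 is exactly a 50% reduction in binding.
DEFAULT_THRESHOLD = -1.0

#: Compound roles used in the staurosporine-derivative screen this package
#: models: three derivatives that synergize with PP2A reactivation and two
#: that do not. Fully overridable in every entry point.
DEFAULT_SYNERGIZERS = frozenset({"CEP-701", "K252a", "UCN-01"})
DEFAULT_NON_SYNERGIZERS = frozenset({"rebeccamycin", "K252c"})

LUMIER_COLUMNS = [
    "bait_id",
    "compound",
    "interaction_signal",
    "abundance_signal",
    "plate_id",
    "well_id",
    "replicate",
]


class HitMode(str, Enum):
    """How stage-1 hits are combined over the synergizer compounds.

    ``ALL_SYNERGIZERS`` (default) requires an interaction call for *every*
    synergizing compound; ``ANY_SYNERGIZER`` requires at least one. Both
    modes require no interaction with any non-synergizing compound.
    """

    ALL_SYNERGIZERS = "all"
    ANY_SYNERGIZER = "any"


@dataclass(frozen=True)
class BindingProfile:
    """Per-bait, per-compound log2 fold changes of chaperone binding.

    Attributes
    ----------
    log2fc : DataFrame
        Baits (rows) x compounds (columns); NaN marks bait x compound pairs
        that were not measured.
    n_replicates : DataFrame
        Replicate count underlying each ``log2fc`` entry (0 where unmeasured).
    threshold : float
        Interaction-call threshold on the log2 scale, strictly negative.
    """

    log2fc: pd.DataFrame
    n_replicates: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if not self.threshold < 0:
            raise ConfigurationError(
                f"interaction threshold must be negative, got {self.threshold}"
            )


@dataclass(frozen=True)
class InteractionCallSet:
    """Boolean interaction calls plus the compound-role configuration."""

    calls: pd.DataFrame  # baits x compounds; pandas 'boolean' dtype, pd.NA = no call
    synergizers: frozenset[str]
    non_synergizers: frozenset[str]
    hit_mode: HitMode = HitMode.ALL_SYNERGIZERS

    def __post_init__(self) -> None:
        overlap = self.synergizers & self.non_synergizers
        if overlap:
            raise ConfigurationError(
                f"compounds cannot be both synergizer and non-synergizer: {sorted(overlap)}"
            )
        known = self.synergizers | self.non_synergizers | {VEHICLE_LABEL}
        unknown = set(self.calls.columns) - known
        if unknown:
            raise ConfigurationError(
                f"compounds in call table without a role: {sorted(unknown)}"
            )


def read_lumier_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format chaperone-assay table (CSV/TSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    return validate_lumier_table(df)


def validate_lumier_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema, positivity and uniqueness invariants of a measurement table."""
    missing = [c for c in LUMIER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"chaperone-assay table missing columns: {missing}")
    df = df.copy()
    for col in ("interaction_signal", "abundance_signal"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            row = df.loc[bad[0]]
            raise DegenerateInputError(
                f"non-positive {col} at plate {row['plate_id']} well {row['well_id']} "
                f"(bait {row['bait_id']}, compound {row['compound']})"
            )
    key = ["bait_id", "compound", "replicate", "plate_id", "well_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise FormatError(
            f"duplicate measurement record for bait {row['bait_id']}, compound "
            f"{row['compound']}, replicate {row['replicate']} at plate "
            f"{row['plate_id']} well {row['well_id']}"
        )
    return df


def bacon_normalize(
    interaction_signal: float, abundance_signal: float, *, well: str | None = None
) -> float:
    """Normalize the prey interaction signal by the bait-abundance signal.

    The bait-control (BACON) reading measures how much bait protein was
    captured; dividing by it makes the interaction score independent of bait
    expression level. The ratio is invariant under any common positive
    rescaling of both luminescence channels.
    """
    if not abundance_signal > 0:
        where = f" at well {well}" if well else ""
        raise DegenerateInputError(
            f"bait abundance signal must be positive{where}, got {abundance_signal}"
        )
    return interaction_signal / abundance_signal


def compute_log2fc(
    measurements: pd.DataFrame, compound: str, *, bait_id: str | None = None
) -> float:
    """Log2 fold change of chaperone binding, compound versus vehicle, for one bait.

    Replicates are aggregated by taking the arithmetic mean of the
    BACON-normalized scores in each arm *before* forming the ratio, which is
    robust to unbalanced replicate counts.
    """
    if bait_id is not None:
        measurements = measurements[measurements["bait_id"] == bait_id]
    baits = measurements["bait_id"].unique()
    if len(baits) != 1:
        raise FormatError(f"expected measurements for exactly one bait, got {list(baits)}")
    scores = measurements["interaction_signal"] / measurements["abundance_signal"]
    dmso = scores[measurements["compound"] == VEHICLE_LABEL]
    treated = scores[measurements["compound"] == compound]
    if dmso.empty:
        raise MissingReferenceError(f"bait {baits[0]} has no DMSO reference measurements")
    if treated.empty:
        raise MissingReferenceError(f"bait {baits[0]} has no measurements for {compound}")
    return float(np.log2(treated.mean() / dmso.mean()))


def binding_profile(
    df: pd.DataFrame, *, threshold: float = DEFAULT_THRESHOLD
) -> BindingProfile:
    """Compute the bait x compound log2 fold-change matrix from a measurement table.

    Baits without any DMSO reference are dropped with a warning (they cannot
    be normalized); compound columns exclude the vehicle label.
    """
    df = validate_lumier_table(df)
    df = df.assign(norm=df["interaction_signal"] / df["abundance_signal"])
    mean_scores = df.groupby(["bait_id", "compound"], sort=True)["norm"].agg(
        ["mean", "size"]
    )
    means = mean_scores["mean"].unstack("compound")
    counts = mean_scores["size"].unstack("compound").fillna(0).astype(int)

    if VEHICLE_LABEL not in means.columns:
        raise MissingReferenceError("no DMSO (vehicle) measurements in the dataset")
    has_ref = means[VEHICLE_LABEL].notna()
    if (~has_ref).any():
        dropped = sorted(means.index[~has_ref])
        logger.warning(
            "%d baits lack a DMSO reference and were dropped: %s", len(dropped), dropped
        )
    means = means[has_ref]
    counts = counts.loc[means.index]

    compounds = [c for c in means.columns if c != VEHICLE_LABEL]
    log2fc = np.log2(means[compounds].div(means[VEHICLE_LABEL], axis=0))
    return BindingProfile(
        log2fc=log2fc, n_replicates=counts[compounds], threshold=threshold
    )


def call_interaction(log2fc: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True iff the compound is called as binding the kinase.

    Binding is detected as *reduced* chaperone interaction; the boundary is
    inclusive, so a log2 fold change of exactly −1 (a 50% reduction) is a hit.
    """
    if not threshold < 0:
        raise ConfigurationError(f"threshold must be negative, got {threshold}")
    return bool(log2fc <= threshold)


def call_interactions(
    profile: BindingProfile,
    *,
    synergizers: Iterable[str] = DEFAULT_SYNERGIZERS,
    non_synergizers: Iterable[str] = DEFAULT_NON_SYNERGIZERS,
    hit_mode: HitMode | str = HitMode.ALL_SYNERGIZERS,
) -> InteractionCallSet:
    """Threshold a binding profile into boolean interaction calls.

    Unmeasured bait x compound pairs stay ``NA`` (no call); they are never
    imputed and disqualify the bait from differential-hit eligibility.
    """
    calls = (profile.log2fc <= profile.threshold).astype("boolean")
    calls = calls.mask(profile.log2fc.isna())
    return InteractionCallSet(
        calls=calls,
        synergizers=frozenset(synergizers),
        non_synergizers=frozenset(non_synergizers),
        hit_mode=HitMode(hit_mode),
    )


def differential_hits(callset: InteractionCallSet) -> set[str]:
    """Baits that interact with the synergizing compounds but no non-synergizer.

    Under ``ALL_SYNERGIZERS`` a bait must be called for every synergizer;
    under ``ANY_SYNERGIZER`` for at least one. In both modes a call for any
    non-synergizer, or a missing call for any role compound, disqualifies the
    bait (missing data is logged, never imputed).
    """
    if not callset.synergizers or not callset.non_synergizers:
        raise ConfigurationError(
            "both synergizer and non-synergizer compound sets must be non-empty"
        )
    syn = sorted(callset.synergizers)
    non = sorted(callset.non_synergizers)
    missing_cols = [c for c in syn + non if c not in callset.calls.columns]
    if missing_cols:
        raise ConfigurationError(
            f"role compounds absent from the call table: {missing_cols}"
        )
    calls = callset.calls[syn + non]
    incomplete = calls.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "%d baits have missing calls for role compounds and are ineligible: %s",
            int(incomplete.sum()),
            sorted(calls.index[incomplete]),
        )
    eligible = calls[~incomplete].astype(bool)
    if callset.hit_mode is HitMode.ALL_SYNERGIZERS:
        syn_ok = eligible[syn].all(axis=1)
    else:
        syn_ok = eligible[syn].any(axis=1)
    non_ok = ~eligible[non].any(axis=1)
    return set(eligible.index[syn_ok & non_ok])


def collapse_to_gene(bait_ids: Iterable[str]) -> set[str]:
    """Collapse bait identifiers onto gene symbols.

    Baits are named ``GENE`` or ``GENE_MUTANT`` (e.g. ``ABL1_T315I``); the
    mutant suffix is stripped and a gene is a hit if any of its variants is.
    Blank identifiers cannot be parsed and pass through unchanged with a
    warning.
    """
    genes: set[str] = set()
    for bait in bait_ids:
        gene = str(bait).split("_", 1)[0]
        if not gene:
            logger.warning("unparseable bait identifier %r passed through unchanged", bait)
            genes.add(str(bait))
        else:
            genes.add(gene)
    return genes


@dataclass
class LumierResult:
    """Full stage-1 result: profile, calls, bait-level and gene-level hits."""

    profile: BindingProfile
    callset: InteractionCallSet
    bait_hits: set[str] = field(default_factory=set)
    gene_hits: set[str] = field(default_factory=set)


def run_lumier(
    df: pd.DataFrame,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    synergizers: Iterable[str] = DEFAULT_SYNERGIZERS,
    non_synergizers: Iterable[str] = DEFAULT_NON_SYNERGIZERS,
    hit_mode: HitMode | str = HitMode.ALL_SYNERGIZERS,
) -> LumierResult:
    """End-to-end stage 1: measurements -> differential gene-level hit set."""
    profile = binding_profile(df, threshold=threshold)
    callset = call_interactions(
        profile,
        synergizers=synergizers,
        non_synergizers=non_synergizers,
        hit_mode=hit_mode,
    )
    bait_hits = differential_hits(callset)
    gene_hits = collapse_to_gene(bait_hits)
    logger.info(
        "stage 1: %d baits, %d bait-level hits, %d gene-level hits",
        len(profile.log2fc),
        len(bait_hits),
        len(gene_hits),
    )
    return LumierResult(profile, callset, bait_hits, gene_hits)


def write_lumier_outputs(result: LumierResult, out_dir: str | Path) -> None:
    """Write the log2fc matrix, call matrix, hit list and run parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.profile.log2fc.to_csv(out / "log2fc.csv", index_label="bait_id")
    result.callset.calls.to_csv(out / "calls.csv", index_label="bait_id")
    (out / "hits.txt").write_text(
        "".join(f"{g}\n" for g in sorted(result.gene_hits))
    )
    params = {
        "threshold": result.profile.threshold,
        "synergizers": sorted(result.callset.synergizers),
        "non_synergizers": sorted(result.callset.non_synergizers),
        "hit_mode": result.callset.hit_mode.value,
        "n_baits": int(len(result.profile.log2fc)),
        "n_bait_hits": len(result.bait_hits),
        "n_gene_hits": len(result.gene_hits),
    }
    (out / "params.json").write_text(json.dumps(params, indent=2) + "\n")
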