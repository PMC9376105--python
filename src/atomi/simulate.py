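"""Synthetic chaperone-assay and siRNA-screen data with known ground truth.

Both generators emulate the plate structure the analysis modules consume and
plant effects exactly on the scales the scoring recovers, so that at zero
noise the full pipeline is an exact fixed point (recovered log2 fold change
== planted effect; recovered HSA synergy == planted synergy). Noise models
are the standard ones for plate luminescence: multiplicative lognormal noise
for the interaction/abundance channels and a truncated-normal coefficient of
variation for viability readouts.

The screen generator plants inhibition on the control-anchored percent scale
(well mean = avg_neg − i/100·(avg_neg − avg_pos)), so the printed
percent-inhibition formula returns exactly the planted value; combination
wells compose effects HSA-additively (max of the single effects plus the
planted synergy). This is a simulator convention chosen for exact
recoverability, not a biological claim.
"""
from __future__ import annotations

import itertools
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .exceptions import ConfigurationError
from .lumier import DEFAULT_NON_SYNERGIZERS, DEFAULT_SYNERGIZERS, VEHICLE_LABEL
from .sirna import ARM_DRUG, ARM_GENETIC, ARM_VEHICLE, NEG_CONTROLS, POS_CONTROL

#: Default seed for all stochastic paths.
DEFAULT_SEED = 20220813


class GroundTruth(BaseModel):
    """Simulator record of planted effects, for recovery testing."""

    binder_map: dict[str, list[str]] = Field(default_factory=dict)
    effect_log2fc: float | None = None
    true_synergizers: list[str] = Field(default_factory=list)
    synergy_effect: float | None = None
    knockdown_effect: dict[str, float] = Field(default_factory=dict)
    arm_effects: dict[str, float] = Field(default_factory=dict)

    def differential_binders(
        self, synergizers: Sequence[str], non_synergizers: Sequence[str]
    ) -> set[str]:
        """Baits planted to bind every synergizer and no non-synergizer."""
        binds = {c: set(b) for c, b in self.binder_map.items()}
        hits = set.intersection(*(binds.get(c, set()) for c in synergizers))
        for c in non_synergizers:
            hits -= binds.get(c, set())
        return hits

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


# ---------------------------------------------------------------------------
# stage 1: chaperone interaction assay


class LumierSimConfig(BaseModel):
    """Configuration of the chaperone-assay simulator.

    ``binder_map`` lists, per compound, the baits it truly binds; binders get
    a planted log2 fold change of ``effect_log2fc`` (default −2, i.e. a 75%
    reduction in chaperone binding), non-binders 0. ``noise_sd_log`` is the
    standard deviation of lognormal multiplicative noise on the interaction
    channel (natural-log scale); ``abundance_cv`` the coefficient of
    variation of bait abundance between wells.
    """

    kinases: list[str]
    synergizers: list[str] = Field(default_factory=lambda: sorted(DEFAULT_SYNERGIZERS))
    non_synergizers: list[str] = Field(
        default_factory=lambda: sorted(DEFAULT_NON_SYNERGIZERS)
    )
    binder_map: dict[str, list[str]] = Field(default_factory=dict)
    effect_log2fc: float = -2.0
    noise_sd_log: float = 0.15
    abundance_cv: float = 0.2
    abundance_mean: float = 1000.0
    baseline_score: float = 2.0
    n_replicates: int = 2
    seed: int = DEFAULT_SEED

    @field_validator("effect_log2fc")
    @classmethod
    def _neg_effect(cls, v: float) -> float:
        if not v < 0:
            raise ValueError(f"effect_log2fc must be negative, got {v}")
        return v

    @field_validator("noise_sd_log", "abundance_cv")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"noise parameters must be >= 0, got {v}")
        return v

    @field_validator("n_replicates")
    @classmethod
    def _reps(cls, v: int) -> int:
        if v < 1:
            raise ValueError(f"n_replicates must be >= 1, got {v}")
        return v

    @model_validator(mode="after")
    def _check_binders(self) -> "LumierSimConfig":
        kin = set(self.kinases)
        compounds = set(self.synergizers) | set(self.non_synergizers)
        for comp, baits in self.binder_map.items():
            if comp not in compounds:
                raise ValueError(f"binder_map compound {comp!r} has no role")
            unknown = set(baits) - kin
            if unknown:
                raise ValueError(
                    f"binder_map for {comp} names unknown baits: {sorted(unknown)}"
                )
        if set(self.synergizers) & set(self.non_synergizers):
            raise ValueError("a compound cannot be both synergizer and non-synergizer")
        return self


def make_differential_scenario(
    n_kinases: int,
    n_differential: int,
    *,
    n_pan: int = 0,
    n_mutants: int = 0,
    seed: int = DEFAULT_SEED,
    **overrides,
) -> LumierSimConfig:
    """Build a screen scenario with planted differential binders.

    ``n_differential`` genes bind every synergizer and no non-synergizer
    (the planted stage-1 hits); ``n_pan`` genes bind all five compounds
    (excluded by the differential logic); the rest bind nothing.
    ``n_mutants`` extra mutant baits (``GENE_M1``) are added for the first
    genes to exercise gene-level collapse.
    """
    if n_differential + n_pan > n_kinases:
        raise ConfigurationError("more planted binders than kinases")
    genes = [f"KIN{i:03d}" for i in range(1, n_kinases + 1)]
    mutants = [f"{g}_M1" for g in genes[:n_mutants]]
    cfg = LumierSimConfig(kinases=genes + mutants, seed=seed, **overrides)
    diff = set(genes[:n_differential]) | {
        m for m in mutants if m.split("_", 1)[0] in set(genes[:n_differential])
    }
    pan = set(genes[n_differential : n_differential + n_pan])
    binder_map = {c: sorted(diff | pan) for c in cfg.synergizers}
    binder_map.update({c: sorted(pan) for c in cfg.non_synergizers})
    return cfg.model_copy(update={"binder_map": binder_map})


def simulate_lumier(cfg: LumierSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a chaperone-assay measurement table plus its ground truth.

    For each bait x compound x replicate the true normalized interaction
    score is ``baseline · 2^effect`` (effect = planted log2fc for binders, 0
    otherwise; DMSO wells are always effect-free). The observed channels are
    ``abundance ~ abundance_mean · LogNormal(cv)`` and ``interaction =
    true score · abundance · LogNormal(noise_sd_log)``.
    """
    rng = np.random.default_rng(cfg.seed)
    binds = {c: set(b) for c, b in cfg.binder_map.items()}
    compounds = [VEHICLE_LABEL] + cfg.synergizers + cfg.non_synergizers
    # lognormal parameterized to unit mean so zero noise is the identity
    ab_sigma = math.sqrt(math.log(1.0 + cfg.abundance_cv**2))

    records = []
    well_counter = itertools.count()
    for bait in cfg.kinases:
        for comp in compounds:
            effect = (
                cfg.effect_log2fc
                if comp != VEHICLE_LABEL and bait in binds.get(comp, set())
                else 0.0
            )
            true_score = cfg.baseline_score * 2.0**effect
            for rep in range(1, cfg.n_replicates + 1):
                abundance = cfg.abundance_mean * rng.lognormal(
                    -0.5 * ab_sigma**2, ab_sigma
                )
                noise = rng.lognormal(
                    -0.5 * cfg.noise_sd_log**2, cfg.noise_sd_log
                )
                i = next(well_counter)
                records.append(
                    {
                        "bait_id": bait,
                        "compound": comp,
                        "interaction_signal": true_score * abundance * noise,
                        "abundance_signal": abundance,
                        "plate_id": f"L{i // 384 + 1:02d}",
                        "well_id": f"W{i % 384 + 1:03d}",
                        "replicate": rep,
                    }
                )
    truth = GroundTruth(
        binder_map={c: sorted(b) for c, b in binds.items()},
        effect_log2fc=cfg.effect_log2fc,
    )
    return pd.DataFrame.from_records(records), truth


# ---------------------------------------------------------------------------
# stage 2: siRNA viability screen


class ScreenSimConfig(BaseModel):
    """Configuration of the siRNA-screen simulator.

    Defaults mirror the screened library's shape: 37 kinases, three
    independent siRNAs each, negative (non-targeting) and positive (death)
    control wells anchoring each plate. Effects are percentages on the
    control-anchored inhibition scale: ``knockdown_effect`` is the
    single-agent effect of depleting any one gene, ``drug_effect`` /
    ``genetic_effect`` the single-agent effect of the combination treatment,
    and ``synergy_effect`` the HSA excess planted for ``true_synergizers``.
    ``cv`` is the well-level measurement coefficient of variation.
    """

    genes: list[str] = Field(
        default_factory=lambda: [f"KIN{i:03d}" for i in range(1, 38)]
    )
    true_synergizers: list[str] = Field(
        default_factory=lambda: [f"KIN{i:03d}" for i in range(1, 11)]
    )
    synergy_effect: float = 25.0
    knockdown_effect: float | dict[str, float] = 10.0
    drug_effect: float = 15.0
    genetic_effect: float = 15.0
    neg_mean: float = 10000.0
    pos_mean: float = 500.0
    cv: float = 0.10
    wells_per_control: int = 8
    arms: list[str] = Field(default_factory=lambda: [ARM_DRUG])
    seed: int = DEFAULT_SEED

    @field_validator("cv")
    @classmethod
    def _cv(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"cv must be >= 0, got {v}")
        return v

    @field_validator("wells_per_control")
    @classmethod
    def _wpc(cls, v: int) -> int:
        if v < 1:
            raise ValueError(f"wells_per_control must be >= 1, got {v}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "ScreenSimConfig":
        if not self.neg_mean > self.pos_mean:
            raise ValueError("neg_mean must exceed pos_mean (death control must kill)")
        unknown = set(self.true_synergizers) - set(self.genes)
        if unknown:
            raise ValueError(f"true_synergizers not in gene list: {sorted(unknown)}")
        bad_arms = set(self.arms) - {ARM_DRUG, ARM_GENETIC}
        if bad_arms:
            raise ValueError(f"arms must be DRUG/GENETIC, got {sorted(bad_arms)}")
        if isinstance(self.knockdown_effect, dict):
            missing = set(self.genes) - set(self.knockdown_effect)
            if missing:
                raise ValueError(
                    f"per-gene knockdown_effect missing genes: {sorted(missing)}"
                )
        return self

    def knockdown_of(self, gene: str) -> float:
        if isinstance(self.knockdown_effect, dict):
            return self.knockdown_effect[gene]
        return self.knockdown_effect

    def arm_effect(self, arm: str) -> float:
        return self.drug_effect if arm == ARM_DRUG else self.genetic_effect


def simulate_screen(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a screen well table (vehicle arm + requested combination arms).

    Planted total inhibition per well:

    * gene wells, vehicle arm: the gene's knockdown effect;
    * gene wells, combination arm: ``max(knockdown, treatment)`` plus the
      planted synergy if the gene is a true synergizer (HSA-additive);
    * negative-control wells: 0 under vehicle, the treatment effect under an
      arm; positive-control wells sit at ``pos_mean`` in every arm.

    Well means are ``avg_neg − i/100·(avg_neg − avg_pos)``; observed values
    multiply the mean by Normal(1, cv) truncated at 0. Each arm occupies its
    own plate.
    """
    rng = np.random.default_rng(cfg.seed)
    unit = (cfg.neg_mean - cfg.pos_mean) / 100.0
    truth_syn = set(cfg.true_synergizers)

    def mean_viability(inhibition: float) -> float:
        return cfg.neg_mean - inhibition * unit

    records = []

    def add_well(plate: str, well: str, target: str, sirna: int, arm: str, mean: float):
        obs = mean * max(0.0, rng.normal(1.0, cfg.cv)) if cfg.cv > 0 else mean
        records.append(
            {
                "plate_id": plate,
                "well_id": well,
                "target": target,
                "sirna_id": sirna,
                "arm": arm,
                "viability": obs,
            }
        )

    for arm in [ARM_VEHICLE] + cfg.arms:
        plate = f"P_{arm}"
        wi = itertools.count(1)
        treatment = 0.0 if arm == ARM_VEHICLE else cfg.arm_effect(arm)
        for gene in cfg.genes:
            kd = cfg.knockdown_of(gene)
            if arm == ARM_VEHICLE:
                total = kd
            else:
                total = max(kd, treatment) + (
                    cfg.synergy_effect if gene in truth_syn else 0.0
                )
            for s in (1, 2, 3):
                add_well(plate, f"W{next(wi):03d}", gene, s, arm, mean_viability(total))
        for label in NEG_CONTROLS:
            for _ in range(cfg.wells_per_control):
                add_well(
                    plate, f"W{next(wi):03d}", label, 0, arm, mean_viability(treatment)
                )
        for _ in range(cfg.wells_per_control):
            add_well(plate, f"W{next(wi):03d}", POS_CONTROL, 0, arm, cfg.pos_mean)

    truth = GroundTruth(
        true_synergizers=sorted(truth_syn),
        synergy_effect=cfg.synergy_effect,
        knockdown_effect={g: cfg.knockdown_of(g) for g in cfg.genes},
        arm_effects={a: cfg.arm_effect(a) for a in cfg.arms},
    )
    return pd.DataFrame.from_records(records), truth


def write_simulation(
    table: pd.DataFrame, truth: GroundTruth, out_dir: str | Path, stem: str
) -> None:
    """Write a simulated table and its ground truth under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{stem}.csv", index=False)
    truth.to_json(out / f"{stem}_truth.json")
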