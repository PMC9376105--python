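import numpy as np
import pandas as pd
import pytest

from atomi.simulate import (
    LumierSimConfig,
    ScreenSimConfig,
    make_differential_scenario,
    simulate_lumier,
    simulate_screen,
)


@pytest.fixture(scope="session")
def noise_free_lumier():
    """Noise-free chaperone-assay dataset: 12 kinases (3 with a mutant bait),
    4 planted differential binders, 2 pan-binders."""
    cfg = make_differential_scenario(
        12, 4, n_pan=2, n_mutants=3, noise_sd_log=0.0, abundance_cv=0.0, seed=11
    )
    table, truth = simulate_lumier(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def noise_free_screen():
    """Noise-free siRNA screen: 12 genes, 4 planted synergizers, both arms."""
    cfg = ScreenSimConfig(
        genes=[f"KIN{i:03d}" for i in range(1, 13)],
        true_synergizers=[f"KIN{i:03d}" for i in range(1, 5)],
        cv=0.0,
        arms=["DRUG", "GENETIC"],
        seed=7,
    )
    table, truth = simulate_screen(cfg)
    return cfg, table, truth


def make_controls_wells(plate, arm, neg=10000.0, pos=500.0, n=4):
    """Well records for one plate/arm's control block."""
    rows = []
    for i in range(n):
        rows.append(dict(plate_id=plate, well_id=f"N{i}", target="NEG_SCRAMBLED",
                         sirna_id=0, arm=arm, viability=neg))
        rows.append(dict(plate_id=plate, well_id=f"A{i}", target="NEG_ALLSTARS",
                         sirna_id=0, arm=arm, viability=neg))
        rows.append(dict(plate_id=plate, well_id=f"P{i}", target="POS_DEATH",
                         sirna_id=0, arm=arm, viability=pos))
    return rows
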