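# atomi

Target deconvolution for multi-kinase inhibitors by paired pharmacological
and genetic screening. `atomi` implements the computational half of a
two-stage strategy for asking *which* of a promiscuous kinase inhibitor's
many targets actually drive a synthetic-lethality phenotype — here, the
synergy between staurosporine-derivative multi-kinase inhibitors and
reactivation of the tumor suppressor phosphatase PP2A in glioblastoma cells.

It is written for screening/bioinformatics scientists who have plate-reader
exports in hand: stage 1 turns chaperone-interaction (LUMIER/BACON)
luminescence tables into differential drug-binding calls; stage 2 scores a
candidate-kinase siRNA viability screen for synergy with a PP2A-reactivating
treatment; a consensus step integrates the pharmacological and genetic arms.
A paired simulator with planted ground truth makes every stage testable
without instrument data.

## The scoring model

**Stage 1 — differential binding.** Inhibitor binding thermodynamically
stabilizes a kinase and weakens its interaction with the co-chaperone Cdc37,
so binding is read out as a *drop* in chaperone interaction. Per well, the
prey (Renilla) signal is normalized by the bait-abundance (FLAG ELISA)
signal; per bait *k* and compound *c*,

    log2FC(k, c) = log2( mean_norm(k, c) / mean_norm(k, DMSO) )

and an interaction is called when `log2FC ≤ −1` (a ≥50% reduction in
chaperone binding; the boundary is inclusive). A kinase is a *differential
hit* when it is called for every synergizing compound and for no
non-synergizing compound (an any-synergizer mode is available); mutant baits
(`GENE_MUTANT`) collapse onto their gene symbol.

**Stage 2 — siRNA synergy scoring.** Each well is anchored to its screen's
negative (non-targeting siRNA) and positive (universally lethal siRNA)
controls:

    % inhibition = 100 · (avg_neg − avg_sample) / (avg_neg − avg_pos)

Per gene and arm, the Gene Activity Ranking Profile (GARP) score is the mean
of the two highest of the three independent siRNA inhibition values. Synergy
follows the Highest Single Agent (HSA) model,

    synergy = GARP_combination − max(GARP_knockdown-alone, drug-alone effect)

with the drug-alone effect measured on the negative-control siRNA wells
under treatment. The same HSA excess is available for two-drug dose–response
matrices (`atomi matrix`). Consensus hits are genes with positive synergy
under both the drug arm (PP2A-activator treatment) and the genetic arm
(PME-1 co-depletion).

## Worked example

```python
from atomi import ScreenSimConfig, simulate_screen, score_screen

cfg = ScreenSimConfig(seed=5)          # 37 genes, 10 planted synergizers,
wells, truth = simulate_screen(cfg)    # planted synergy 25 points, CV 10%
scores, report = score_screen(wells, "DRUG")
print(scores.head(6).round(2).to_string(index=False))
print(f"single-agent drug effect: {report.single_drug_effect:.2f}%")
```

prints

```
  gene  garp_vehicle  garp_arm  single_drug_effect  synergy  rank
KIN010         15.03     46.30               13.62    31.27     1
KIN004         13.70     44.23               13.62    30.54     2
KIN002          6.51     43.59               13.62    29.97     3
KIN007         15.54     43.74               13.62    28.20     4
KIN008         12.21     41.60               13.62    27.98     5
KIN009         15.01     41.73               13.62    26.72     6
single-agent drug effect: 13.62%
```

Reading: `KIN010` knockdown alone inhibits viability by ~15%, the drug alone
by ~13.6%, but the combination reaches ~46%, an HSA excess (synergy) of ~31
percentage points — correctly ranking this planted synergizer at the top.
Genes are sorted by descending synergy; planted null genes score near 0.

The same stages run from the shell, reading/writing CSV:

```
atomi simulate screen --seed 5 --out sim/
atomi sirna --input sim/screen.csv --arm drug --out scored/
atomi lumier --input chaperone.csv --synergizers CEP-701,K252a,UCN-01 \
      --non-synergizers rebeccamycin,K252c --threshold -1.0 --out stage1/
atomi run --config atomi.json        # full two-stage pipeline + report.json
```

Input schemas (long-format CSV/TSV) are documented in the module docstrings
of `atomi.lumier` and `atomi.sirna`; any real chaperone-assay or
viability-screen export mapped onto those columns runs through the identical
code path, including both differential hit modes.

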