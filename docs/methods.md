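# Methods

## Stage 1: chaperone-interaction binding calls

The LUMIER/BACON readout gives two luminescence channels per well: the prey
(Renilla-tagged Cdc37) interaction signal and the bait-abundance (FLAG
ELISA) signal. Normalization is the plain ratio `interaction / abundance`
— the stated purpose of the bait-control channel is to control for bait
amount, and the ratio is the minimal such control. It is scale-free: any
common positive rescaling of a plate's luminescence leaves every downstream
quantity unchanged (enforced by a property test). Alternative normalizations
can be slotted in by pre-dividing the table.

Replicates are aggregated by taking the arithmetic mean of normalized
scores within each arm *before* forming the compound/DMSO ratio. This is
robust to unbalanced replicate counts; users preferring the mean of
per-replicate ratios can aggregate upstream.

The interaction call is `log2FC ≤ threshold` with `threshold = −1.0` by
default: −1 is exactly a 50% reduction in chaperone binding, and the
boundary is inclusive so that a precisely-50% reduction is itself a hit.
The threshold must be negative (binding weakens the chaperone interaction;
a positive threshold would invert the assay's meaning).

Differential hits default to the intersection reading — called for *every*
synergizing compound, for *no* non-synergizing compound — which is the
stricter of the two defensible readings of "interacts with the synergizers
but not the non-synergizers"; `HitMode.ANY_SYNERGIZER` gives the union
reading. Missing bait × compound combinations are never imputed: a bait
with a missing call for any role compound is ineligible in both modes and
logged, since neither "binds all synergizers" nor "binds no non-synergizer"
can be verified for it. Compound roles ship with a default configuration
(synergizers CEP-701, K252a, UCN-01; non-synergizers rebeccamycin, K252c)
and are fully overridable.

Bait identifiers follow `GENE` or `GENE_MUTANT`; gene-level collapse strips
the first-underscore suffix and a gene is a hit if any variant is. Collapse
happens *after* bait-level calling, so a wild-type non-binder cannot veto a
mutant binder.

## Stage 2: siRNA screen scoring

Percent inhibition is exactly the control-anchored formula
`100·(avg_neg − avg_sample)/(avg_neg − avg_pos)`, pooling both
negative-control siRNA types into `avg_neg`. Values are deliberately not
clipped to [0, 100]: negative inhibition (growth stimulation) and
stronger-than-death values are real signal and participate in GARP
unmodified. A plate whose negative-control mean does not exceed its
positive-control mean fails QC and is rejected (logged, with its wells
excluded); a plate missing a control class is a hard error.

GARP is the mean of the two highest of the gene's three siRNA inhibition
values. With ties, any two maximal values give the same mean, so no
tie-break rule is needed. Genes without a complete siRNA triplet in both
arms are excluded and listed in the run report rather than scored from
partial data.

### HSA operands and anchoring

Synergy per gene is the Highest Single Agent excess

    synergy = GARP_arm − max(GARP_vehicle, single_treatment_effect)

where `single_treatment_effect` is the percent inhibition of the
negative-control siRNA wells under the combination arm. The HSA model
requires all three operands on one common percent scale, which dictates the
default anchoring choice: **all wells are normalized against the
vehicle-arm controls** (`anchor='vehicle'`). Vehicle anchoring folds the
treatment's main effect into the combination-arm wells, so `GARP_arm` is
the absolute combination effect and the subtraction above is exactly the
HSA excess; on simulated data it returns the planted synergy to machine
precision at zero noise.

An `anchor='arm'` switch normalizes each well against its own plate and
arm's controls instead. That expresses combination-arm scores relative to
the treatment-alone baseline (the treatment effect is subtracted, with a
denominator rescaling, from every gene well), and the single-agent
treatment effect is then necessarily measured against the vehicle anchor —
against its own arm's controls it is identically zero. The operands are no
longer scale-commensurate, so arm-anchored HSA scores are useful for
ranking within an arm but not as calibrated excesses; this mode exists
because plate-local normalization is common practice and the comparison is
informative.

The genetic arm (PME-1 co-depletion) is treated exactly like a drug: its
single-agent effect is the inhibition of PME-1-siRNA + negative-control
kinase-siRNA wells under that arm. Consensus hits require synergy strictly
above `min_synergy` (default 0, i.e. any positive HSA excess) in both arms.
Note that with single-well siRNA measurements at realistic noise, null
genes clear a zero threshold in both arms at an appreciable rate (the arms
share the vehicle GARP, correlating their errors), so the default consensus
is a sensitive, not specific, gate; raise `min_synergy` for a specific one.

Dose–response matrices are scored with the same HSA rule per inner cell
(observed minus the larger same-dose single-agent response); the scalar
summary is the mean excess over inner cells, invariant under transposing
the matrix together with its dose lists.

## Simulators

Both generators exist so that every scoring stage has a planted-truth
oracle; their defaults are the study-shaped conditions used throughout the
tests, and they are deterministic under a fixed seed (default 20220813).

**Chaperone assay.** True normalized interaction scores are
`baseline · 2^effect` with `effect = −2` for planted binders (a 75%
binding reduction, comfortably past the −1 call threshold) and 0 otherwise;
DMSO wells are always effect-free. Bait abundance is lognormal with CV 0.2
around a common mean, and the interaction channel multiplies the true score
by abundance and by unit-mean lognormal noise with log-sd 0.15 — the
standard multiplicative error family for luminescence ratios. Two
replicates per bait × compound.

**siRNA screen.** Effects are planted directly on the control-anchored
percent-inhibition scale: a well with total inhibition *i* has mean
viability `avg_neg − (i/100)·(avg_neg − avg_pos)` (negative-control mean
10000, death-control mean 500), so the printed formula recovers *i*
exactly. (Planting as a fraction of the negative-control mean alone would
be recovered rescaled by `neg/(neg−pos)` ≈ 1.05 and would break the exact
fixed-point property; the control-anchored convention is a simulator
choice, not a biological claim.) Combination wells compose HSA-additively:
`max(knockdown, treatment) + synergy` for the 10 planted synergizers,
`max(knockdown, treatment)` otherwise, with knockdown 10, treatment 15 and
synergy 25 percentage points by default over 37 genes × 3 siRNAs.
Observed viability multiplies the mean by `Normal(1, CV)` truncated at 0,
CV 0.10, one well per gene × siRNA × arm; each arm occupies its own plate
with 8 wells per control type.

Not emulated: well-position/edge effects, plate drift, siRNA off-target
phenotypes, dose–response of either assay, and inter-screen protocol
differences (exposure times). Passing recovery tests therefore demonstrate
correctness of the scoring arithmetic and hit logic under idealized plate
statistics, not robustness to spatial artefacts or off-target biology.

## Noise and the limits of strict rank recovery

At the default conditions the per-well viability noise (CV 10% of a
~8500-unit mean ≈ 850 units) corresponds to ~9 percentage points on the
inhibition scale (one point = `(avg_neg − avg_pos)/100` = 95 units). GARP
over three single wells retains ~6–7 points of noise, so per-gene synergy
estimates carry ~8–9 points of sd against a 25-point planted effect.
Individual synergizers are recovered essentially always, but the *joint*
event "all 10 synergizers strictly outrank all 27 nulls" (270 order
comparisons between extremes of two noisy samples) holds in only ~72% of
replicates — measured once over fixed 200-replicate seed grids
(143–150/200 across three grids) and frozen as the regression bound
enforced in the test suite. A companion test asserts the idealized ≥95%
separation rate at these same conditions and is expected to fail; it is
kept, rather than weakened, to document the gap between the arithmetic
ideal and what single-well screens at 10% CV can deliver. Screens needing
strict separation at this effect size require replicate wells or ~6% CV.

## Numerical and degenerate-input choices

Zero or negative bait abundance, missing DMSO references, inverted or
missing controls, incomplete siRNA triplets, and malformed dose matrices
all raise typed errors naming the offending record; nothing is imputed.
Fold changes and percent inhibitions are exact floating-point expressions
of their formulas with no epsilon smoothing; the only tolerance in the
package is the 1e-6 allowance on the untreated cell of a dose matrix.
Screen output is sorted by descending synergy with the gene symbol as a
deterministic tie-break, so identical inputs yield byte-identical outputs.
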