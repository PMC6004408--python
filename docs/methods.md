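# Methods

`moapred` predicts the functional effect — activation or inhibition — of a
small molecule at a protein target, for the four target families where
functional annotation is most reliable (GPCRs, nuclear hormone receptors, ion
channels, transporters). This note documents the models, the data-assembly
rules, the evaluation protocol, the synthetic benchmark generator, and the
numerical choices made where the design was genuinely open.

## Chemistry substrate

Structures are standardized with RDKit's `rdMolStandardize`: sanitize →
cleanup → largest organic fragment (salt/solvent stripping) → charge
neutralization → canonical SMILES. Tautomers are *not* canonicalized; two
tautomeric inputs may standardize to different parents. Drug-likeness
requires ≥ 1 carbon atom, molecular weight in [100, 1000] Da inclusive, and
no atom with atomic number in [21, 32] ∪ [36, 52] ∪ (53, ∞) — i.e., the
typical organic elements plus light counter-ions, As/Se/Br and iodine are
retained. The element rule is configurable per call.

Compounds are encoded as 2048-bit hashed circular (Morgan) fingerprints of
radius 2, the standard ECFP4-like representation. Bit positions follow
RDKit's hashing and are deterministic for a given standardized structure.
Similarity is the Tanimoto coefficient |A∩B| / |A∪B|; the degenerate 0/0
case (two empty fingerprints) is defined as 0. The mean similarity of the
k = 5 nearest training neighbors is the applicability-domain distance
measure; k = 1 gives the nearest-neighbor similarity used in chemical-space
analyses.

## Dataset assembly

Assay annotations (compound, target, endpoint type, potency in μM, optional
BioAssay Ontology mechanism term) become per-target compound sets:

- **Activity threshold.** Potency ≤ 10 μM (inclusive) is active; > 10 μM is
  non-binding. IC50/EC50 actives are functional; Ki/Kd actives are
  binding-only.
- **Functional label.** The BAO term is mapped to a binary label
  (activation/agonism/opening → activator; antagonism/blocking/closing/
  inhibition/inverse agonism → inhibitor). When a term is present it
  overrides the endpoint-unit fallback (EC50 → activator, IC50 → inhibitor);
  unknown terms are hard errors.
- **Conflict removal.** A compound with both activator and inhibitor evidence
  at the same target is dropped from that target's functional sets; a
  compound with both active and non-binding evidence at a target is dropped
  from the inactive set. Conflicts are strictly per-target.
- **Putative inactives.** When an external pool is supplied, sphere exclusion
  samples pool compounds whose maximum Tanimoto to every active is ≤ 0.4, in
  a seed-shuffled order over a by-id-sorted view (so the selection is
  invariant to pool ordering). The per-target quota defaults to 100× the
  active-set size, capped by the pool — a configurable knob, since no
  principled per-target number exists.
- **Size floors.** Targets need ≥ 10 activating and ≥ 10 inhibiting
  compounds; kept targets with 1–4 binding-only compounds have that set
  emptied (five-fold cross-validation needs at least one binder per fold).

## Architectures

All random forests use 100 trees with √n_features feature sampling and a
fixed seed; trained models are bit-reproducible given the same inputs.

**Arch1 — single multi-class forest.** One forest over every
(target, function) label, trained only on functional actives; each training
row is one compound–target–function annotation, so a promiscuous compound
contributes several rows and predicted probabilities sum to 1 across all
labels. Trees are depth-capped at 20. Because the probability mass is spread
over many labels, raw scores are small; a decision threshold θ converts them
to calls: labels with p ≥ θ are candidates, the higher of the two functions
wins (exact tie → inhibitor, the majority prior), no candidate → inactive. θ
is chosen by exhaustive search over the 1st–100th percentiles of the pooled
*out-of-fold* score distribution, maximizing the mean F1 over the three
output labels; ties prefer the larger (more conservative) θ. θ is never fit
on training-set or test-set scores.

**Stage 1 — binding gate (Arch2/Arch3).** Per-target binary forest, all
actives (activating ∪ inhibiting ∪ binding-only) vs the inactive set,
unlimited depth, `class_weight="balanced"` plus per-instance weights giving
each active the inactive:active ratio. The two weightings compound; the
instance weights can be disabled by a switch. A compound proceeds to Stage 2
only when p(bind) > 0.5 strictly; p = 0.5 is called inactive.

**Stage 2.** Arch2 trains one activator-vs-inhibitor forest; Arch3 trains
two independent forests (activator-vs-inactive, inhibitor-vs-inactive). Both
are Platt-calibrated (sigmoid) with 3 internal folds so outputs behave as
probabilities; for Arch3 the calibration is what makes the two independent
models comparable. Arch2's p_act + p_inh = 1; Arch3's probabilities are
individually in [0, 1] with unconstrained sum. Rows are internally permuted
before the calibration split so results cannot depend on caller row order.
When the gate passes, a functional label is always forced: activating iff
p_act > p_inh, otherwise inhibiting (ties → inhibitor). Calibration requires
≥ 3 members per class (hard error below; a warning below the dataset floor
of 10, which can only occur when the library is driven directly).

A standalone `platt_fit` primitive implements the sigmoid fit
σ(s) = 1/(1+exp(A·s+B)) by minimizing the smoothed-target log-loss
(t⁺ = (N⁺+1)/(N⁺+2)); the pipeline's calibrated models use scikit-learn's
`CalibratedClassifierCV`, which implements the same procedure per fold.

## Evaluation protocol

**Cross-validation.** Stratified five-fold splits per target over the four
set labels (activating / inhibiting / binding / inactive); label proportions
per fold match the global ratio within rounding, folds are exact partitions.
Binding-only compounds appear only in Stage 1 training portions — they carry
no functional truth to score. For Arch1, every fold's out-of-fold scores are
pooled to fit θ before any metric is computed; each test compound is scored
at its annotated target (plus held-out inactives at their target). Truth at
*other* targets is unknown — absence of an annotation is not evidence of
inactivity — so cross-target calls are not asserted.

**Metrics.** One-vs-rest precision, recall and F1 per (target, label), with
F1 = 2PR/(P+R) and 0 when P+R = 0. A label present in truth but never
predicted scores 0; a label absent from a target's truth is excluded from
that target's averages (the two cases are logged distinctly). Aggregations:
target-averaged (unweighted mean over targets of per-target label-averaged
metrics) and protein-class-averaged (per-class means, then unweighted mean
over the four classes); spreads are reported both across folds and across
targets. A conditional variant restricted to functional compounds that
passed the Stage 1 gate isolates Stage 2 performance. Threshold-free
ranking metrics (PR-AUC and the like) are deliberately not reported: the
three architectures' scores live on different scales and are not comparable
as distributions, only their final calls are.

**Temporal validation.** Models trained on one period are scored on a later
annotation batch; any overlap of compound ids with the training sets is a
hard error (leak guard). Only class-averaged metrics are reported, since
per-target test sets may be very small.

**Architecture comparison.** Two-sample Kolmogorov–Smirnov test on
per-target metric distributions, read at the 0.05 level.

**Applicability domain.** Each functional test compound gets the mean
Tanimoto of its k = 5 nearest training neighbors *of its true label*;
compounds are binned at width 0.05 on similarity, and the per-bin TPR is the
recall of functional labels in that bin. AD-AUC integrates TPR over distance
(1 − similarity) across populated bin centers by the trapezoid rule, with
the full [0, 1] distance span as the reference scale; empty bins are
excluded, and a curve with a single populated bin has zero area by
convention. The axis orientation and normalization are package conventions
(documented here because more than one convention is defensible); AD-AUC
values are therefore comparable within this package, not across tools.

## Synthetic benchmark generator

Real functional-bioactivity corpora are proprietary, so the test bed is a
seeded generator that reproduces the statistical structure such data
exhibits, not its chemistry. Fingerprints are generated directly as bit
vectors: each functional class has a 120-on-bit prototype; members apply
density-preserving noise (on-bits flip off with rate p, off-bits flip on
with rate p·m/(n−m), keeping expected density). Cross-set similarity is
controlled by the fraction of on-bits shared between prototypes, solved by
bisection against a closed-form ratio-of-expectations approximation of the
Tanimoto coefficient (tight at n = 2048). Infeasible knob combinations (a
requested similarity above what the noise level permits) raise immediately
with a diagnostic.

Defaults encode the structure of large pharma functional panels: expected
activator–inhibitor member similarity 0.835, binder–inhibitor 0.958, 5:1
inhibitor:activator imbalance. Knobs are *expected pairwise* similarities;
realized nearest-neighbor medians sit a few hundredths higher (a maximum
over a finite set exceeds its mean) — measured medians at 200 members per
class land within ±0.05 of the knobs.

The inactive background mixes two populations, mirroring the provenance
split of real negative data: diffuse sphere-exclusion-like inactives far
from everything (expected similarity 0.05) and near-miss experimental
non-binders at similarity 0.8 to a functional cluster (half of the
background by default). The near population matters: with only far
inactives, both Arch3 stage-2 models saturate (every functional compound
outscores all inactives under every model) and the calibration ceiling
(N⁺+1)/(N⁺+2) then mechanically favors whichever model has more training
positives — the architecture contrast the generator exists to probe
disappears. Near-miss analogs force the stage-2 forests to learn the fine
structure around the functional clusters, as real negative screening data
does.

`label_noise` emulates assay annotation error: each recorded functional
label is wrong with the given probability, so the observed sets are
deterministic mixtures of both generating clusters — under strong imbalance
the observed activator set is flooded by mislabeled inhibitors, which is
exactly the regime where real minority-class failures concentrate. The
ground-truth manifest records every compound's generating cluster, so
experiments can train on contaminated labels and score against truth.
With `near_inactive_fraction=0` and `label_noise=0` the generator reduces to
the plain two-cluster-plus-far-background structure.

Temporal batches are drawn at a controlled expected similarity (`novelty`)
to the training clusters, optionally spread over a range, with an optional
error gradient (label-flip probability increasing with distance) for
applicability-domain experiments. Novelty 1.0 duplicates training compounds
under fresh ids; id collisions with the base universe are refused.

An auxiliary SMILES mode emits drug-like molecules from a small fragment
grammar (core–linker–core with caps, MW ≈ 150–450 Da) so end-to-end runs
exercise standardization and fingerprinting; those molecules carry no
engineered cluster structure.

**What passing tests show, and what they do not.** The generator reproduces
similarity separations, imbalance, background provenance and label noise —
not real medicinal chemistry: no activity cliffs, no scaffold series, no
assay batch effects, one cluster per functional class. Recovery results on
synthetic universes demonstrate that the architectures behave as designed
under the stated statistical conditions; they are not performance claims
about any real compound collection.

## Canonical experiments (problem sizes)

Three frozen experiments (`moapred.benchmarks`) back the test suite and the
reproduction script; sizes were chosen as the smallest at which the effects
are stable on a single CPU:

- **Separable benchmark** — 5 targets × (60 activating, 120 inhibiting, 60
  binding, 200 inactive), every inter-set similarity ≤ 0.7, noise 0.01;
  five-fold CV. All three architectures should reach class-averaged
  F1 ≥ 0.9 here; they in fact score ≥ 0.99.
- **Imbalance contrast** — 10 fresh two-target universes, 30:1
  inhibitor:activator, separation 0.87 against intra-class ≈ 0.888 (nearly
  coincident clusters), 10% label noise; 25% held-out split, shared Stage 1
  gate, scored against generating-cluster truth. Reports the paired
  Arch3 − Arch2 activator F1 and recall deltas.
- **AD gradient** — 3 targets, temporal batch of 120 compounds/class/target
  spread over novelty 0.65 ± 0.3 with an error gradient; reports the AD
  curve, its AUC, and the Spearman correlation between bin similarity and
  TPR.

## Known limitations

- Single-prototype classes understate real within-class chemotype diversity;
  conclusions about absolute model accuracy do not transfer to real data.
- Arch1 evaluation asserts nothing about cross-target inactivity (unknowable
  from annotation absence), so its inactive-label metrics come only from
  held-out experimental inactives.
- The AD-AUC normalization is a package convention; compare AD-AUC values
  only within this package.
- The in-house standardizers used by data providers are unpublished; the
  RDKit pipeline here is a documented, reproducible stand-in, and identical
  inputs standardized elsewhere may differ (e.g., tautomers).
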