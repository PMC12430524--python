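# Methods

## The classification problem

A protein variant's drug response is treated as a two-class label (S =
sensitive, R = resistant) to be predicted from the variant's
*conformational ensemble*: a sample of equilibrium structures, here
summarized frame by frame as backbone torsion vectors.  The working
hypothesis is that resistance-associated mutations shift the preferred
backbone geometry of a small number of residues, so a handful of φ/ψ
angles should suffice to separate the classes — and those angles should
point at structurally meaningful sites.

## Data model

A study consists of variants, each with three independent trajectories
of 10,000 frames; only the final 1000 frames of each trajectory are
retained (3000 frames/variant), on the grounds that the early part of a
trajectory is equilibration.  A 276-residue chain (numbered from 448, in
BRAF kinase-domain numbering) yields 2·276 − 2 = 550 torsions: φ is
undefined for the first residue and ψ for the last, and neither is
imputed.  Angles are degrees on (−180, 180], features are named
`phi{resid}`/`psi{resid}`, and the canonical feature order (ascending
residue, φ before ψ) is also the deterministic tie-break order used in
tree fitting.

All averaging and differencing of angles is circular: means are the
direction of the mean resultant vector, dispersions are circular SDs
√(−2 ln R̄), and differences are wrapped to (−180, 180].

## Synthetic ensembles

The generator emulates the study design without any molecular dynamics.
Per angle a shared base mean is drawn once per study (uniform on
(−120°, 120°), kept away from the wrap so unimodal fluctuations stay on
one branch of the circle); each frame's angle is that mean plus von
Mises noise.  Class structure is *planted*: a chosen set of angles gets
±offset/2 added for R/S variants respectively (default offset 60°,
default planted set = the angles the published selection retained for
the drug).  Variants within a class are not identical: each variant
perturbs all its mean angles by Gaussian jitter drawn **once per
variant** (not per frame), which is precisely what makes
leave-one-variant-out a generalization test rather than a row-splitting
exercise.  Unknown-status (VUS) variants are planted on the side of
their published call so that predictions about them have a ground truth.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| concentration κ | 15 | von Mises κ=15 gives a per-angle circular SD of ≈15°, the dispersion scale reported for the wild-type reference ensemble |
| variant_jitter_sd | 8° | well below offset/2 = 30°, so classes remain separable, but large enough that a held-out variant is not a copy of any training variant |
| planted offset | 60° | the study-design contrast: ≈4 within-class SDs between class means |
| base_mean_range | ±120° | keeps means ± offset/2 ± jitter clear of ±180° so raw-degree tree splits are meaningful |
| retention | last 1000 of 10,000 per trajectory | the study's retention rule |

An optional equilibration transient ramps the planted signal and jitter
in as 1 − exp(−t/τ) when full trajectories are generated, emulating
relaxation away from a shared starting structure; it drives the
convergence diagnostics' "non-equilibrated head window" scenarios.

What the generator does **not** emulate: multimodal or skewed angle
distributions, frame-to-frame autocorrelation within a trajectory,
couplings between angles, and any physical energetics.  Consequently,
passing tests demonstrate that the pipeline's statistics and algorithms
behave as specified under the study's sampling design — not that the
published biological conclusions are correct, and not how the pipeline
degrades under multimodality or strong autocorrelation.

A backbone builder (standard trans-peptide bond lengths/angles, ω frozen
at 180°) realizes any φ/ψ vector as N/CA/C coordinates; recomputing
torsions from the built chain reproduces the inputs to <1e−6°, which
makes the extractor's correctness testable without external structures.

## Feature selection

CART-style binary trees with the Gini criterion.  The threshold scan is
exhaustive over midpoints of consecutive distinct sorted values;
impurity ties break to the smaller threshold, feature ties to the
canonical feature order.  Only strictly impurity-reducing splits that
honor a minimum leaf size (default 5 frames, to prevent memorizing
single frames) are accepted.  Selection trees are depth-2 by default —
each published tree contributed at most two angles, and depth-2 trees
reproduce that cardinality — and trees are fit on frame-level rows of
all labeled variants (the published selection used single global trees;
a fold-safe variant can be run by selecting within each training fold).
Each round's split features are removed from the pool before the next
round, so rounds are disjoint by construction (asserted on every run).

Splits on raw circular values can in principle be defeated by wraparound;
the generator's base-mean range avoids this regime, and the limitation
is accepted to match the original analysis, which also split raw
degrees.

## Classification and evaluation

The forest is bagging only: each of n_trees (default 100) trees is fit
on a bootstrap resample of the training rows over the full selected
feature list (no per-split feature subsampling — with ≤6 features there
is little to subsample).  Frame prediction is the majority tree vote;
variant prediction is the majority frame vote; both ties resolve to S,
because an R call triggers clinical action and should require a strict
majority.  Class imbalance (7 S vs 5 R variants for dabrafenib) is left
unweighted.

Leave-one-variant-out: one fold per labeled variant, training on all
other variants' frames; the held-out variant's frames never appear in
training (asserted structurally each fold).  Accuracy is variant-level.
Every class must have ≥2 variants, otherwise some fold would train on a
single class and the evaluation refuses to run.  A permutation null
(variant→label assignment shuffled, class sizes preserved, fixed seeds)
provides the no-signal baseline; its accuracy settles around — in
practice at or below — the majority-class base rate.

Metrics treat R as the positive class for the confusion matrix and
specificity; precision/recall/F1 are reported per class (and are then
independent of the positive-class choice).  MCC substitutes 0 and sets a
flag when a denominator factor vanishes.  Note that the published metric
table's R-class precision/recall block is transposed relative to the
confusion matrix implied by the published per-variant calls (one FN
gives R recall 0.80 and precision 1.00, not the reverse); accuracy, MCC,
specificity and both F1 values are unaffected by the transposition, and
this package reports the values implied by the confusion matrix.

## Shapley attribution

Exact interventional Shapley values of the forest's resistant-vote
fraction (a continuous output in [0, 1], more informative than the hard
label).  The value of coalition S for frame x is the mean model output
over a background set with the features in S taken from x; Shapley
weights |S|!(k−|S|−1)!/k! are applied over all 2ᵏ coalitions.  The
default background is 100 training frames sampled with a fixed seed.
Efficiency (base + Σφ = model output, to 1e−9), symmetry and null-player
behavior are asserted in the tests, and the implementation is checked
against an independently coded permutation-enumeration oracle to 1e−12.
Enumeration is refused above k = 16 features.

## Angle-difference analysis

Per dihedral: circular means of the pooled S frames and pooled R frames
(a per-variant-mean mode is available, since pooling weights variants by
frame count), wrapped signed difference, and a Welch t-test computed on
values unwrapped about the pooled circular mean — valid for concentrated
samples, which is the regime the 15° dispersion scale implies.  An angle
is flagged when |difference| exceeds the magnitude threshold AND p < α
(default 0.05, no multiple-testing correction by default: the magnitude
gate is the effective filter, as in the original analysis; Bonferroni is
a flag away).  The threshold default is the published constant 15°;
`wt_threshold` recomputes the data-driven version as the mean over
angles of the per-angle circular SD of the wild-type frames (the
published provenance — "the standard deviation over residues in
wild-type" — is ambiguous; this reading makes the constant-dispersion
case exact and reproduces ≈15° under the default generator).

## Convergence battery

* **RMSD plateau** — CA-atom RMSD to a reference frame after Kabsch
  superposition (proper rotation enforced via SVD sign correction).  The
  plateau detector scans rolling windows (default 500 frames) and
  reports the earliest index from which every subsequent window has
  |least-squares slope| < 1e−4 Å/frame and SD < 0.15 Å; degenerate
  (collinear) configurations and series shorter than the window are
  refused.
* **Ramachandran windows** — (φ, ψ) pairs of all residues pooled into a
  2-D histogram on fixed 10° bins covering (−180, 180]²; windows are
  compared by base-2 Jensen–Shannon distance (bounded in [0, 1], 0 iff
  identical).  Two independent 1000-frame windows of the default
  stationary generator sit near 0.03, so 0.05 is used as the null-scale
  reference; this calibration is a package choice, as no quantitative
  criterion was published.
* **Selection stability** — the iterative selection is re-run on frame
  windows (the study re-analyzed 200-frame windows of the retained
  tail); agreement is summarized as pairwise Jaccard overlap of the
  selected angle sets and overlap against the full-retention selection.
  Stationary data gives overlap ≥ 0.5; a drifted head window degrades
  it.

## Pipeline and reproducibility

`run_pipeline` chains simulate-or-load → featurize → select → classify
(LOVO + VUS) → evaluate → attribute → angle statistics → convergence,
writing every table (TSV/JSON) plus a manifest with the config hash,
derived stage seeds and output checksums.  All randomness derives from
the single config seed via seed sequences, so identical configs produce
byte-identical outputs.  Unknown config keys are rejected.

## Problem sizes used in the shipped checks

Unit tests run a miniature study (12 labeled variants × 120 frames × 58
angles).  The study-scale checks run the full 12 × 3000 × 550 design for
matrix layout, selection recovery and LOVO accuracy; the 20-permutation
null is run on a frame-subsampled study (40 retained frames/trajectory,
25 trees, identical settings in both arms) — the null concerns the
variant-label assignment, not the frame count, and this sizing keeps the
full battery to a few minutes on one CPU.

## Known limitations

Single-chain, protein-only, N/CA/C-complete models; no χ or ω features;
no probability calibration or hyperparameter search; exact Shapley only
(no sampling approximation); binary drug-response labels.  Real
trajectory formats (DCD/XTC) are expected to be converted to multi-model
PDB or angle TSV upstream.
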