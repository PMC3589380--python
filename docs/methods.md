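# Methods

`supradecode` implements a complete multivoxel pattern analysis (MVPA)
pipeline for testing whether a *supramodal* — sensory-modality-invariant
— representation of actions can be decoded from fMRI beta patterns, in
a design with two groups (sighted, congenitally blind), two perception
modalities (auditory for everyone, visual for the sighted only), two
stimulus classes (hand-action vs. environmental non-action stimuli),
and motor-pantomime probe trials. Because the original scanner data are
not public, the package is organised around a synthetic generator with
known ground truth; real beta maps can be substituted through the NIfTI
+ TSV dataset interface.

## The decoding model

Examples are per-stimulus beta patterns x ∈ R^p over a 3D voxel grid,
with binary labels y ∈ {−1, +1} (non-action / action). The classifier
is a soft-margin linear SVM,

    min_{w,b}  ½‖w‖² + C Σᵢ max(0, 1 − yᵢ(w·xᵢ + b)),

with an unpenalised bias. C is never tuned; it is fixed from the data
as C = 1 / mean‖xᵢ‖² (the SVMlight default), recomputed from the
surviving-feature training submatrix at every elimination step. The
implementation solves the dual through libsvm (`sklearn.svm.SVC`,
linear kernel); tests pin the semantics against an independent
constrained-optimisation oracle of the primal objective (agreement to
1e−5 on small instances). Prediction ties (decision value exactly 0)
resolve to the action class.

## Assembly: balancing, scaling, folds

Class imbalance (20 action vs. 10 non-action sounds; 23 vs. 11 videos)
is removed per condition at the stimulus level, identically for every
subject: minority stimuli are duplicated uniformly at random without
replacement per round (so 10 → 20 is an exact doubling) and majority
stimuli are down-sampled at random. This yields 560 examples per
sighted condition (280 per class, 20 per class × 14 subjects) and 320
in the blind auditory condition. Duplicates carry a `duplicate_of`
pointer and always follow their source stimulus into a fold, so no
stimulus straddles a train/test boundary.

Each condition's balanced matrix is scaled per voxel: standardise over
examples, then apply tanh, mapping everything strictly into (−1, +1)
(zero-variance voxels → 0). Standardise-then-tanh is a package
decision; the convention only fixes the units of the squashing.
Scaling is fit on the full balanced matrix before fold splitting by
default, faithfully mirroring the emulated workflow; a `per_fold`
scaling mode (statistics from the training fold only) is available for
leakage-free preprocessing. All examples — including pantomime probes —
are scaled with the statistics of their own acquisition condition
(pantomimes use the perception condition of their group and session).

Stimuli are dealt into k = 4 class-stratified folds (per-class fold
sizes differ by at most one), the fold unit being the stimulus, not the
example, because every subject contributes an example for the same
stimulus.

## RFE inside nested cross-validation

Per fold and condition, a full recursive-elimination trace is run:
train the SVM on the surviving voxels, record test accuracy, discard
the ⌈2%⌉ (at least one) of voxels with smallest |w| — ties broken by
removing the lower voxel index — then cluster-correct the survivors
(connected components below a minimum size are dropped; face adjacency
by default, the 18- and 26-neighbour variants are configurable), and
repeat until no voxel survives. The per-iteration Gram matrices are
computed once and downdated as features leave, which keeps a full
1728-voxel trace under a second.

The best iteration of a trace is the test-accuracy argmax; among tied
maxima the *smallest* surviving set is selected, because the purpose of
elimination is a minimal sufficient voxel set. (A config flag instead
selects one shared iteration index across the three conditions by their
mean accuracy.) The best fold maximises the across-condition mean of
best accuracies; reported condition summaries are mean ± SD of per-fold
best accuracies. The cluster-correction minimum is 150 voxels (1,200
µL at 2 mm isometric) at brain scale; the desk-scale default is a
grid-proportional 5 voxels on the 12³ grid.

## Supramodal classifier and knock-out analyses

On the best fold, the three conditions' training sets are pooled
(classes remain balanced; no re-balancing) and the same RFE procedure
is run once more; the selected voxels form the *knock-out mask* and the
selected model is the combined supramodal classifier, scored on the
pooled test set. Three follow-ups:

* **Exclusion** — each condition's classifier is retrained on its best
  voxel set minus the knock-out mask ("removal" is re-fitting on the
  surviving voxels, not zeroing weights; an empty survivor set scores
  the defined chance value 0.5 with a warning flag).
* **Restriction** — classifiers are retrained on knock-out voxels only
  and evaluated on every condition's test set, filling a 3 × 3
  train × test accuracy table whose off-diagonal cells measure
  cross-modality and cross-group generalization.
* **Pantomime probing** — motor-pantomime examples (always test-only)
  are fed to each classifier and the fraction labeled "action" is
  tested against 0.5.

## Inference

Accuracy significance uses a training-label permutation test: the
classifier is re-fitted with shuffled training labels at the *fixed*
selected feature set and re-scored on untouched test labels; p =
(1 + #{null ≥ observed}) / (n_perm + 1). The reference n_perm is 500;
desk-scale runs default to 99. Because selection (best fold × best
iteration) is not repeated inside the null, p-values for the selected
accuracies inherit an optimism bias — a property of the emulated
procedure itself, measurable here: on pure-noise data the selected
best accuracy rejects far above the nominal rate, while the same test
without selection is exactly calibrated (verified in the suite).

Exclusion effects are assessed with a two-sided Wilcoxon signed-rank
test on paired per-subject best-fold test accuracies (whole map vs.
excluded) per condition — exact by a subset-sum convolution over
(doubled, midrank-tied) ranks up to n = 25, normal approximation above
— and aggregated across the three conditions with Fisher's method
(−2Σln p ~ χ²(2k)). Pantomime action rates use the exact binomial
upper tail. Fewer than five nonzero per-subject differences yield a
conservative p = 1 for that condition.

## Synthetic generator

The generator emulates the study design: 14 sighted + 8 blind
subjects; 20 action + 10 non-action sounds heard by everyone; 23
action + 11 non-action videos (sighted); 10 motor pantomimes per
subject per session type (auditory sessions for all, visual for the
sighted — 280 sighted and 80 blind pantomime examples). Informative
voxels form face-connected clusters grown by randomised breadth-first
search, pairwise disjoint: a shared set S (default 40 voxels) active
for actions in every modality, and auditory / visual / motor sets
(30 voxels each) active only in their own modality. An action example
is effect·1(S ∪ modality set) + subject offset + N(0, σ²) noise per
voxel; a pantomime carries the action effect at S ∪ M; non-action
examples are offset + noise. The subject offset is a scalar N(0,
0.2²) applied to all voxels — the simplest exchangeable subject
effect; σ defaults to 0.5.

Default effect sizes are 1.0 in every set (strong, compact signal for
feature-recovery experiments). Two preset regimes change only the
effects, chosen from the aggregate-discriminability relation
d ≈ e·√k/σ so realized accuracies land in the realistic 0.75–0.9
band rather than saturating: `modality_dominant` (shared 0, modality
0.25 — decodable within condition, nothing transfers across
modalities) and `shared_signal` (shared 0.3, modality 0.15 — the
regime showing the knock-out signature: exclusion hurts, restriction
generalises across modality and group).

A small forward model of sparse-sampling acquisition is included: each
trial contributes amplitude × a gamma-variate response (shape 4, unit
scale, peak at the third of five volumes, peak normalised to 1)
sampled at the volume times, plus noise; per-stimulus betas are
recovered by FIR least squares and averaged over volumes 2–4 (1-based
numbering throughout).

What the generator does *not* emulate: hemodynamic variability, motion
or physiological noise, spatial smoothing, anatomical normalization,
group differences in informative voxel location (the ground truth is
shared between sighted and blind groups — so same-modality,
cross-group transfer is expected even at the whole map, unlike real
data), and voxel-wise noise correlations. Passing tests therefore
demonstrate correctness and qualitative behaviour of the *procedure*,
not expected accuracy levels on real scanner data.

## Numerical and degenerate-case conventions

* Zero-variance voxels scale to 0; already-scaled matrices refuse
  re-scaling.
* Elimination always removes at least one voxel, so traces terminate.
* |w| ties eliminate the lower voxel index first; accuracy ties select
  the smaller voxel set; best-fold ties select the lower fold index.
* Permutation p uses the add-one estimator and is never 0.
* Empty survivor set after exclusion → accuracy 0.5 + warning flag;
  empty knock-out mask is an error for restriction.
* All randomness flows from a single integer seed; runs are
  bit-reproducible (verified byte-identical reports).

## Problem sizes used in the shipped experiments

The shipped configurations run on a 12×12×12 grid (1728 voxels) with
the full 14 + 8 subject design; permutation tests use n_perm = 99 and
recovery experiments use 10 replicate datasets. These desk-scale sizes
were chosen so a complete analysis, including permutation inference,
finishes in about a minute on one core while exercising every stage at
the study's real example counts.

## Known limitations

* Pooled-before-folds scaling reproduces the emulated preprocessing
  order and therefore a mild train/test leak; use `scaling: per_fold`
  to remove it.
* Selection optimism in permutation p-values for selected accuracies
  (see Inference above).
* The 3×3 cross-condition table re-uses each condition's own scaling;
  cross-condition transfer therefore assumes comparable voxel-wise
  response scales across conditions.
* `balance_classes` duplicates examples before scaling, so duplicated
  stimuli influence the per-voxel scaling statistics twice — matching
  the emulated order of operations.
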