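# Methods

## Problem and model

A 2D CNN classifying 3D brain MRI must be trained and evaluated on 2D
slices. How slices are dealt into cross-validation folds decides whether
the reported accuracy is meaningful:

* **subject-level split** — subjects are dealt to folds; all slices of a
  subject stay on one side of every train/test boundary;
* **slice-level split** — all slices of all subjects are pooled and dealt
  individually, so slices of one subject appear in both training and test
  folds.

Axial T1-weighted slices of one subject are highly correlated, so under a
slice-level split the model can score a test slice by recognising the
subject from its training siblings, regardless of the diagnostic label.
The package quantifies that inflation with a controlled pipeline:
synthetic cohorts whose intra-subject correlation and class signal are
knobs, entropy-based slice selection, nested cross-validation with an
inner hyperparameter grid search, and a randomized-label control in which
any above-chance test accuracy is, by construction, evaluation error.

## Synthetic cohorts

Each subject's volume is

    voxels = template + effect_size * 1[label=1] * 1[effect_region] + noise

with `template` Gaussian-filtered white noise (kernel SD
`template_smoothness`, default 3 voxels) standardized to mean 0 / SD 1
inside the brain mask, and `noise` voxelwise i.i.d. Gaussian with SD
`slice_noise_sd` drawn independently per slice. Background outside the
mask is exactly zero, as in skull-stripped scans. The mask is a centered
3D ellipsoid whose mid-slice cross-section covers ~60% of the slice and
whose polar semi-axis slightly exceeds the half-depth, so every slice has
a non-empty, centrally-peaked cross-section; the resulting per-slice
foreground-area gradient is what gives the entropy ranking a meaningful
ordering (central slices carry the most gray-level diversity).

Because the template is shared by all slices of a subject and smooth along
the slice axis (adjacent-slice template correlation ≈ 0.97 at smoothness
3), within-subject slice pairs correlate far above between-subject pairs;
`slice_noise_sd` is the single knob attenuating that correlation. At the
default 0.2 the same-subject slices are near-duplicates — the regime in
which slice-level splits leak hardest.

Default study condition (the "desk-scale" preset): 34 subjects (17 per
class, the small-cohort size of interest), volume shape (12, 64, 64),
smoothness 3.0, noise SD 0.2. These emulate the statistical structure the
leakage mechanism needs, not MRI physics: no bias fields, no scanner
effects, no anatomy. Passing tests therefore demonstrate properties of
the *evaluation schemes*, which transfer to real data through the one
statistic that matters here (intra-subject slice correlation), not
properties of any diagnostic model.

### Label randomization in the null control

`randomize_labels` defaults to independent fair coin flips. The null
*control* preset instead uses a random **balanced permutation** of the
17/17 label vector. The distinction matters at this cohort size: 34 coin
flips leave an expected majority share of ≈ 56.8%, and any consistent
classifier tracks that prior on unseen subjects (measured: 66% "chance"
accuracy on a 21/13 relabeling), which would confound the chance-level
reading of the subject-level arm with class imbalance. The balanced
permutation keeps labels independent of images while fixing the chance
level at exactly 50%; at a few hundred subjects the two constructions are
practically indistinguishable.

## Slice selection, resizing, standardization

For each volume the Shannon entropy of every axial slice is computed over
a 256-bin equal-width gray-level histogram spanning the volume's intensity
range (so per-slice scores are comparable), with `0·log 0 = 0`:

    E_S = − Σ_k p_k log2 p_k ,  0 ≤ E_S ≤ log2(256).

The top 8 slices are kept, ordered by descending entropy with ties broken
by ascending slice index (deterministic outputs). Whether the histogram
covers the whole slice or only in-mask pixels is configurable
(`entropy_domain`); the default is the whole slice, background included,
which matches the upstream slice-selection recipe this protocol follows.
Both options are tested.

Selected slices are resized with bicubic interpolation (cubic spline over
the 4×4 neighbourhood, pixel-center coordinate mapping, mirror boundary);
the desk-scale target is 64×64, with 224×224 available for full-scale
runs. Intensity standardization offers two scopes, because "voxel-wise
standardization within the brain mask" admits two readings: per-image
(each slice centered/scaled by its own in-mask statistics; idempotent;
the default) and per-voxel-across-subjects (per-position statistics
fitted, deliberately, on the training portion of each fold only — fitting
them on the full dataset would itself be leakage).

## Fold construction and nested CV

Folds are stratified by class and dealt deterministically: units (subjects
or pooled slices) are shuffled within each class with a seeded RNG,
concatenated class-by-class, and dealt round-robin. This guarantees both
that overall fold sizes differ by at most one unit and that per-fold class
counts stay within one unit of the global proportion — guarantees that
off-the-shelf stratified splitters do not make jointly for the overall
unit count. Whether the original protocol stratified is not documented;
stratification is the conservative choice for 34-subject cohorts, where an
unlucky deal could otherwise produce single-class folds.

Nested CV: the outer k-fold loop estimates generalization; for each outer
fold the k−1 training folds are re-dealt (same strategy) into inner folds
(default k−1, configurable; the desk preset uses 2 to keep CPU time in
minutes), every grid point is scored by mean inner-validation slice
accuracy, ties break toward the smaller learning rate then smaller decay,
and the winner is refit on the full outer-training data. Outer test
slices never reach the inner loop (asserted by instrumentation in the
tests). The outer k defaults to 5; 10 is available — the source protocol
is reported inconsistently between five- and ten-fold, and neither is
asserted as the true one.

The split strategy applies identically at both loop levels: the contrast
under study is between whole pipelines, and mixing strategies across
levels would blur it.

## Classifiers

The three transfer-learning architectures (VGG16 feature-extractor with a
three-layer ReLU head and frozen backbone; VGG16 with GAP head, fully
fine-tuned; ResNet-18 with an appended sigmoid unit, fully fine-tuned;
new layers Xavier-initialized) are captured as declarative `ModelSpec`
values. Building them requires pretrained backbone weights, an optional
runtime dependency the package neither bundles nor downloads; requesting
one without weights raises an explicit error. All quantitative work uses
the surrogate.

The **surrogate CNN** is written in NumPy: a 2×2 average-pool stem, two
3×3 convolution + ReLU + 2×2 max-pool blocks (8 and 32 channels), a 4×4
average-pooling grid head (512 features) and one sigmoid unit, ~27k
parameters. Design criteria, in order: train in about a second on one CPU
core at 64×64 inputs, and have enough capacity to memorize which of 34
subjects a slice came from — the capacity that converts a slice-level
split into inflated accuracy. A plain global-average-pooling head (32
features) measurably lacks that capacity (training accuracy plateaus near
0.8 on the memorization task), hence the coarse spatial grid; with
`pool_grid=1` the head reduces to plain GAP.

Training: Adam on sigmoid cross-entropy (the loss is an assumption; the
source never states one), batch size 32 and 16 epochs in the desk preset
(128/50 at full scale), inverse-time learning-rate schedule
`lr_t = lr / (1 + decay · t)` with `t` the 0-based epoch ("decay" is
never defined upstream; inverse-time is the convention of that software
generation). Weight init and batch shuffling derive from one seed, so
training is bit-reproducible on CPU.

The inner grid search spans learning rates {1e-5 … 1e-3} × decays
{0, 0.1, 0.3, 0.5} at full scale. The desk-scale reduced grid is
{1e-3, 1e-2} × {0, 0.3}: one decade higher than a naive scaling-down of
the full grid, because a small CNN trained from scratch needs larger Adam
steps than fine-tuning runs of pretrained networks — at lr ≤ 1e-3 the
surrogate cannot reach memorization within a CPU-sized epoch budget.

## Leakage audit and the experiment

`audit_leakage` reports, per test fold, the fraction of its slices whose
subject owns at least one slice on the training side. Subject-level
assignments audit to exactly 0; slice-level assignments with 8 slices per
subject audit to ≈ 1 (a slice escapes only if all 7 siblings land in its
fold, which is combinatorially negligible at k=5).

The experiment runs preprocessing → nested CV for every (model, strategy)
pair, reports mean outer-fold train/test slice accuracies (unweighted mean
over folds, no per-subject aggregation) per replicate seed and pooled, and
derives the **inflation difference** = slice-level − subject-level mean
test accuracy. The randomized-label control enforces `effect_size = 0`
and randomized labels; its subject-level arm is the chance-level check and
its slice-level arm the leakage measurement. Replicate seeds re-generate
the cohort and re-deal folds, so pooled numbers average over data, split
and weight randomness; every reported number is recomputable from the
stored seeds and configs alone.

Desk-scale outcome (recomputed by `scripts/acceptance.py` and the
analysis drivers): subject-level ≈ 50%, slice-level ≈ 95%, an inflation
of ≈ 45 accuracy points on labels that are pure noise.

A note on replication: the slice-level arm is very stable across
replicate seeds, but the subject-level arm carries subject-level sampling
noise — an unseen subject's eight slices receive almost identical
predictions, so one 34-subject replicate contributes roughly 34 effective
observations, not 272, and a 5-seed pooled mean has an SD of about 4
accuracy points. The acceptance script therefore pools the subject-level
arm over 15 replicate seeds (slice-level over 5), which narrows the
chance-level estimate without changing its expectation.

## Numerical choices and degenerate inputs

* Entropy of a constant slice (or constant domain) is 0 bits; the
  histogram range is the volume's domain range, degenerate ranges short-
  circuit to 0.
* Standardization refuses zero-SD images/positions with an error naming
  the offender rather than producing NaNs.
* Max-pool backward routes the gradient to every tied maximum
  (subgradient); ties occur essentially only at ReLU zeros, where the
  gradient is masked anyway.
* Training raises a explicit error on non-finite loss, carrying the fold
  and grid point when inside nested CV.
* Fold dealing, grid tie-breaks and slice ranking are all deterministic
  given seeds; there is no hidden global RNG state.

## NIfTI I/O

Volumes and masks are reoriented to canonical RAS order on load; axial
slices are indexed 0-based from the inferior end, so selected slice
indices are comparable across storage orientations. The loader refuses
volumes without a mask, non-binary masks, shape mismatches, non-finite
voxels and ambiguous affines. Registration and skull stripping are out of
scope: the package consumes already-preprocessed volumes.

## Known limitations

* The synthetic generator models correlation structure, not anatomy or MRI
  physics; absolute accuracies on real cohorts depend on factors it omits.
* The surrogate CNN is a capacity stand-in, not a reimplementation of the
  VGG/ResNet transfer models; transfer specs are declarative only.
* Desk-scale protocol reductions (64×64 inputs, 2 inner folds, 2×2 grid,
  16 epochs) were chosen once as the package's default study condition;
  full-scale values remain available through the same interfaces.
* Single-site, single-volume-per-subject cohorts only; no longitudinal
  structure, no multi-class labels.
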