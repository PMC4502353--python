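# Methods

`selfloc` implements a subject-level multivoxel pattern analysis (MVPA)
pipeline for decoding *perceived self-location* from hippocampal BOLD
activity in a 2×2 factorial out-of-body-illusion experiment, together with
a synthetic data generator that makes every stage testable without any
human data. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
show.

## The experiment the package models

Participants view the scanner room through a head-mounted display from one
of two positions (Location A or B) while receiving visuo-tactile strokes
that are either synchronous (inducing the illusion of being at that
location) or asynchronous with a 1-s delay (breaking the illusion; the
matched control). The factorial crossing gives four conditions. Each 24-s
block has three phases: *Room* (13.5 s, scene visible), *Curtain* (8 s,
vision fully occluded — visual input identical across all four
conditions), and *Eyes-closed* (2.5 s). Each condition repeats 10 times
per run; five runs of 250 volumes are acquired at TR = 4 s with
1.5 × 1.5 × 1.8 mm voxels, and the first three volumes of each run are
discarded as non-steady-state.

The scientific question is whether the hippocampus carries a multivoxel
code for where the participant *feels* located, over and above what the
visual input explains. Decoding is therefore restricted to the Curtain
phase, and the critical contrast is: Location A vs B decodable from
synchronous trials, but sync-trained classifiers failing on asynchronous
trials.

## Preprocessing

Fixed order: discard initial volumes → 3-mm FWHM isotropic Gaussian
smoothing (mm converted to per-axis voxel sigmas; kernel renormalized at
the volume boundary so constants are preserved) → ROI extraction (columns
in lexicographic voxel order, the voxel universe of every downstream map)
→ per-voxel, per-run normalization to percent of the run mean → trial
labels shifted two volumes later in time (hemodynamic delay) → per-voxel,
per-run linear detrending → single-trial responses formed by averaging the
volumes whose acquisition onset falls in the shifted half-open Curtain
window. With TR = 4 s and phase bounds 13.5/21.5 s this selects exactly
two volumes per block.

Choices where the procedure was genuinely open:

* **Normalization variant.** "Relative to the run average" could mean
  division (percent of mean) or subtraction. Division is the default; the
  two differ only by a per-voxel-per-run rescaling by mean/100 (within a
  fraction of a percent of 1.0 on baseline-normalized data), and a test
  asserts that full searchlight maps under the two variants agree to a
  fraction of an accuracy point.
* **Shift vs detrend order.** The label shift moves labels, not data, so
  detrending before or after it yields identical responses; the package
  folds the shift into the trial-window selection.
* **Volume-to-phase assignment.** Acquisition-onset-in-half-open-interval.
  Midpoint rules can select one or three volumes per block depending on
  alignment; the onset rule yields the stated 8-s/2-volume average
  deterministically.

## Searchlight decoding

The ROI (left + right hippocampus combined, analyzed in native space) is
covered by overlapping, approximately spherical clusters: for *every* ROI
voxel, its k = 33 nearest ROI voxels by Euclidean distance in physical mm
(anisotropic voxel size respected; ties broken by lexicographic index).
Each cluster is decoded with a linear soft-margin SVM (C-SVC, C = 1, no
per-fold rescaling, no hyperparameter search) under leave-one-run-out
cross-validation; the fold accuracy is the percent of left-out-run trials
identified correctly and the cluster accuracy is the unweighted mean over
folds. A voxel's *representative accuracy* is the mean accuracy of all
clusters containing it; the map peak is the maximum voxelwise value. Zero
decision values classify as Location A — a deterministic tie-break on a
measure-zero event.

Cross-condition generalization reuses the fold structure: the classifier
trained on synchronous trials of all runs but r predicts the asynchronous
trials of run r.

### SVM implementation

The solver is an in-package port of the LIBSVM algorithm (sequential
minimal optimization, second-order working-set selection, equality
constraint, unregularized bias) operating on precomputed Gram matrices and
JIT-compiled with numba. The batched searchlight kernel computes each
(cluster, fold) Gram matrix once and reuses it across all permutation
labelings, and initializes the dual variables at the C bound whenever the
training labels are balanced (a feasible start that roughly halves
iteration counts on noise-dominated data). This is what makes
10⁴-iteration permutation schemes tractable on one CPU. The test suite
verifies weight vectors, intercepts, and predictions against
`sklearn.svm.SVC(kernel="linear")` — the same optimization problem solved
by the reference library — across random problems, and a brute-force
searchlight reimplementation reproduces the pipeline's maps bit-exactly on
a 216-voxel ROI.

At the default LIBSVM stopping tolerance (1e-3) the SMO iteration path
depends on trial order, which can flip individual near-boundary
predictions; at tolerance 1e-6 searchlight maps are exactly invariant to
trial reordering (asserted by a test). Inference is unaffected either way
because every labeling is processed identically.

## Permutation inference

Significance is nonparametric: the identical mapping procedure is repeated
with trial labels permuted (10,000 iterations at protocol scale;
reduced, stated counts in tests), and

    P = (1 + #{permuted values > true value}) / (1 + n_iterations)

with a strict ">". Familywise error across the map is controlled by the
null distribution of the *map maximum*; voxelwise (uncorrected) P-values
use the same formula per voxel and are thresholded at P < 0.001 for the
descriptive informative-voxel maps — note this threshold is attainable
only with ≥ 1000 iterations, since min P = 1/(N+1).

* **Exchangeability scheme.** Labels permute independently within each
  run, preserving per-run class balance — the structure the
  leave-one-run-out design assumes. (Whether the original protocol
  permuted within run or across the session is not derivable from its
  description; within-run is the choice here.)
* **Cross-condition null.** Each iteration permutes the *synchronous
  training* labels and re-applies the permuted-trained fold classifiers to
  the untouched asynchronous test trials: the classifier, not the test
  set, carries the location hypothesis.
* **Subregions.** Informative-voxel counts are partitioned into left/right
  × anterior/posterior. Hemisphere comes from the world-x sign; the
  anterior/posterior boundary is y = −21 mm when an MNI-like frame is
  declared, otherwise each hemisphere splits at the midpoint of its
  voxels' projections on their longest principal axis (anterior = +y end).
  The boundary is a convention, exposed as configuration.

Under label exchangeability the familywise-error P-values are valid by
construction; the type-I calibration test measures the empirical rejection
rate at α = 0.05 over 100 null subjects and requires it within [0, 0.08]
(binomial tolerance around the nominal level at 199 iterations).

## Group statistics

Two-tailed throughout, α = 0.05. Peak accuracies (sync vs async) compare
by paired t-test, routed through a Shapiro–Wilk gate to the Wilcoxon
signed-rank test when the differences fail normality (gate requires n ≥ 3;
below that the t-branch is used). Informative-voxel counts compare by
Wilcoxon signed-rank (zeros dropped — Wilcoxon's original rule; exact null
for ≤ 25 untied pairs, else normal approximation with continuity
correction). Subregion counts are tested with the Friedman rank test
(average ranks on ties, χ² approximation, df = k − 1). A one-sample t-test
from summary statistics (mean, SD, n) supports re-testing printed
behavioral summaries; the tests reproduce P = 0.102 for the
−0.67 ± 0.82 (n = 6) curtain-vividness rating. These are standard tests
computed through scipy.stats behind the package's routing contract.

## The synthetic generator

`SimulationSpec` defaults describe one subject of the emulated protocol:
five runs × 40 blocks (10 per cell), 24-s blocks with 13.5/8/2.5-s phases,
TR = 4 s, three dummy volumes plus seven trailing rest volumes per run
(250 volumes/run total; the rest volumes keep the shifted Curtain window
of the last block inside the run), and a 150-voxel ROI formed by two
ellipsoids ("hippocampi") in an 18×14×10 grid of 1.5 × 1.5 × 1.8 mm
voxels.

Signal model: two fixed zero-mean, mutually orthogonal, unit-RMS pattern
vectors over `n_informative_voxels = 20` voxels are drawn once per
subject. During each block's Room+Curtain span, delayed by
`hemodynamic_delay_volumes = 2`, synchronous blocks add
`pattern_amplitude` × (pattern A or B); asynchronous blocks add a
location-independent common activation of equal energy (orthogonal to both
patterns), so overall stimulation responses match while location
information is absent. Flags can instead give the asynchronous condition
the same or label-swapped patterns, for generalization and anti-learning
checks. The delay is a whole-volume boxcar shift because the analysis
itself models hemodynamics as a two-volume label shift; canonical
double-gamma HRF convolution is available behind `hrf_convolve`.

Noise and nuisance: baseline 100 with i.i.d. Gaussian noise of
`noise_sd = 1` (≈1% signal fluctuation, ordinary for a 3T block design),
optional AR(1) temporal autocorrelation, per-run random linear drift
(`drift_slope_sd = 0.5` signal units over a run), and a decaying 5%
excess on the dummy volumes emulating non-steady-state magnetization.
`pattern_amplitude = 3` (three times the voxelwise noise SD) was chosen to
reproduce the qualitative contrast the protocol reports — synchronous
decoding clearly above chance, asynchronous transfer at chance — since no
effect size in signal units is derivable from the source material; no
printed accuracy values are targeted. All randomness flows through
numpy's PCG64 via `SeedSequence([seed, stage])`, making subjects
bit-reproducible.

What passing tests show: the pipeline recovers planted multivoxel
location codes, its familywise error is calibrated under the null, and the
sync/async dissociation logic behaves as designed. What they do not show:
robustness to physiological noise, motion, susceptibility artifacts,
segmentation error, or HRF variability — none of which the generator
emulates.

## Problem sizes in the validation suite

The acceptance checks run at deliberately scaled-down sizes chosen as this
package's own desk-scale conditions: 150-voxel ROI, k = 15 searchlights,
199 permutation iterations for subject-level inference (the P-value floor
1/200 is then the strongest attainable evidence), 100 null subjects for
type-I calibration, 20 signal subjects for the dissociation check, 200
permutations for the chance-level check. Protocol-scale runs (k = 33,
10,000 iterations) use the same code paths and remain practical (a
10,000-iteration, 150-voxel subject completes in roughly two minutes on
one CPU).

## Known limitations

* Native-space, subject-level analysis only; no registration, no
  group-level voxelwise maps.
* The searchlight is centered at every ROI voxel; sparser partitions are
  not implemented (stride sensitivity can be explored via custom masks).
* Wilcoxon falls back to the normal approximation in the presence of tied
  absolute differences even at small n.
* The Friedman wrapper requires k ≥ 3 conditions (k = 2 degenerates to a
  sign test, out of scope).
* Below-chance *true-label* map means on null data (≈48–49%) are a known
  small-sample property of cross-validated accuracy; the permutation null
  shares and absorbs this, and permuted-label accuracies center on 50%.
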