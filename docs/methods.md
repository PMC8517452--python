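# Methods

This note documents the models, conventions, and numerical choices behind
`prostacad`, and what the synthetic experiments do and do not establish.

## Problem setting

The pipeline characterizes clinically significant peripheral-zone
prostate cancer (volume ≥ 0.5 ml) on co-registered mpMRI. The label being
predicted is the histopathologic grade split GG ≤ 2 versus GG > 2, with
GG > 2 ("high aggressive") as the positive class throughout. Inputs are
assumed registered upstream: four scalar channels on one axis-aligned
grid (T2w in arbitrary units; ADC in 10⁻⁶ mm²/s; DCE maximum uptake as
percent signal increase in the first minute; a voxel-wise malignancy
probability in [0, 1]). Producing the probability and uptake maps (the
voxel-level classifier and the pharmacokinetic model behind them) is out
of scope; they are pipeline inputs.

## Candidate detection

A voxel is kept iff it passes all three rules, inclusive on the keep
side: probability ≥ 0.60, 200 ≤ ADC ≤ 1600 (×10⁻⁶ mm²/s), uptake ≥ 100%.
The ADC band is stated in the literature as "mm²/s", which is physically
implausible for raw SI units; we store the unit explicitly as
10⁻⁶ mm²/s, the standard prostate ADC scale. Kept voxels are grouped
into 26-connected 3D components.

**Area rule.** A component is emitted iff its area strictly exceeds
100 mm². "Area" of a 3D component is ambiguous; we default to the
*volume-equivalent* reading — component volume divided by the axial
slice thickness — because the 100 mm² threshold is defined as 60% of the
smallest clinically significant lesion volume (0.5 ml), which holds
exactly under this reading on 3 mm slices (100 mm² × 3 mm = 300 mm³ =
0.6 × 500 mm³), and because under the alternative maximal-axial-
cross-section reading a minimum-size spherical 0.5 ml lesion (largest
cross-section ≈ 76 mm²) would be discarded, defeating the rule's stated
purpose. The maximal axial cross-section remains available
(`DetectionConfig.area_mode = "max_axial"`) and is always reported per
candidate.

The human lesion-confirmation step is replaced by an overlap surrogate:
the candidate with maximal Dice against a reference mask.

## Preprocessing

Fixed order: Gaussian de-noise → isotropic resample → ROI re-segmentation
→ discretization.

- **De-noising**: isotropic Gaussian of physical σ = 0.5 mm, converted
  per axis to voxel units; reflective boundaries (avoids edge darkening
  on small fields of view). Applied to both T2w and ADC by default,
  switchable per channel.
- **Resampling** to 0.5 mm isotropic; trilinear for images, nearest
  neighbour for masks (outputs stay binary). The output grid is
  corner-aligned: voxel 0 keeps its position and the grid is the densest
  one at the target spacing that stays inside the input sample range, so
  interpolation never extrapolates, trilinear resampling reproduces
  affine intensity ramps exactly, and a single-voxel axis degenerates
  gracefully without a special case. Physical extent is preserved within
  one voxel.
- **Re-segmentation** keeps mask voxels whose intensity lies within the
  in-ROI [P1, P99] window, inclusive, with the linear-interpolation
  percentile convention. It is applied per channel (each image's own
  percentiles), since outlier trimming is an image-intensity operation.
  Note that with interpolated percentiles re-segmentation is *not*
  exactly idempotent — a second pass recomputes the percentiles of the
  already-trimmed distribution and may trim a few more voxels; the tests
  assert the true weaker property (nested, small second-pass loss).
- **Discretization** is fixed-bin-number over the in-mask range:
  `level = min(N, 1 + ⌊N (x − x_min)/(x_max − x_min)⌋)`; a constant ROI
  maps to level 1. Two independent discretizations coexist: N = 64 feeds
  the intensity-histogram statistics, N = 32 feeds GLCM/GLRLM — the only
  reading consistent with both stated bin counts. FBN makes texture
  invariant to positive affine intensity rescaling, which matters for
  non-quantitative T2w signal.

## The 92-feature vector

Order and names are a frozen public contract (golden-file test):
ROI volume (mm³, measured on the resampled mask before re-segmentation;
a config flag switches to the native mask); nine ADC intensity
descriptors; 25 GLCM and 16 GLRLM features from each of ADC and T2w.
T2w contributes texture only — its intensities are not quantitative.

Among the intensity descriptors, `mean/p25/p50/p75/skewness/kurtosis`
are computed on raw in-mask ADC values (Fisher skewness and excess
kurtosis from population moments; both defined as 0 at zero variance),
while `intensity_kurtosis`, `intensity_variance`, and
`intensity_hist_mean` are the same moments on the 64-bin discretized
levels — the reading that makes the eight statistics distinct.

Texture matrices are computed per direction at one-voxel distance over
the 13 unique non-antiparallel offsets of the 26-neighbourhood; GLCMs are
symmetrized and normalized, GLRLM runs are maximal in-mask runs (a
masked-out voxel terminates a run). Features are computed per direction
and arithmetically averaged; directions with no valid pair are excluded
from the average. After isotropic resampling this makes the averaged
features invariant under all 48 axis-aligned cube symmetries (verified to
1e-8), the operational meaning of "rotationally invariant". Degenerate
conventions: information-correlation features are 0 at zero marginal
entropy; GLCM correlation is 1 for a zero-variance (single-level) matrix;
inverse variance sums off-diagonal cells only.

Feature definitions follow the standard IBSI formulas; every GLCM/GLRLM
feature is verified against an independent brute-force implementation
(explicit loops) to 1e-10 on randomized small ROIs.

## Feature selection

Features are min–max scaled to [0, 1] on training rows; held-out values
are deliberately not clipped, and constant training columns map to 0.
Each feature is ranked by its bootstrap AUC: the mean over 1000
case-resampled replicates of the tie-corrected (midrank) AUC, folded to
max(AUC, 1 − AUC) so that features whose *low* values mark aggression
rank correctly; 95% CI by the percentile method; replicates missing a
class are redrawn; one set of resample indices is shared across features.
Redundancy pruning visits pairs with |Pearson ρ| strictly above 0.9 in
descending |ρ| and drops the lower-AUC member (a 1e-12 guard keeps
correlations numerically at the limit); pairs with an already-dropped
member are skipped.

The wrapper feeds nested top-*n* subsets to the SVM under stratified,
patient-grouped 4-fold CV (grouping prevents leakage when one patient
has two lesions; folds failing to contain both classes are reshuffled
with derived seeds, max 10 attempts). Accuracy uses the standard 0.5
score threshold. The **overfitting point** is operationalized as the
smallest n at which mean test accuracy is maximal and does not improve
at n+1 or n+2 — the point where the training curve keeps rising while
the test curve stops. The box constraint is then tuned by grid search
over C = 1..50 on the identical folds, ties resolved toward the
smallest C (strongest regularization).

## Classifier and score

`K(x, z) = (⟨x, z⟩ + 1)³` (gamma 1, coef0 1 — the conventional
polynomial-kernel parameterization on [0, 1]-scaled features). Decision
values are calibrated by a Platt sigmoid fitted on the training decision
values with the regularized targets (N₊+1)/(N₊+2) and 1/(N₋+2), solved
by damped Newton iterations — monotone, deterministic, and
JSON-serializable, so the model file fully determines scoring. Whether
the score is "a probability" is not asserted; it is a calibrated
monotone transform of the margin, clamped to [0, 1].

Cutoffs are found by exhaustive search over the midpoints of adjacent
sorted unique scores (plus the all-positive and all-negative
thresholds), with positives called strictly above the cutoff. Youden
ties resolve toward higher specificity. The NPV-max cutoff considers
only thresholds making ≥ 1 negative call and breaks ties by maximal
specificity, then the lower threshold. Note the guarantee "zero false
negatives at the NPV-max cutoff" holds exactly when the lowest-scoring
training case is a negative (otherwise no threshold attains NPV = 1);
this is the regime a trained scorer produces on its own training set.

The three-tier band: aggressive if score > Youden cutoff, indeterminate
in the 15% window directly below it, indolent at or below 0.85 × cutoff.
The bands partition [0, 1] and the level is monotone in the score.

## Evaluation statistics

Confusion metrics carry Wilson 95% CIs (bounds snapped to exact 0/1 at
degenerate counts); PPV/NPV are reported absent (not 0) when no
positive/negative call exists. Mann–Whitney U is exact for tie-free
samples with n ≤ 8 per side, otherwise the tie-corrected normal
approximation without continuity correction. Paired AUCs are compared
with DeLong's test (midrank structural components; a zero-variance
difference returns p = 1); the between-center comparison uses Pearson's
chi-squared without continuity correction (Yates optional). All tests
are two-sided. No multiple-testing correction is applied across the
per-feature tests, mirroring common practice in this setting; treat the
monoparametric p-values accordingly.

## Synthetic data

The phantom emulates the *statistical* structure the pipeline assumes,
not MR physics: an ellipsoidal gland, planted non-overlapping ellipsoidal
lesions ≥ 0.5 ml, and two generative classes mirroring the GG split —
high-aggressive lesions have lower ADC (850 vs 1100 ×10⁻⁶ mm²/s class
means, inside the detection band; the well-known inverse ADC–grade
relation, here an assumption), larger volumes (0.8–2.5 vs 0.5–1.2 ml),
and rougher texture, implemented as a shorter Gaussian-random-field
correlation length (1.2 vs 3.0 mm). Lesion voxels carry probability and
uptake plateaus (0.85, 150%) above the detection thresholds. Default
grid 80×80×24 at (0.6, 0.6, 2.4) mm. Everything is a pure function of
the spec including its seed.

The feature-table generator produces standard-normal features with a
chosen informative subset (class mean shift Δμ in sd units, default
1.5σ), optional high-correlation blocks via shared latent factors, class
prevalence 0.41 (33 aggressive of 81, the training mix of the clinical
setting), and 12% two-lesion patients for the grouping logic.

**What passing tests do not show.** The phantoms have no scanner or
protocol variability, no registration error, no transition-zone anatomy,
no benign mimickers (prostatitis, hyperplasia), and their class
separation is planted. Synthetic performance numbers therefore
characterize the *correctness* of the machinery — detection recall,
oracle equivalence, cutoff optimality, selection behavior,
reproducibility — not expected clinical accuracy; clinical headline
numbers require patient data this package does not ship.

## Problem sizes and numerical conventions

The default acceptance run uses 24 phantom cases (64×64×20 grid) for the
imaging study and 81 training / 68 validation rows (33 positives each,
the clinical cohort sizes) with six informative features and one
ρ = 0.996 near-duplicate pair for the classification study; these sizes
are the package's declared study conditions. Tolerances: texture oracle
1e-10 absolute; rotation invariance 1e-8; geometric channel agreement
1e-3 mm. All RNG is NumPy `default_rng` seeded explicitly; CV folds,
bootstrap indices, and SVM fits are deterministic given the seed, and a
training run reproduces its model file bit for bit. Model files embed a
SHA-256 content hash; loading verifies it and the schema version.

## Known limitations

- Single-lesion candidate confirmation is overlap-based; a clinical
  deployment would reinstate the human-in-the-loop step.
- Matrix-merging aggregation (pool matrices, then compute features) is
  not the default; the per-direction-then-average procedure is
  implemented as the primary definition.
- No nested CV: the wrapper's CV accuracy is model-selection accuracy,
  not an unbiased generalization estimate — by design, matching the
  procedure being reproduced; the validation split provides the honest
  estimate.
- Shape features beyond volume, filtered-image features, and 2D
  per-slice texture are out of scope.
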