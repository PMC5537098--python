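# Methods

This note records the models implemented in `vstmap`, the configurations
behind each feature family, the choices made where the underlying method
admits many variants, and what the synthetic phantoms do and do not show.

## Problem setting

The unit of analysis is a 2-D CT slice with HU-like integer intensities,
a radiologist-drawn binary mask of one *primary lesion* (≥ 16 pixels, one
connected component), and optionally an organ mask (e.g. the liver)
restricting analysis to a crop region.  Per-sample annotations are sets of
visual semantic terms (VSTs).  Three stages follow: feature extraction,
similar-lesion counting, and per-term feature selection/classification.

## Feature bank (495 + 1 dimensions)

Block dimensions are fixed (intensity 6, texture 376, shape 20, histogram
32, edge 61 = 495; +1 similar-lesion count = 496).  The named families
admit many internal variants; the configurations below are declared
choices that pin the bank down exactly.

**Intensity (6).** Lesion median; Shannon entropy (bits) of a 32-bin
histogram of lesion intensities; fraction of lesion pixels above a
threshold (defaulting to the within-class-variance optimum `T*` of the
crop region, overridable via `FeatureConfig.proportion_threshold`); and
the difference between the lesion mean and the mean of a surrounding ring
at three dyadic scales (morphological dilation by 2, 4 and 8 px minus the
mask).

**Texture (376).** Computed on the bounding-box patch with outside-mask
pixels replaced by the lesion median, so statistics are mask-driven.

* GLCM (12): 3 Haralick statistics (contrast, correlation, energy) × 4
  offsets (0°, 45°, 90°, 135°) at distance 1 on 32 quantised gray levels.
* Gabor (32): 4 dyadic frequencies (1/16, 1/8, 1/4, 1/2 cycles/px) × 4
  orientations × (mean, sd) of the complex response magnitude inside the
  mask.
* Daubechies (324): the patch is resampled to 64×64 (bilinear, no
  anti-aliasing, for translation invariance), decomposed with db4 at 3
  levels (periodised); each of the 9 detail subbands (levels 3→1 ×
  orientations H, V, D) contributes a 6×6 grid of block mean-square
  energies.
* Haar (1): total detail energy of a 1-level Haar decomposition of the
  same 64×64 patch.
* Run-length (7): SRE, LRE, GLN, RLN, RP, LGRE, HGRE from a run-length
  matrix of horizontal runs on 16 quantised levels.  (Implemented here
  directly; the surrounding steps use scikit-image/PyWavelets.)

**Shape (20).** Compactness 4πA/P²; moment-ellipse eccentricity;
roughness = perimeter / convex-hull perimeter; local area integral
invariant (mean over boundary pixels of the in-mask fraction of a
radius-r disk) at 15 radii r = 2…16 px; mean and sd of the
centroid-to-boundary radial distance.

**Histogram (32).** Uniform LBP (P = 8, R = 1): the fraction of lesion
pixels in each of the 10 uniform codes plus the energy and entropy of
that distribution; and 20 equal-width intensity bins over a configurable
HU window (default [−200, 400]); out-of-window values are clipped into
the edge bins so counts conserve the lesion pixel count.

**Edge (61).** 60 profiles normal to the subpixel lesion contour (equally
spaced by arc length, ±4 px at 0.5-px steps, bilinear sampling); the
sharpness of each profile is its maximum absolute finite-difference
slope.  The 61st value is the entropy of Sobel gradient magnitudes on a
one-pixel band around the contour.

**Normalisation.** Columns are z-scored with the population sd (divide by
N); constant columns map to zero.  The per-column (mean, sd) is stored and
re-applied verbatim at prediction time — test data never re-fits the
normalisation.

## Similar-lesion counting

The weight λ in `J(λ, T) = (1 − λ) σ_w(T) − λ |m_l(T) − m_b(T)|` is chosen
from the primary lesion's homogeneity: λ = 0.75 when at least 68% of its
pixels fall within one (population) sd of its mean — the Gaussian
expectation, boundary inclusive — and λ = 0.15 otherwise.  `T*` minimises
J over a grid of all integer intensities between the 1st and 99th
percentile of the crop region; ties break to the smallest threshold, and
a threshold that empties a class scores +∞.  The lesion class is the side
of `T` on which the user-drawn primary mask's mean lies (J itself is
symmetric in the two classes).

Candidate clusters are 4-connected components of the thresholded crop
region, ordered by the scanline position of their topmost-leftmost pixel;
clusters below `min_cluster_px` (default 9) are dropped, and any cluster
overlapping the primary mask is excluded so the primary is never counted.
Each cluster's signature is

* α = √(Δmean² + Δsd²), the contrast between the cluster interior and a
  two-pixel ring immediately outside it (dilation by 2 px minus the
  cluster).  The two first-order statistics are collapsed into one
  magnitude because the similarity distance needs a scalar α; the
  definition is isolated in `cluster_signature` and easy to swap.
* β = major/minor moment-ellipse axis ratio of the cluster's pixel
  coordinates, with the minor axis floored at 1 px for degenerate
  (collinear) clusters.

A cluster is counted when its Euclidean distance to the primary's
signature in (α, β) space is at most `similarity_threshold` (default
10.0; α is HU-like, β dimensionless).  Both the threshold and
`min_cluster_px` are config-exposed; the defaults are declared values,
not fitted ones.  Without an organ mask, the crop region defaults to the
primary bounding box expanded by 4× its diagonal, clipped to the image.

## PmEI feature selection

Per term `a_k ∈ {1, −1}` (both classes required):

1. Every z-scored feature column is discretised into 8 equal-frequency
   bins (ties share the lower bin; a constant column yields one code and
   hence zero information).  Eight bins are a scale-robust default after
   z-scoring.
2. Relevancy is the plug-in mutual information `I(f; a) = H(f) + H(a) −
   H(f, a)` in bits; features are sorted by descending relevancy, ties by
   ascending column index.
3. The top feature initialises the selected set; the pooled fivefold
   cross-validated accuracy `τ = (TP + TN)/N` of an SVM (Gaussian kernel,
   C = 1, kernel width 1/(number of active features), untuned) is its
   baseline.  Folds are stratified by class and fully seeded —
   stratification avoids single-class folds on imbalanced terms.
4. Remaining features are scanned once in ranking order; a candidate is
   kept iff τ strictly increases (ties reject).  Features are never
   revisited or removed, so the accepted-τ sequence strictly increases by
   construction (asserted on every run) and the selected-set size is
   data-driven.
5. Selected features get ranking values: relevancies rescaled linearly so
   the maximum maps to 5 and the minimum to 1 (all 5 when equal);
   unselected features get 0.  This 0–5 convention is a declared choice.

A known property of this greedy, strict-improvement scheme: on data where
the labels are independent of all features, the *internal* final τ is not
an unbiased accuracy estimate.  It is the running maximum of ~n_features
correlated CV estimates, and a permutation-chance simulation (60 runs of
the selector on label-independent 200×50 designs) places it at 0.65 ±
0.03 rather than 0.5.  The held-out accuracy of the selected model on
fresh data from the same design remains at chance (0.5), which is what
the test suite asserts alongside the simulated null band for τ itself.

## Training, prediction, persistence

Terms occurring in fewer than 20% or more than 75% of training samples
(boundaries inclusive) are dropped before training: near-absent or
near-universal terms give the selector too little class signal and invite
overfitting.  Terms whose minority class is smaller than the fold count
are skipped with a warning.  After selection, each term's classifier is
refitted on the full cohort over its selected columns; the bundle stores
the support vectors, dual coefficients, intercept, kernel width and class
order — prediction evaluates the RBF decision function directly from
these, so a saved bundle is a plain versioned JSON file with no pickled
objects, and loading a bundle with a mismatched format version fails
hard.  Prediction emits one binary decision per modelled term.

## Synthetic phantoms: what they show and what they do not

`make_lesion_phantom` renders an elliptical liver (levels are HU-like:
background −50, liver 80 by default) containing a primary lesion and
planted satellites as filled rotated ellipses with flat, speckled or
bimodal-checker fill, plus optional global Gaussian noise, all as int16
and fully seeded.  These shapes have analytically known moments, which is
what the shape/signature oracles rely on.  The phantoms do **not**
emulate CT noise physics, partial-volume effects, anatomy beyond one
elliptical organ, lesions with diffuse margins, or 3-D structure —
passing the recovery tests demonstrates correctness of the algorithmic
pipeline on controlled inputs, not clinical performance.  Likewise
`make_feature_label_matrix` plants a label signal (default: sign of the
sum of the informative columns, plus label flips) in otherwise i.i.d.
normal features; real radiomic features are heavily correlated, so
selection behaviour on real cohorts can differ.

Cohort-level checks use phantom cohorts whose terms are driven by single
appearance attributes (lesion density, elongation, multiplicity) with a
deliberately universal extra term that the occurrence filter must remove.

## Problem sizes and numerical choices

Tests and the acceptance script use 96–128 px images, cohorts of 24–40
phantoms, 200×50 selection designs, 20 seeds per recovery experiment and
1,000 sampled joint tables for the MI oracle — sizes chosen so each
experiment still has clear statistical margins while the whole suite runs
on one CPU in minutes.  Numerical conventions: population sd throughout;
base-2 logarithms for all entropies; (row, col) 0-based coordinates;
4-connectivity for candidate clusters and 8-connectivity for validating
the user-drawn ROI; boundary-inclusive comparisons at every documented
threshold (λ rule, occurrence filter, similarity distance).  Degenerate
inputs have pinned behaviour: constant columns z-score and discretise to
zero/one code, a single-pixel-wide cluster gets a floored minor axis, an
emptied threshold class scores +∞, and an empty retained vocabulary warns
instead of failing.

## Known limitations

* Strictly 2-D, single-lesion-ROI analysis; no scanner harmonisation.
* The greedy selector cannot deselect a feature once accepted (a hybrid
  search would be a natural extension).
* The similarity threshold and minimum cluster size are declared defaults;
  on real data they would need calibration against reader counts.
* Organ segmentation is out of scope: without an organ mask the crop
  region is a box around the primary lesion, which can admit clusters
  from neighbouring organs.
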