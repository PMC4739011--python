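# Methods

This note documents the models and procedures implemented in `dermolesion`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and the limits of what the synthetic test bed can show.

## Preprocessing

Hair removal rests on the black top-hat transform
`T(I) = closing(I, b) − I` with a disk structuring element `b`. The
transform responds to structures *darker than their surroundings and
thinner than the element*; with a disk a few pixels wide this isolates
hairs while leaving the (much larger) lesion body untouched. Parameters:

| parameter | default | rationale |
|---|---|---|
| NTSC luminance weights | (0.2989, 0.5870, 0.1140) | the standard NTSC-1953 coefficients |
| median window | 5 px | removes sensor noise and small shines without blurring hair edges |
| disk radius | 5 px at 768-px width, scaled with width, floor 3 px | must exceed half the hair stroke width at any resolution |
| hair binarization threshold | 20 intensity levels | above sensor noise, below any hair-to-skin contrast of interest |
| hair minimum skeleton length | 50 px (scaled) | rejects dots and globules, which are diagnostic, not artifact |
| hair minimum elongation | 4 | see below |
| inpainting dilation | 2 px | covers anti-aliased hair borders |
| frame threshold / row fraction | 30 / 0.9 | a frame row is almost entirely near-black |

**Elongation definition.** Elongation is computed as
`skeleton_length² / component_area`, i.e. skeleton length over mean stroke
width. For a straight hair this equals the familiar major/minor moment-axis
ratio (an 80 px × 2 px line scores 40 either way), but crossing hairs merge
into X- or star-shaped components whose moment ellipse is nearly round;
the skeleton-based ratio stays large for them, so bundles of crossing
hairs are still recognized. For the same reason the binarized top-hat is
closed with a 2-px disk before component analysis: a hair crossing a
region nearly as dark as itself briefly dips below the binarization
threshold, and the closing keeps it one component.

**Border padding.** The grayscale closing pads the image with its global
median rather than edge reflection: reflection doubles the apparent width
of a hair that hugs the image border and hides it from the transform.

**Inpainting** replaces each (dilated) hair pixel with the channel-wise
median of the nearest non-hair pixels. It is deterministic and idempotent.
Known limitation: a hair crossing a structure *as dark as the hair itself*
is invisible to the top-hat by construction — this is a limit of the
method, not of the implementation.

## Segmentation

The healthy skin surrounds the lesion and is homogenized by preprocessing,
so the *background* is grown from the corner seed (0, 0): a 4-connected
neighbor joins when its intensity differs from the running region mean by
at most `tolerance` (default 10% of the image intensity range), and the
mean is updated after every merge. The lesion is the complement, with
interior holes filled and only the largest component kept. The
homogeneity predicate and tolerance are our choices; a running mean makes
the region robust to slow illumination drift while a fixed seed keeps the
result deterministic. An optional multi-corner union mode exists for
images whose lesion touches one border, but is off by default.

Quality is measured as border error = XOR-area / true-area. On 50 rendered
blob lesions with σ = 3 sensor noise and five hair overlays the median
border error is ≈ 0.3% and all 50 stay below the 6% bound
(`scripts/acceptance.py` recomputes this).

## Shape descriptors

Eight outline descriptors, deliberately not based on perimeter length
(hard to estimate on rasters): maximal diameter (pixel centers, convex
hull), equivalent-circle diameter `√(4·Area/π)`, radial-distance variance
`(1/|B|) Σ (d − d̄)²/d̄²` over the 8-connected inner boundary `B`,
rectangularity and elongation from the *minimum-area oriented* bounding
rectangle (rotating calipers over the pixel-cell hull, so an axis-aligned
square scores exactly 1 and the measures honor rotation invariance),
moment-ellipse eccentricity `√(1 − λ_min/λ_max)`, Haralick compactness
`μ_R/σ_R` (capped at 1e6 for zero-spread radii), and Bribiesca's
normalized discrete compactness `C_DN = (C_D − C_Dmin)/(C_Dmax − C_Dmin)`
with `C_D = (4n − P)/2`, `C_Dmin = n − 1`, `C_Dmax = (4n − 4√n)/2`.

Digitization caveat: all descriptors are rotation-stable to ~3% on
fixtures ≥ 100 px across except the radial-distance variance, which
depends on the rasterized boundary and stabilizes only to ~5%.

## Color descriptors

Computed in CIELAB (sRGB → XYZ D65 → L\*a\*b\*). Lesion-pixel (a\*, b\*)
chromaticities are clustered into four groups; k-means (k-means++ init,
seeded) is the default, with Gaussian-kernel k-means (σ ∈ {1, 2}) and Ward
agglomerative clustering as the stated alternatives. Kernel k-means runs
on a 2 000-px seeded subsample (its kernel matrix is quadratic in size),
Ward on a 10 000-px subsample; remaining pixels join the nearest centroid.

* **Number of colors**: `max(1, ⌊max pairwise centroid distance / τ⌋)`
  with τ = 12 in (a\*, b\*) units.
* **White/black presence**: L\* > 65 / L\* < 15, counted present only when
  the largest 4-connected patch exceeds 1% of the lesion area.
* **Concentricity** = PA · CI · HE over the two clusters with the smallest
  convex hulls (S1 = core, S2 = ring): PA = largest cohesive fraction of
  S1; CI = fraction of S1 inside the hull of S2; HE = fraction of S2
  *outside* the hull of S1. Exactly 1 for a cohesive core inside a clean
  ring; ≈ 0 for side-by-side color patches.
* **Centroid distance**: geometric vs intensity-weighted centroid per
  channel; channels with negative values (a\*, b\*) are shifted to
  non-negative weights first. Lab channels are the default; RGB can be
  passed explicitly.
* **Histogram distances**: 4 × 8 × 8 histograms over fixed ranges
  (L\* ∈ [0, 100], a\*, b\* ∈ [−128, 128)) so histograms are comparable
  across regions; L1 and L2 norms, the L2 including the square root so it
  is a genuine norm.

## Texture descriptors

Intensities are linearly quantized over the lesion's min–max range into
G = 16 levels (G is our choice; 16 balances sparsity of the accumulators
against contrast resolution on typical lesion areas). The GLCM accumulates
pairs over the four unit offsets, discards pairs crossing the mask
boundary, symmetrizes and normalizes; six measures follow (contrast,
correlation, energy, homogeneity, maximum probability, dissimilarity),
with correlation in its standard positive form and dissimilarity with the
absolute difference. The GLRLM counts maximal constant-level runs along
0°/45°/90°/135°, broken at the mask boundary, and sums the four matrices
into one orientation-invariant accumulator (the camera has no reference
orientation); eleven measures follow. Run percentage is normalized by 4n —
each pixel belongs to exactly one run per orientation, so `Σ j·P̂_ij = 4n`
and RP ∈ (0, 1].

## Asymmetry

Three decompositions of the lesion: central part vs border ring (the
central part holds 50% of the area, found by bisecting an erosion depth on
the distance transform), halves along each principal axis, and quarters
from both axes. On-axis pixels go to the lower-index part, so every
decomposition is an exact partition. For a base feature (Lab-histogram
distances between region pairs, the GLCM measures per quarter with a
shared whole-lesion quantization, per-quarter a\* and hue variances) the
population variance across parts measures asymmetry; quarter-to-whole
ratios `R_Qi = f_Qi/f_W` are also emitted. The two shape-asymmetry indices
reflect the mask about each principal axis and report XOR-area /
lesion-area; this principal-axis reflection index is a documented stand-in
for the published clinical asymmetry indices, whose exact formulas are out
of scope here, and is flagged as such in the feature names' documentation.

## Preparation

* **MDLP discretization** (used only to compute information-theoretic
  quantities for selection; classifiers consume continuous scaled
  features): recursive binary splits at boundary midpoints, accepted when
  information gain exceeds
  `(log₂(N−1) + log₂(3^c − 2) − [c·H(S) − c₁·H(S₁) − c₂·H(S₂)])/N`.
* **Scaling**: features passing a chi-square goodness-of-fit test against
  a fitted normal (Sturges bins merged to expected counts ≥ 5, α = 0.05,
  minimum 20 samples) are z-scored over 3 standard deviations; the rest
  are min-max rescaled to [−1, 1]. Statistics are fitted on training folds
  only and applied to test folds — the test sample never influences its
  own scaling.
* **SMOTE**: synthetic minority samples `x + u(x_n − x)` with u ~ U(0, 1)
  and `x_n` one of k = 5 nearest same-class neighbors; every class is
  raised to the majority count. Synthetics are convex combinations, so
  per-class feature ranges are never exceeded. Applied to training folds
  only inside cross-validation (a global mode exists for strict
  whole-table rebalancing).
* **CFS**: greedy forward search on
  `Merit = k·r̄_cf / √(k + k(k−1)·r̄_ff)` with correlations measured as
  symmetric uncertainty `2·(H(X)+H(Y)−H(X,Y))/(H(X)+H(Y))` on the
  discretized features; features MDLP leaves uncut carry SU = 0. The
  search stops at 20 features or when no addition improves merit;
  ties break on feature name for determinism.

## Classification and validation

One binary scorer per class, combined winner-takes-all (argmax of
posterior scores, ties to the fixed BN < CN < MM < SN order). Families:
kNN (k ∈ {3, 5, 10, 15}), L2 logistic regression (C = 1), Gini decision
tree (min leaf 2, no pruning), RBF SVM. Misclassifying melanoma costs 4×
as much as any other error; the cost enters as the positive-class weight
of the melanoma-vs-rest subproblem (kNN has no weight mechanism and
ignores it). SVM posteriors come from a Platt-style sigmoid calibration
fitted by internal 3-fold cross-validation on the training fold; during
grid search the winner-takes-all uses raw decision-function margins
instead, which leaves the selected (C, γ) unchanged while avoiding a
calibration fit per grid cell.

Grid search sweeps C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} × γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}
(11 × 10), scores each pair by Monte Carlo validation accuracy on splits
independent of the final evaluation, and breaks ties toward smaller C then
smaller γ (the weakest model among equals).

Validation is stratified Monte Carlo cross-validation: each iteration
draws a random 10% test split with per-class proportions preserved
(at least one test sample per class), refits the whole preparation chain
(scaling, SMOTE, optionally selection) on the training fold, and
accumulates the confusion matrix and scores. Accuracy, one-vs-all TPR/TNR
per class, and ROC/AUC (trapezoidal, tie-grouped thresholds; the
conventional FPR-on-x orientation) are computed from the pooled results.
The default is 100 iterations.

## Synthetic test bed

`synth.gen_lesion_image` renders disk / ellipse / Fourier-blob outlines on
a homogeneous pale-skin background (RGB (190, 175, 165), σ = 3 Gaussian
sensor noise) on a 512×512 canvas, with uniform / concentric / displaced /
quadrant-recolored color patterns, checker or noise texture, dark hair
lines, and an optional black frame. The concentric pattern separates its
rings with thin bands of the outermost color so that the digital convex
hull of an inner ring never bleeds into its neighbor — a perfect
concentric structure then scores exactly 1. The palette keeps every lesion
structure clearly brighter than hair, so the hair-removal premise holds on
the fixture; images violating that premise (near-black lesion cores) are a
documented failure mode, not a test condition.

`synth.gen_feature_table` emits Gaussian class-conditional feature tables
at the 100/70/70/60 (CN/BN/SN/MM) imbalance of a typical atlas sample:
each informative feature receives a per-feature random permutation of four
evenly spaced class means (adjacent gap = separation/2 within-class σ, so
all informative features carry comparable signal), per-class noise scales
spread over a 3:1 ratio (unequal class covariances make the Bayes
boundaries quadratic, as with real lesion types of unequal variability),
and independent standard-normal noise features.

What passing on this bed does *not* show: robustness to gel bubbles,
vignetting, color-constancy failures, multi-component real pigment
networks, or lesions touching the frame — none of which the generator
emulates.

## Problem sizes

The test suite and the acceptance script run the study at desk scale as
the package's own defaults: 50 lesions for segmentation quality, ten
300-row tables for selection, 100 Monte Carlo iterations for the headline
SVM validation (50 in the acceptance script, where four families are
compared), and a 5-iteration validation inside each grid cell.
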