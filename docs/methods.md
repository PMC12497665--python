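# Methods

`cribromics` implements a region-level MRI-radiomics analysis that asks
whether cribriform Gleason-pattern-4 prostate cancer regions (GP4Crib+)
can be told apart from GP3 and non-cribriform GP4 regions (GP4Crib-)
using quantitative features of co-registered T2-weighted images and
IVIM-derived parameter maps. Because region-level clinical data of this
kind cannot be shared, the package ships a synthetic phantom cohort
generator that reproduces the *structure* of such a dataset, and every
downstream stage — map fitting, mask erosion, feature extraction, model
selection, evaluation — is exercised end to end on phantoms.

## Signal model and parameter maps

Diffusion-weighted signal follows the two-compartment intravoxel
incoherent motion (IVIM) model

    S(b) = S0 · [ f · exp(−b·D*) + (1−f) · exp(−b·D) ]

with tissue diffusion `D` (mm²/s), pseudo-diffusion `D*` (an order of
magnitude faster), and perfusion fraction `f`. The maps are computed by
the *segmented* fit: because the perfusion compartment is negligible at
b ≥ 200 s/mm², an ordinary least-squares line through ln S(b) over the
inclusive window 200–800 s/mm² yields the ADC (negative slope), and the
intercept deficit against the measured b=0 signal yields the fractional
blood volume, fBV = 1 − exp(A)/S(0). This estimator is exact for
monoexponential signals (f=0); with f > 0 the residual pseudo-diffusion
at b=200 biases ADC upward by a few 10⁻⁶ mm²/s under the default
phantom parameters — the tests assert both behaviours. Voxels with a
non-positive signal anywhere in the selected window are flagged and set
to zero rather than fitted; negative fitted ADC/fBV values are clamped
to zero (and fBV capped at 1) as non-physical.

Supported b-value schemes are {0, 200, 800} (default) and
{0, 50, 300, 800}; in the latter only 300 and 800 enter the ADC fit, and
the b=50 channel is ignored by construction.

## Region erosion

Histology-to-MRI co-registration and partial-volume effects make region
boundaries unreliable, so masks are eroded before extraction:

1. **Edge slices are removed.** A slice survives only if the region
   occupies both the slice directly above and directly below it
   (occupancy judged on the region itself, not the prostate).
2. **In-plane disk erosion.** Each surviving slice is eroded in 2D with
   a disk of radius `ceil(acquisition in-plane voxel / grid in-plane
   voxel)` grid voxels (≥ 1), using Euclidean distance with ≤
   comparison — i.e. one full acquisition voxel is peeled off
   isotropically in the XY plane of the map grid.

Regions left empty (`empty_after_erosion`) or with a single voxel
(`single_voxel`) are discarded; a `--no-erosion` control configuration
skips step 1–2 and keeps everything with ≥ 2 voxels. A third reason code
(`lost_on_extraction_grid`) covers regions that survive on the map grid
but alias away under nearest-neighbour resampling to the coarser-in-z
T2w grid (2.73 mm → 3 mm); this is an unavoidable property of the grid
pair, not a failure.

## Feature extraction

Per region, 153 features named `<map>_<family>_<Feature>`:

| map | families | count |
|-----|----------|-------|
| ADC | shape + first-order | 26 |
| fBV | shape + first-order | 26 |
| T2w | shape + first-order + GLCM/GLRLM/GLSZM/NGTDM/GLDM | 101 |

Key conventions:

* **T2w normalization**: z-score over the whole image, scaled ×100,
  applied before resampling; bin width 3 for discretization (chosen so
  typical scans land in the 10–100-bin regime; a scan with intensity
  range [6.81, 330.4] spans [2.27, 110.13] bins).
* **Resampling**: images by cubic B-spline (SimpleITK), masks by
  nearest neighbour; targets 0.27×0.27×3 mm (T2w) and 1.03×1.03×2.73 mm
  (ADC/fBV). The phantom emits volumes natively on these grids, so the
  resampling step is the identity in the default pipeline (it is tested
  separately).
* **Discretization**: fixed bin width on an absolute grid,
  `level(x) = floor(x/w) − floor(min/w) + 1`, so bin edges sit on
  multiples of the width rather than being anchored at the region
  minimum.
* **ADC units**: maps are carried in mm²/s; features are reported in
  10⁻³ mm²/s so that coefficients and cutoffs are on the conventional
  printed scale. The default ADC/fBV bin width (25) applied to those
  stored values collapses typical prostate regions into a single bin,
  making ADC/fBV first-order Entropy 0 and Uniformity 1; this mirrors
  the default-bin-width behaviour of the standard extraction framework
  for maps in small units and affects only those two features.
* **Texture**: 3D, 26-connectivity, distance 1, 13 unique angles.
  GLCM (24 features) and GLRLM (16) are computed per angle and the
  feature values averaged; GLSZM (16) uses 26-connected equal-level
  zones; NGTDM (5) uses the mean absolute difference to the
  neighbourhood mean gray tone; GLDM (14) uses dependence threshold
  α = 0 with dependence size defined as 1 (the centre voxel) plus the
  number of in-mask Chebyshev-distance-1 neighbours of equal level, so
  sizes start at 1 and the 1/j² features are always defined. Degenerate
  single-level regions return documented limiting values (GLCM Contrast
  0, Correlation 1, …). Five families total 75 scalars; some extraction
  frameworks advertise slightly larger texture counts, but the five
  standard family definitions used here enumerate exactly 75.
* **Shape** (7): VoxelVolume, SurfaceArea, SurfaceVolumeRatio,
  Sphericity, Maximum3DDiameter, MajorAxisLength, Elongation.
  SurfaceArea defaults to the marching-cubes mesh estimator with a
  0.5-voxel Gaussian pre-smoothing of the binary mask — raw marching
  cubes on a binary lattice systematically inflates a smooth surface's
  area by ~9% (a digitized ball would cap at sphericity ≈ 0.91); with
  the smoothing a radius-10-voxel ball reaches sphericity ≈ 0.96. An
  exposed-face-count estimator (`method="voxel"`) is also provided and
  is exact for axis-aligned cuboids. Maximum3DDiameter is the largest
  pairwise distance between occupied voxel centres (convex-hull
  accelerated); axis lengths are 4·√λ of the physical-coordinate
  covariance eigenvalues, zero-clamped for degenerate flat regions.

## Modeling

The binary target is GP4Crib+ (1) versus GP3/GP4Crib- (0).

* **Split** 60/20/20 into train/validation/test. Overall sizes follow
  largest-remainder apportionment; per-class quotas are apportioned the
  same way and reconciled against the overall sizes (so a 242/176/47
  class table of 465 regions splits 279/93/93 with every class within
  ±1 of its exact share). Within a class, rows are ordered by volume
  and dealt to the split with the lowest fill fraction, balancing the
  volume distribution; the seed randomizes only tie-breaks.
* **mRMR ranking** (MID scheme) on the training rows: step k picks the
  feature maximizing I(f; target) − mean of I(f; s) over already
  selected s, with mutual information estimated on 10 equal-frequency
  bins; at most 20 features; ties break lexicographically. Constant
  features are excluded up front (their MI is 0 by construction).
* **Feature count** k is chosen by stratified threefold CV balanced
  accuracy over the pooled train+validation rows, ties toward smaller
  k. Pooling is deliberate: threefold CV inside a 93-row validation set
  with ~9 positives is not reliably stratifiable; a
  `cv_pool="validation_only"` switch restores the narrower variant.
* **Classifier**: L2-penalized logistic regression, C=1, max_iter=10,
  class_weight='balanced' (n_total/(2·n_class)), fitted intercept,
  tolerance 1e-4 (scikit-learn). Hitting the iteration cap is recorded,
  not fatal. The final model is fitted on train+validation pooled and
  applied to the untouched test split. An exhaustive grid search over
  C ∈ {0.001…10}, penalty ∈ {l1, l2, elasticnet}, max_iter ∈ {10…500},
  three class weightings and the intercept flag is available
  (`tune_hyperparameters`, ties resolve toward the default
  configuration); the default pipeline uses the fixed configuration
  above, which is also the configuration such a search prefers on
  well-separated data.
* **Prediction**: P = 1/(1+e^−(w0+Σ wi·xi)), label = [P ≥ 0.5]. For a
  single-feature model the decision boundary −w0/w1 is the feature
  value with P exactly 0.5.

## Evaluation

Balanced accuracy (mean of sensitivity and specificity), ROC AUC
(normalized Mann–Whitney U, ties half), PR AUC (average precision), each
with a 95% percentile bootstrap CI over 1000 region resamples.
Replicates that lose a class are redrawn (and counted) so exactly 1000
enter every interval. Significance against the all-negative baseline
(balanced accuracy exactly 0.5) is the one-sided exceedance probability:
the fraction of replicates whose balanced-accuracy delta over 0.5 is
≤ 0.

## Phantom cohort: what it emulates, and what it does not

Each case is an ellipsoidal prostate (~36 cc) on a 64×64×20 DWI grid
(1.03×1.03×2.73 mm) with a co-registered T2w volume at 0.27×0.27×3 mm.
One to three non-overlapping ellipsoidal tumour regions per case carry
labels drawn at 52/38/10% (GP3/GP4Crib-/GP4Crib+); region volumes are
log-normal with per-label medians 0.16/0.20/0.08 cc (log-sd 1.0, clipped
to 0.006–3 cc). Voxelwise D is Gaussian per tissue class — 0.85, 1.05,
1.20, 1.60 ×10⁻³ mm²/s (sd 0.10×10⁻³) for GP4Crib+/GP4Crib-/GP3/benign —
encoding the qualitative finding that cribriform tissue diffuses least;
these are synthetic stand-ins, not calibrated clinical values, since no
quantitative per-subpattern ADC distributions are available. f is
Gaussian around 0.06–0.10, D* = 20×10⁻³ mm²/s, S0 = 100 inside the
prostate. DWI channels are forward IVIM evaluations corrupted by Rician
noise (|signal + complex Gaussian|, σ = 2, i.e. b=0 SNR 50); σ = 0 gives
bit-exact noiseless data for identifiability tests. T2w intensities are
Gaussian per tissue with mildly different means, so T2w texture features
are plausible but carry far less class signal than ADC — by design, the
pipeline should discover the ADC contrast.

Not emulated: prostate zonal anatomy, histology deformation,
co-registration error, scanner artifacts beyond Rician noise, and any
quantitative calibration of class contrasts. Consequently, passing
end-to-end tests demonstrates that the pipeline recovers a planted
diffusion contrast under realistic data structure and noise — not that
the clinical effect size is reproduced. Phantom separability is
intentionally stronger than clinical reality, so absolute test metrics
of phantom runs exceed what the corresponding clinical analysis reports.

Because the per-label volume medians are generator targets (pre-erosion),
and a 0.08 cc ellipsoid spans only ~2–3 slices of a 2.73 mm grid, the
edge-slice rule plus disk erosion removes roughly half of all synthetic
regions — cribriform ones hardest — a deliberately harsher attrition
than clinical cohorts show, and the reason pipeline-level analyses
default to ~150 cases (~300 generated regions).

## Problem sizes and numerical choices

Analysis drivers and end-to-end tests default to 150-case cohorts
(~300 generated regions, ~150 surviving), chosen to keep a 20-seed
recovery experiment comfortably reproducible on a laptop-class machine
while leaving ≥ 5 surviving cribriform regions in most draws — enough
for stratified threefold CV. Rare cohort draws that leave fewer than
three surviving positives raise a stratification error; the acceptance
script regenerates with the next derived seed in that event and reports
the seed used. Bootstrap size is 1000 everywhere; derived seeds
(phantom, split, CV, bootstrap) are offsets of the master seed and are
recorded in the run log. All randomness flows through
`numpy.random.Generator`; reruns of any stage with the same config are
bit-identical.

## Known limitations

* The GLDM dependence-size and NGTDM neighbourhood conventions follow
  the definitions documented above; other implementations differ in
  whether the centre voxel counts and how empty gray levels are
  indexed, so cross-package feature values need not match exactly.
* Erosion assumes axis-aligned grids with the z-axis as the slice
  direction; oblique acquisitions are out of scope.
* fBV is the intercept-deficit estimator; no D* map is produced and no
  full biexponential fit is attempted.
* The mesh surface-area estimator trades a small bias on sharp-cornered
  shapes (cuboid corners get rounded) for accuracy on smooth ones; the
  face-count estimator makes the opposite trade. Feature vectors use
  the mesh estimator throughout.
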