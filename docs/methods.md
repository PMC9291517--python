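# Methods

`rvshape` reimplements a complete population-level shape analysis of the
right ventricle (RV) in tricuspid regurgitation (TR): binary
segmentation volumes are turned into signed distance transforms, a
particle-based shape model places ordered correspondence landmarks on
every surface, PCA defines a low-dimensional shape space, a classifier
separates TR from comorbid controls on the PCA loadings, and group
differences are localized with per-point Hotelling T² maps and a linear
discrimination-of-variation (LDV) shape score. Because clinical
segmentations cannot be redistributed, the package ships a synthetic
cohort generator whose ground truth makes every stage testable.

## Synthetic cohort generator

Every subject is a star-shaped surface `r(θ, φ)` over one shared
spherical parameter grid (θ = colatitude, base pole at θ = 0, apex pole
at θ = π; φ = 0 faces the free wall). The template is a half-ellipsoid
(semi-axes 22 × 16 × 35 mm) with a crescent-shaped cross-section (a
smooth septal indentation of relative depth 0.25), giving an axially
asymmetric geometry for which rigid alignment is well posed and whose
scale matches an adult RV blood pool.

Group-level deformations are smooth Gaussian bumps in parameter space:

| group | deformation | default amplitude |
|---|---|---|
| TR | outward free-wall bulge at (θ=π/2, φ=0), width 0.45 rad | 5 mm |
| TR | apex blunting (outward bump at the apex pole) | 3 mm |
| TR | base widening (outward ring near θ=π/5) | 3 mm |
| comorbid control | inward mid-free-wall displacement | 2 mm |
| control + pHTN | additional mid-cavity narrowing (all φ) | 2.5 mm |

Amplitudes are free parameters of the generator: the clinical source
material reports deformation *directions* and significance maps, not
millimetre effect sizes, so the defaults were chosen once as plausible
and are not tuned. The default composition is the study's: 6 healthy,
27 comorbid controls, 21 TR (54 subjects), with pHTN/CHF/other subgroup
tags assigned 40/40/20% by a deterministic largest-remainder rule.

Subject-level anatomy noise is a smooth random radial field: real
spherical harmonics to degree 4 with iid normal coefficients, scaled via
the addition theorem so the pointwise standard deviation equals
`noise_sd` (default 1 mm) exactly. Consequently the RMS radial
difference between two subjects is √2·`noise_sd`, which the tests check
by Monte Carlo.

`landmark_jitter_sd` (default 0) optionally adds isotropic 3-D jitter to
the ground-truth correspondence points only, emulating landmark
placement error. It exists because purely radial noise makes each
correspondence point vary along a single line across subjects: the
per-point 3×3 covariance is rank-1 and the parametric Hotelling test
becomes strongly conservative. Calibration checks of the Hotelling/FDR
machinery therefore switch jitter on (0.5 mm); with jitter off the tests
assert conservativeness instead. Voxelized masks never carry jitter, so
the default invariant — ground-truth points within half a voxel of the
mask's zero level set — holds whenever jitter is 0.

What the generator does **not** emulate: MRI intensities and
segmentation error, papillary structure, valve anatomy, anisotropic
slice artefacts, and any cardiac motion. Passing tests therefore
demonstrate that the *pipeline machinery* behaves correctly under known
ground truth, not that the clinical effect sizes are reproduced.

## Preprocessing

Masks are linearly interpolated onto an isotropic grid (default 1.5 mm,
between the typical in-plane and through-plane resolutions of short-axis
cine MRI) and thresholded at 0.5 (a majority rule). Alignment is
translation-only by default: all masks are padded onto one common grid
and shifted so their foreground centroids coincide with the grid center.
Because the centroid of a *thresholded* shifted mask is a staircase
function of the sub-voxel offset, the shift is chosen by a direct search
over fractional offsets; when the staircase leaves no offset accurate
enough, the mask is re-sampled through a 2× supersampled grid with
majority pooling, which decorrelates threshold flips and restores a
nearly continuous centroid response. Masks already centred to within
0.22 voxel are left untouched, making preprocessing idempotent.
Principal-axis rotation (sign-disambiguated by third moments) is opt-in;
no size normalization is ever applied, since RV dilation is part of the
disease signal.

Signed distance transforms are exact Euclidean, inside-negative, with
distances measured to the voxel-face interface (a voxel center adjacent
to the boundary has |d| = spacing/2).

## Particle correspondence

M particles (default 512) are optimized on all K surfaces jointly.
The objective blends

* a per-shape **sampling** term: Gaussian-kernel pair repulsion
  `Σᵢ Σⱼ≠ᵢ exp(−|xᵢ−xⱼ|²/2σᵢ²)` with per-particle bandwidths
  `σᵢ = 0.6 × (distance to nearest neighbour)`, clamped below at a
  quarter voxel; and
* a cross-cohort **correspondence** term: `log det` of the regularized
  covariance (ridge 10⁻² mm²) of the stacked K×3M particle matrix,
  evaluated in its K×K dual form.

weighted `α·correspondence + (1−α)·sampling` with α = 0.5 (α = 0 during
the first split level). Two numerical choices matter and were found
necessary rather than assumed. First, the bandwidth factor must stay
below ≈0.7 of the local spacing: a Gaussian pair potential with larger σ
makes particle *merging* energetically favourable and the configuration
collapses. Second, steps are scaled per particle (each particle moves
along its own tangential force, capped at 0.5σᵢ): forces span orders of
magnitude under adaptive bandwidths and a global normalization freezes
every particle except the most crowded one.

Particles grow by splitting 1→2→…→M; children are offset from parents by
half a voxel *within the tangent plane* (a normal offset would project
straight back onto the parent) along a seeded random direction shared
across subjects, which guarantees identical cohorts receive identical
landmarks. Each split level runs three descent sub-stages with
bandwidths refreshed between them; every step is accepted only if it
does not increase the (fixed-bandwidth) objective after reprojection, so
the final sub-stage's objective trace is non-increasing by construction.
The first particle is seeded by marching from the grid center along +z
to the surface crossing — projecting from deep inside the shape sits
near the medial axis and lands on arbitrary walls per subject.

Particles stay on the surface via damped Newton projection
`x ← x − D(x)·∇D/|∇D|` (gradient norm clamped at 0.2) to |D| below half
a voxel, at most 20 iterations.

For fast downstream testing the generator's exact correspondences can
bypass optimization (`attach_ground_truth`): the parameter grid is
subsampled to M points by deterministic farthest-point selection started
at the apex pole, with the same indices for every subject.

## Shape space and statistics

PCA is fit by thin SVD of the centered K×3M matrix on the full cohort
(mirroring the workflow order: model first, split afterwards; a
train-only fit is available via the split utilities). Eigenvalues use
the K−1 normalization; mode signs are fixed so each mode's
largest-magnitude component is positive. The mode count retained for
classification is the smallest explaining 99% of variance.

The classifier stage follows the published recipe: stratified 80/20
split (train size = ⌊0.8·K⌋); Borderline-SMOTE-1 upsampling of the two
minority groups (TR patients and healthy volunteers) to the comorbid
control count, implemented directly — a minority sample is "borderline"
when at least half but not all of its k = 5 nearest neighbours belong to
other classes, and synthetic samples are convex combinations
`x + u·(x′−x)`, u ∈ (0,1), of a borderline sample and a same-class
neighbour; lasso stability selection (1000 random 80% subsets by
default; each fit is `LassoCV` with 3-fold CV, a 100-point path,
tolerance 10⁻⁴, 10⁵ iterations, no intercept — the 0/1 labels are
mean-centred so the interceptless fit is not forced to absorb the class
mean); the four most dominant modes feed a `LogisticRegressionCV`
(lbfgs, ROC-AUC selection, 3-fold). Because ROC-AUC is invariant to the
coefficient scale, CV ties across the regularization grid are common;
the C grid is ordered descending so ties resolve toward the weakest
regularization. Metrics are computed from the confusion counts at
threshold 0.5 by their defining ratios; ROC by threshold sweep, AUC by
the trapezoid rule.

The LDV score of subject i is `(xᵢ − x̄)·d` with `d` the difference of
the two group-mean shape vectors, affinely rescaled so the group means
score −1 (TR-bearing group) and +1. Centring shifts all raw scores by
one constant that the affine map absorbs; it is used for numerical
hygiene only. Per-group Gaussians are moment-matched (population sd).
`overlap_fraction` uses the score-range intersection — the overlap
notion is under-specified in the source analysis, so this is an explicit
documented interpretation.

Hotelling T² maps test each correspondence point's 3-D coordinates with
the two-sample statistic, pooled covariance ridged by 10⁻⁶ mm², p-values
from the exact F(3, n₁+n₂−4) transform, Benjamini–Hochberg FDR across
the M points, significance at adjusted p < 0.05. A permutation variant
(label shuffles of the same statistic) is available for small groups.

## Problem sizes used in tests

The default test run keeps each property at the smallest size that still
exercises it: Hotelling calibration uses 20 subjects × 128 points × 50
shuffles; classifier recovery uses 20 seeded 54-subject cohorts with 50
lasso repeats; stability selection uses 200 repeats (scaled down from
the 1000-repeat default) over 20 runs; optimizer oracles use M = 128 on
a sphere and a 6-subject low-noise cohort. The full-size configuration
(M = 512, 1000 repeats) is the library default.

## Known limitations

* The correspondence optimizer is a simplified reimplementation of
  particle-based shape modeling: no geodesic kernels, no multi-domain
  anatomy, no Procrustes in the loop, and its iteration counts and
  bandwidth rules are this package's own defaults.
* The generator's radial parameterization cannot express folds or
  overhangs; all synthetic anatomy is star-shaped by construction.
* With K ≪ 3M the covariance in the correspondence term is always
  rank-deficient; the ridge makes the log-determinant well defined but
  the absolute objective value is not comparable across K.
* Clinical headline figures (82% recall / 87% precision, 31 modes at
  99% variance, 250/512 significant points, 75%/57% LDV clustering)
  were measured on 54 patient MRIs that are not distributable; nothing
  in this package claims to reproduce those numbers, and its tests
  assert the corresponding *properties* on synthetic cohorts instead.
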