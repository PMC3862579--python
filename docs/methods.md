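# Methods

## Segmentation and contour geometry

Images are expected to show a single bright flower or petal on a dark
background.  Foreground is `red > threshold`; the threshold defaults to
Otsu's method on the red-channel histogram, with a fixed integer accepted
for reproducible batch runs.  Cleanup keeps the largest 8-connected
component (ties broken by the row-major position of the first pixel) and
fills interior holes; no opening/closing is applied so that genuine
marginal serrations are never eroded.  Calibration is `2.54 / dpi` cm per
pixel for scans; camera images without a supplied cm-per-pixel value are
measured in relative units and flagged.

The object boundary is traced along pixel corners (the "crack" boundary),
giving a closed polygon whose shoelace area equals the pixel count exactly.
Raw crack boundaries, however, have L1 staircase length — up to 4/π (27%)
longer than the smooth outline they digitize — so perimeter-type
measurements pass through a Douglas–Peucker simplification with a 1.4 px
tolerance.  This simplification is exact on axis-aligned rectangles (a
10×10 px square keeps its 4 corners and perimeter), and on smooth outlines
it collapses the staircase onto near-tangent chords: measured disc
perimeters land within ~0.15% of 2πr and 30°-rotated squares within ~0.35%.
Area is always taken from the *unsimplified* polygon, because simplification
can bias area by up to ~0.7% on rotated edges while the raw polygon area
(= pixel count) is essentially unbiased for pixel-center rasterization.
Convexity measured on rasters is clamped at 1.0: quantization can push the
hull perimeter of a convex digital object marginally above its smoothed
perimeter, and values above 1 are geometrically impossible.

The moments-equivalent ("best fitting") ellipse is computed from second
central image moments of the filled mask (scikit-image regionprops), or
from closed-form polygon moments for analytic contours.  Convex hulls are
taken over contour vertices; for crack boundaries this equals the pixel
hull.

## Landmarks

Petal outlines are reduced to n = 96 landmarks at arc-length positions
k·L/n measured from the claw base tip, which the scan protocol places as
the lowest point of the image (maximal row; ties go to the leftmost pixel).
Anchoring translates the base tip to (0, 0) and flips y so the blade points
to positive y; the traversal direction is disambiguated so the first
landmark step has non-negative x.  No Procrustes rotation or scaling is
applied: petal size is biologically meaningful here and is deliberately
left in the coordinates so the shape model can capture it.  Landmark
positions are independent of the contour's starting vertex and stable to
within ~1e-12 of the object diameter under 2× contour densification.

## Shape model

PCA is performed on the covariance (not correlation) of the flattened
anchored landmark vectors, in cm.  Eigenvector signs are fixed by making
each component's largest-magnitude loading positive, so models are
bit-reproducible across runs.  All nonzero-variance components are kept by
default; cumulative variance fractions are reported so statements of the
form "four components capture X% of the variation" can be evaluated on any
dataset.  Per-cultivar summaries in a chosen component plane use the score
centroid and axis-aligned 1-SD ellipse.  Standard and spray-type
subpopulations are fitted as independent models by passing each subset
separately.

## Quantitative genetics

For clonal material, among- vs within-genotype mean squares from one-way
ANOVA give `V_E = MS_W`, `V_G = (MS_A − MS_W)/n̄` with `n̄` the *average*
number of samples per genotype used as a real number (designs are
unbalanced in practice).  Negative method-of-moments `V_G` is clamped to 0
and flagged.  `H² = V_G/(V_G + V_E)` is invariant to affine trait
rescaling; `CV_G = 100·√V_G/x̄` is not (and is meaningless after
z-scoring, so pooled standardized estimates report it as missing).
Genetic covariance uses the cross-product analogue
`cov_G = (MCP_A − MCP_W)/n̄`, keeping `r_G = cov_G/√(V_G1·V_G2)` on the
same estimator scale as the variance components; the simpler covariance of
genotype means is available as an alternative method.  `r_G` is clamped to
[−1, 1] and reported missing when either `V_G` is zero.  Reaction norms
across two environments (autumn/winter, coded 0/1) reduce to intercept =
autumn mean and slope = winter − autumn mean per genotype, computed on data
standardized within subpopulation; single-environment genotypes are
excluded and listed.

## Statistics

Candidate trait distributions (normal, log-normal, logistic) are fitted by
maximum likelihood (log-normal with location fixed at 0, skipped for
non-positive data) and ranked by the one-sample Kolmogorov–Smirnov
statistic.  Since parameters are estimated from the same sample, KS
p-values carry Lilliefors-type bias and are labeled approximate; the
family *ranking* is the supported inference.  Group comparisons: t-test /
ANOVA-F with a protected Fisher LSD follow-up (pairwise t on the pooled
within-group MSE, only after a significant omnibus F) in parametric mode;
Mann–Whitney U / Kruskal–Wallis with medians in non-parametric mode.

## Clustering and heatmaps

Cultivar distances are Euclidean on the column-z-scored cultivar ×
parameter mean matrix (z-scoring prevents cm² areas from dominating
dimensionless factors); parameter distances use the columns of the same
matrix.  Missing cells are imputed by column mean and flagged; constant
columns are dropped.  Neighbor joining is the standard Saitou–Nei
agglomeration with two determinism guarantees: Q-criterion ties (within
1e-12) are broken toward the lexicographically smallest pair of cluster
labels (a cluster is labeled by its smallest leaf), and children are stored
in label order, so the displayed leaf order depends only on the distances
and labels, never on input row order.  Negative branch lengths are clamped
to zero and counted on the returned tree.  Heatmap rows/columns follow a
midpoint-rooted left-to-right leaf traversal; each column is rescaled to
[0, 1] and drawn red (low) to white (high).

## Synthetic fixtures

`make_petal_polygon` joins a pointed-claw trapezoid to a blade whose
half-width follows a normalized beta-like profile `v^a (1−v)^b` along the
blade axis; the (a, b) exponents give obovate, reniform and fan blade
vocabularies.  Serration adds `serration_count` sinusoidal teeth of
amplitude `serration_amplitude` (cm) radially about the blade center,
tapered by a smoothstep so only the distal half of the blade margin is
toothed — radial displacement cannot self-intersect while the radius stays
positive, and validity is checked.  An `asymmetry_skew` shear breaks the
mirror symmetry.  Ground truth (area, perimeter, hull metrics, solidity,
convexity, ellipse axes, claw-tip position) is computed with shapely and
closed-form polygon moments — a code path disjoint from the raster
measurement pipeline, so round-trip tests compare two independent
implementations.

`make_flower_rosette` unions rotated copies of a petal (seeded angular and
radial jitter emulating irregular petal arrangement) and then applies a
morphological closing of radius 0.03 cm.  Without it, near-tangent petal
edges leave crevices of arbitrarily small width that no raster could
resolve and no photographed corolla would show; the ground truth describes
the regularized polygon exactly.  Rasterization marks a pixel foreground
iff its center lies strictly inside the polygon (no antialiasing) and
returns that same fill as the ground-truth mask.

`simulate_clonal_population` draws `value(g,r,e) = μ + G_g +
shift(e)·δ_g + ε` with multivariate-normal genotype effects (given SDs and
genetic correlation matrix, PSD-checked), independent residuals, and an
optional per-genotype environmental sensitivity δ_g ~ N(1, 0.3) for
reaction-norm studies.  Defaults (55 genotypes × 5 replicates; area and
convexity traits with means 33 cm²/0.80, genetic SDs 6.2/0.137 and
residual SDs 3.6/0.062) emulate a standard-carnation-scale flower
experiment with true H² ≈ 0.75/0.83 and genetic CVs near 19%/17%.
`make_latent_factor_petals` provides the linear ground truth for PCA
recovery: a mean petal plus four Gram–Schmidt-orthonormalized
parameter-sensitivity directions (blade width, blade length, claw length,
shear) scaled by distinct factor SDs (1.0, 0.7, 0.45, 0.3 cm) plus small
isotropic noise (0.01 cm).  Petals generated by sweeping raw spec
parameters instead have non-orthogonal, arc-length-coupled landmark
effects, and PCA mixes such factors — a property of the map, not a defect
of the model.

## What the synthetic tests do and do not show

The fixtures have clean contrast, exact polygon boundaries, a single object
per frame and Gaussian trait noise.  Passing tests therefore demonstrate
the correctness of the geometry, estimators and algorithms — not robustness
to shadows, specular highlights, touching objects, background texture or
non-Gaussian trait distributions, which real flower photographs contain.
Absolute descriptor values on real images additionally depend on the
unknown camera scale for uncalibrated views.

## Problem sizes and numerical choices

Validation runs use object diameters of ≥ 300 px (resolution chosen per
shape), 50 random shapes for raster-vs-oracle comparison, 500-seed
Monte-Carlo recovery for H² at 60 genotypes × 6 replicates, 200-seed
recovery for r_G at 200 genotypes × 8 replicates, 100 random additive
trees for neighbor joining, and 100 simulations of 12 cultivar pairs for
replicate clustering; all fit in well under a minute of CPU.  Tolerances:
contour simplification 1.4 px; distance-matrix symmetry 1e-10; NJ
Q-criterion tie window 1e-12; eigendecomposition via `numpy.linalg.eigh`
on the explicit covariance (192×192), with eigenvalues clipped at 0.

## Known limitations

Multi-object scenes require pre-cropping; there is no blade/claw boundary
detection, so serration localization relies on the generator's taper rather
than measured tooth positions; KS-based family selection between nearly
nested families (normal vs logistic, normal vs low-σ log-normal) is
intrinsically noisy even at n = 2000 (the logistic wins on truly normal
data in roughly 5% of samples); r_G estimates at small designs
(≈ 55 genotypes × 5 replicates) carry sampling SDs of ~0.2 and should be
averaged or interval-reported; and the NJ heatmap documents its own
distance and scaling choices rather than claiming equivalence to any
particular legacy R plotting package.
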