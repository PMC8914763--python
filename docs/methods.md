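# Methods

This note records the model behind `thermasym`, the choices made where the
design was genuinely open, and what the synthetic phantoms do and do not
establish about real clinical thermograms.

## Physical picture and assumptions

Skin surface temperature maps perfusion. A bilaterally symmetric structure
(the face, the open mouth cavity) imaged frontally should produce a
left–right symmetric temperature field up to ~0.2 °C physiological
fluctuation; a unilateral lesion with increased perfusion adds a localized
warm anomaly on one side. The pipeline assumes:

- frontal pose, a single face filling most of the frame, against a
  background several °C cooler than skin;
- the mouth cavity, when open, is the warmest structure in its view;
- abnormality expresses as *unilateral* warming. Bilateral or diffuse
  changes cancel in left-minus-right statistics and are invisible here.

## Pipeline stages and numerical choices

**Edge detection.** Unnormalized 3 × 3 Prewitt convolution, border handled
by edge replication (zero padding would manufacture a spurious frame edge).
The edge threshold is *relative*: magnitude ≥ `edge_threshold_frac` (default
0.2) × the ROI-maximum magnitude. A relative cut is invariant to constant
temperature offsets and to any uniform rescaling of the kernel, so the edge
map does not depend on the Prewitt normalization convention. Face-view ROI:
pixels ≥ 27 °C (body surface); mouth-view ROI: pixels ≥ 34.5 °C (cavity).
The mouth floor sits between the warmest skin (~33 °C + noise) and the
coolest cavity interior (~35 °C) of the phantoms and of typical clinical
values; both floors are configurable.

**Convex hull.** Qhull via `scipy.spatial.ConvexHull`; vertices stored
counterclockwise in the (x = col, y = row) plane starting from the
lexicographically smallest (row, col) vertex. Points interior to an edge are
not vertices. Fewer than 3 distinct points, or an all-collinear set, is a
degeneracy error.

**Ellipse fit.** The direct least-squares conic fit with the ellipse
constraint 4AC − B² = 1, in the numerically stable split-matrix form
(quadratic/linear blocks, reduced 3 × 3 eigenproblem). It is unique and
non-iterative — no initialization to document, no convergence failures.
Points are mean-centered before fitting for conditioning; noiseless points
on a true ellipse are recovered to ~1e-10 relative error. An aspect ratio
below 1.02 raises an "ambiguous axis" warning and flags the result: a
near-circle has no meaningful major axis. The RMS algebraic residual (with
unit-norm quadratic coefficients) is attached to the result as a fit
diagnostic.

**Axis and split.** The symmetry axis is the major axis through the fitted
center. Pixels strictly inside the hull polygon are assigned to a side by
the sign of the 2-D cross product with the axis direction; exactly-on-axis
pixels (cross product 0) are discarded rather than double-counted, which
keeps the side sets disjoint — with float axis parameters this affects at
most a one-pixel-wide line. Side labels are geometric, not anatomical: every
downstream feature is symmetric under a side swap, so anatomical left/right
never needs to be resolved.

**Features.** Absolute differences of side statistics (mean, max, MAD), plus
the exceedance counts: on the warmer side (larger mean), the number of
pixels strictly hotter than the cooler side's maximum plus the asymmetry
threshold (0.4 °C by default — the same threshold throughout the package).
Averaging over `n_estimates = 5` contour estimates, with hull vertices
perturbed by independent uniform ±1 px offsets before the ellipse fit in
estimates 2..5, models the operator variability of manually tracing a
contour; the unperturbed hull still bounds the analysis field, so jitter
moves the *axis*, not the region. Averaged counts are therefore fractional.
A failed estimate (degenerate split) is discarded; only total failure is an
error.

**Classifier and evaluation.** 1-NN with Euclidean distance; distance ties
broken by the lowest training-row index (deterministic). Features are
z-scored with training-fold statistics by default: the raw count n_m can
reach ~50 px while the temperature features live near 0.1 °C, and without
standardization a single feature would carry essentially all of the
distance. A zero-variance training feature gets unit scale (it then
contributes nothing). Evaluation pools confusion counts over
`n_repeats = 12` random class-balanced splits (12 training patients per
class) rather than averaging per-repeat metrics — pooling keeps the counts
integral and the report single-valued. The ROC score is the signed
nearest-neighbor margin d(nearest NT) − d(nearest T), which reduces to the
1-NN label at threshold 0; AUC is the trapezoidal area, identical to the
tie-corrected Mann–Whitney statistic. Group separation per feature uses
Welch's t-test (group SDs differ by an order of magnitude, so pooled
variance is inappropriate).

## The phantom generator

Phantoms emulate the stated acquisition conditions: 240 × 320 px grids, a
~22 °C uniform background, an elliptical face (default semi-axes 90 × 65 px)
at 33 °C center temperature with a 1.5 °C quadratic radial falloff,
i.i.d. Gaussian sensor noise of SD 0.06 °C (the camera's thermal
sensitivity), and in the mouth view a smaller coaxial ellipse at 35.5 °C
representing the open cavity. Lesions are isotropic Gaussian bumps (peak
amplitude at the center, σ = radius/2) added to face-interior pixels,
strictly off-axis; the standard abnormal case uses a 1.0 °C peak and 8 px
radius, roughly a 1–2 cm warm anomaly at this pixel scale. Cohorts derive
per-member seeds counter-style from the cohort seed, so members are
independent but the cohort is exactly reproducible.

Study sizes follow the clinical protocol being modeled: cohorts of 23 + 23,
training splits of 12 per class, 12 repetitions, five contour estimates per
patient. The axis-recovery experiment uses 100 phantoms with tilts uniform
in ±15°; at the default noise level the recovered axis is within 2° of
truth in ≥ 95% of trials (typically all 100, median error ~0.02°).

**What the phantoms do not show.** They are deliberately minimal: no hair,
glasses, scars, pose rotation out of plane, asymmetric adipose tissue or
vascular texture — all known confounders of clinical facial thermography.
The face boundary is a clean ellipse, which is exactly the geometry the
hull-plus-ellipse axis estimator assumes; real jaw/neck contours will
degrade axis accuracy in ways these tests cannot measure. Passing the
phantom suite therefore validates the *computational* chain (geometry,
features, classifier, protocol), not clinical performance. On phantoms, a
1.0 °C lesion is separable essentially perfectly; the interesting regime is
near the noise floor (≈ 0.1–0.2 °C peak amplitude), where performance falls
from ~0.9 accuracy to chance.

## Degenerate inputs and edge cases

- Constant images have no edges (explicit error, not an empty result).
- Asymmetry exactly equal to the 0.4 °C threshold is *normal*: "not higher
  than" is the normal-side criterion, so the rule is a strict inequality.
- A test identical to a training vector is classified as that vector's
  class (distance 0 wins).
- Metrics with a zero denominator raise an error naming the metric rather
  than returning NaN.
- Only k = 1 is implemented; the config validates k as odd and the
  classifier rejects k > 1 explicitly.

## Known limitations

- The mouth-cavity contour is isolated by a fixed warm-pixel floor; a
  closed-mouth or cool-cavity image yields no ROI and the patient is
  excluded (logged) rather than mis-segmented.
- The pooled-repeats convention re-tests each patient in every repetition
  it is held out, so pooled test outcomes are correlated across repeats;
  chance-level metrics on small cohorts scatter roughly ±0.1 around 0.5.
- Axis estimation assumes one dominant convex warm region per view;
  multiple faces or strong occlusions are out of scope.
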