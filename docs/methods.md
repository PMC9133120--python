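# Methods

This note documents the models, numerical choices, and limitations behind
`atlasmorph`, in the order the pipeline runs.

## Coordinate model

Grids are axis-aligned: a volume is `(lengths, steps, starts)` with 0-based
voxel indices addressing voxel centers, `world = start + index * step` per
axis, all world units in millimetres. Arrays are stored in (x, y, z) index
order. Headers with non-identity direction matrices are rejected rather
than silently reoriented — the pipeline's data model assumes axis-aligned
reconstructions, and rejecting keeps the coordinate semantics unambiguous.
MINC volumes are not read; NIfTI-1 and NRRD cover the supported inputs, and
the ASCII MNI `.tag` dialect covers landmarks (header lines through
`Points =` preserved verbatim on round-trip; per-row quoted labels
optional, since the dialect in the wild is inconsistent about them).

Transforms are stored in the atlas→specimen direction and tagged with it
explicitly. A composite applies its stages in list order to points; volume
resampling onto a specimen grid goes through the inverted composite. This
single stated convention replaces the filename-suffix conventions
(`_inverted_grid`) that otherwise encode direction implicitly.

## Phantom generator

The synthetic population stands in for stained micro-CT heads. The atlas is
a set of nested ellipsoids ("head", "brain", "snout") with intensities in
[0, 1], smoothed edges (0.8 voxel Gaussian) so the similarity metric has
gradients, landmarks at component surface poles, and one positive integer
segmentation label per component. The default grid is 48³ voxels at 0.1 mm
(a deliberately desk-scale stand-in; real atlas grids run to hundreds of
voxels per axis at 0.007–0.054 mm).

Each specimen is the atlas pushed through a known transform
`T(x) = R(x + u(x))`: a random rigid `R` (rotations up to ±6°, translations
up to ±0.2 mm about the grid center) composed with a smooth random warp `u`
built as Gaussian-filtered white noise (correlation length 1.2 mm) scaled
to a 0.4 mm peak amplitude, with the amplitude halved until
min det J > 0.05 so the warp is guaranteed diffeomorphic. On top of the
geometry: a multiplicative smooth bias field (±15%), an additive background
offset (optional), and i.i.d. Gaussian noise (sd 0.02). These default
magnitudes are chosen once to emulate the acquisition nuisances of real
scans (mis-orientation, staining gradients, detector noise) at sizes a
48³ grid can resolve. Landmarks are mapped through `T` exactly — the
ground truth is analytic — while the image and segmentation are pulled
back through the numerically inverted `T` (tolerance 1e−3 mm).

What the phantoms do *not* emulate: realistic anatomy and texture, partial
volume effects at real-scan resolution, stage-dependent anatomy, staining
chemistry, or non-diffeomorphic acquisition artifacts. Passing the phantom
suite therefore demonstrates the pipeline's internal consistency and its
recovery of known geometric perturbations, not its accuracy on real scans.

## Preprocessing

Min-max normalization maps intensities exactly onto [0, 1]. Background
thresholding estimates a lower anatomical density bound by Otsu's method
when no explicit threshold is given (deterministic and parameter-free;
overridable), dilates the above-threshold mask with a ball of radius
2 voxels (isotropic, radius exposed), and zeroes everything outside.
This step matters more than it looks: the registration metric is the
*uncentered* NCC, so a nonzero background offset contributes a large
constant term to every inner product and blinds the metric to anatomy.
Normalize-then-threshold is the standard chain the pipeline applies before
any registration.

Bias correction is a homomorphic Gaussian-lowpass divide (default scale
2 mm) rescaled to preserve the mean — a deliberately simple
inhomogeneity-reduction step, not a full B-spline/histogram-sharpening
N3 implementation; it removes the slowly-varying gain that perturbs NCC
and nothing else.

Rigid initialization from paired landmarks uses the closed-form SVD
(Kabsch) orthogonal-Procrustes solution with determinant correction, so
reflections are never produced; collinear configurations are rejected
because they leave a rotation axis unconstrained.

## Registration

The affine stage optimizes 12 world-space parameters (translation,
rotation, log-scale, shear, composed about the fixed-image center) with
Powell's direction-set method — chosen because the uncentered NCC has no
cheap analytic gradient in the affine parameters and 12 dimensions is
comfortably within derivative-free range. Per-parameter scales (2 voxel
steps for translations, 0.02 for angles/log-scales/shears) condition the
search. A 4-level (default; 3 at 48³ desk scale) coarse-to-fine pyramid
with 2× downsampling and Gaussian anti-aliasing provides capture range;
translation is initialized from the center-of-mass offset.

The non-linear stage is a demons-style greedy ascent on the *exact*
gradient of the global uncentered NCC with respect to the warped image,
times the warped image's spatial gradient, Gaussian-smoothed (fluid
regularization, default 0.2 mm) and accumulated compositively:
`u_new(x) = δ(x) + u(x + δ(x))`. Each update is scaled so the largest
per-iteration motion is one voxel step (times a step factor) and is
rejected — with step halving — if it would fold the field
(min det J ≤ 0). Iterations stop on an NCC stall (4 non-improving steps)
or an iteration cap; the best-NCC field is kept. This is an intentional
simplification of geodesic/symmetric diffeomorphic optimizers: it
preserves the interface, the NCC objective, and diffeomorphy, which is
what the downstream propagation and QC depend on.

Both stages are deterministic: no randomness anywhere, so a registration
re-run is bit-identical.

Atlas construction performs all n·(n−1) ordered pairwise affine
registrations, averages each specimen's transforms in matrix-log space
(`expm(mean(logm(M_i)))` — element-wise averaging of rotations is not a
valid transform mean), resamples through the averaged affines and takes
the voxel-wise arithmetic mean as the affine template, then runs four
non-linear iterations against the evolving template at increasing pyramid
depth, re-averaging after each.

## Propagation

Field inversion solves `v(x) = −u(x + v(x))` by damped fixed-point
iteration. The damping factor is `1/(1 + L)` with `L` the maximum
displacement-gradient norm of the field: plain iteration diverges once
‖∇u‖ approaches 1, which registration-grade fields routinely do locally,
while the damped scheme stays contractive for any fold-free field.
Defaults: tolerance 0.01 mm, 50 iterations (100 for segmentation
propagation, whose composite inversion is the hardest case).

Landmarks propagate through the forward composite; points landing outside
the specimen grid are kept and flagged, never dropped, so the shape-QC
screens see them. Segmentations propagate by nearest-neighbour resampling
through the inverted composite, guaranteeing output labels are a subset of
the input labels plus background.

## Morphometrics

GPA centers, optionally scales to unit centroid size, and rotates each
configuration to the evolving mean until the mean moves less than 1e−10
(coordinate-wise), never using reflections. Procrustes distance is the
root summed squared difference between unit-size, optimally rotated
configurations.

The 3-D TPS uses kernel `U(r) = r`. That kernel is conditionally
*negative* definite, so the bending energy of a fitted spline is
`−wᵀKw` (clipped at zero against rounding) and the bending-energy matrix
is the negated upper-left block of `L⁻¹`; both are verified positive
semidefinite in the tests. A consequence worth knowing: a single displaced
control point induces a small affine trend in the fitted map, so only the
*non-affine* component of its influence decays with distance.

Semi-landmark patches are filled either bilinearly from four corner
anchors (no template) or by TPS transport of a template's dense points
through the sparse-anchor correspondence. Sliding moves curve points along
central-difference chain tangents and surface points within tangent planes
estimated by local PCA of the 8 nearest scheme neighbours; the
bending-energy mode solves the exactly quadratic problem in the sliding
parameters in closed form per specimen, the Procrustes mode projects the
residual-to-mean onto the tangent subspace. Updates are accepted only if
the objective does not increase, and the mean is re-estimated between
iterations.

Shape PCA decomposes deviations from the mean, by default after orthogonal
projection onto the tangent space at the mean (the component along the
vectorized mean is removed); the flag is recorded in the result. Projection
of a second dataset onto a reference PC basis uses non-centered deviations
from the *reference* mean ("uncentered scores"), and the per-PC Pearson
correlation of the two score vectors is reported. Allometry is multivariate
least squares of aligned coordinates on log centroid size, with R² as the
explained fraction of total Procrustes variance.

## Quality control

The `overall` RMSE mode evaluates the landmark-error formula exactly as
defined (sum over landmarks of per-landmark mean squared deviations, no
1/p inside the root); because a per-specimen error is also needed for the
quality regression, a `specimen` mode (root mean over landmarks) and its
`landmark` transpose are provided explicitly rather than silently
substituting one for the other.

The quality model is OLS of per-specimen RMSE on cc, cc², cc³, with R²
reported and a default review threshold of cc = 0.90. Outlier screening
computes each specimen's Procrustes distance to the mean shape and flags
those beyond Q3 + 1.5·IQR, with quartiles by linear interpolation of order
statistics (the common "type 7" rule); when IQR = 0, only distances
strictly above Q3 flag. PC-extreme screening morphs the mean to the
observed minimum and maximum of a chosen PC and ranks specimens by |score|.
All screens write review lists; removal is never automatic.

## Landmark-correction network

The optimizer is a residual MLP: `corrected = input + scale * f(norm(input))`
with two tanh hidden layers (default width 64), trained by full-batch
gradient descent with momentum (lr 3e−3, momentum 0.9, up to 2000 epochs)
and early stopping on a held-out split (patience 200). Features are the
flattened coordinates of the optimizable landmark subset after the manual
shapes are GPA-aligned and each automated configuration is superimposed on
its manual counterpart; normalization statistics come from the training
split only. The output layer is zero-initialized, so the untrained network
is exactly the identity — on error-free data it provably stays there, and
on biased data training only ever moves it away from identity to the
extent the data demand. Loss is mean squared coordinate error in the
shared frame, which equals squared Procrustes-aligned RMSE. Training is
deterministic per seed; models serialize to self-describing JSON
(layer sizes, weights, normalization, training metadata).

On the synthetic systematic-bias task (400 specimens, 0.3 mm smooth bias,
0.05 mm noise) the held-out RMSE ratio after/before correction sits near
the linear-oracle floor for that generator; the test criterion (< 0.6) is
met with margin across training seeds.

## Voxel-based morphometry

Jacobian determinants of `x ↦ x + u(x)` use central differences at
interior voxels and one-sided differences at boundaries (flagged in the
map's metadata), with world-step spacing. Negative determinants are
reported as a fraction, never clipped. Composite-form determinants
multiply by the determinant of the affine's linear block.

Voxel-wise tests fit an OLS per masked voxel (intercept + group indicators
+ optional covariates): two groups give a two-sided t, more give an F for
the group factor. The default response is log det J, treating expansion
and shrinkage symmetrically; voxels with numerically zero residual
variance are assigned p = 1 rather than spurious significance. FDR control
is Benjamini–Hochberg across masked voxels. Both the raw-p and q maps are
returned, plus per-group variance maps.

## Problem sizes

The shipped defaults and tests run at phantom scale: 48³ grids (32³ for
the atlas-construction tests), populations of 8–12, optimizer sets of
400 configurations, 100-replicate FDR simulations on 200-voxel masks.
These sizes were chosen so the full suite and the acceptance script
complete in minutes on a single CPU while still exercising every stage at
meaningful amplitude; every algorithm is size-agnostic and takes its grid
and population from its inputs.

## Known limitations

- The non-linear registration is a greedy NCC-demons stand-in, not a
  geodesic/symmetric method; it has no theoretical inverse-consistency
  guarantee (diffeomorphy is enforced per step, symmetry is not).
- Bias correction removes smooth multiplicative gain only.
- The phantom's realism limits what green tests prove about real scans
  (see above); small structures near the voxel scale (the phantom "snout")
  propagate with Dice around 0.85–0.9 purely from resampling
  discretization.
- Sliding semi-landmarks against the sample mean assumes the mean is a
  sensible target; no relaxation against a reference template is provided.
- Voxel-wise inference offers BH-FDR only; random-field or permutation
  cluster inference is out of scope.
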