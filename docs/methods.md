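# Methods

This note documents the models behind drrforge, the defaults and why they
were chosen, the numerical choices, and what the synthetic phantom does and
does not establish about real data.

## Coordinate conventions

Volumes are `(z, y, x)` arrays: z cranio-caudal, y antero-posterior, x
left-right. The PA projection always integrates along y, so a parallel DRR of
a `(Z, Y, X)` volume has shape `(Z, X)`. Voxel indices are 0-based and refer
to voxel centers; the world position of voxel `(i, j, k)` is
`origin + index·spacing` (mm), and the bounding box extends half a voxel
beyond the outermost centers. HU values are floored at −1024 (scanner air
convention), which also guarantees non-negative attenuation downstream.

## Attenuation model

A single effective energy is assumed. The HU→μ relation is the standard CT
definition, `μ(HU) = μ_water·(1 + HU/1000)` clamped at zero, with
`μ_water = 0.02 mm⁻¹` (water at roughly 60–70 keV). The point-source
technique additionally decomposes voxels into three classes by HU threshold —
air below −500, bone above +300, soft tissue between — zeroing the air class
and scaling the bone class by `bone_factor = 2.0`. This mimics the
class-specific weighting of material-decomposition DRR pipelines at desk
scale; a polyenergetic spectrum with per-keV attenuation tables is
deliberately out of scope. All parameters are exposed on `AttenuationModel`.

Consequence worth knowing: with the default models the point-source and
parallel Beer–Lambert projections differ *by construction* (bone is twice as
attenuating, sub-−500-HU lung tissue attenuates nothing in the decomposed
model). The parallel-limit equivalence below is therefore always checked
under a neutral model (`bone_factor = 1`, thresholds outside the HU range)
that makes both projectors share one μ field — the equivalence is a statement
about geometry, not about the attenuation model.

## Parallel projectors

`beer_lambert_project` accumulates `L(z,x) = Σ_y μ(HU)·dy` directly on the
voxel grid — each voxel of a column contributes exactly once with path length
`dy` — and returns either the line integral or `I = I₀·e^{−L}`.

`sorted_weighted_project` sorts each column ascending, assigns normalized
positions `x_i = i/(n−1)` (a single-sample ray gets `x = 1`, full weight),
and returns the weight-normalized convex combination `Σ w_i v_i / Σ w_i`.
Normalizing by `Σ w_i` is essential: without it the output would scale with
ray length, making DRR brightness depend on patient thickness. Equal values
may receive different weights depending on their (stable-sorted) order, but
since the values are equal the output is unaffected. All-zero weight vectors
raise rather than return 0/0.

The SoftMip profile is implemented on the normalized position scale with
breakpoint `b = 0.5`: `f(x) = 0.5x` below the breakpoint, rising linearly to
`f(1) = 1` above it (for `b = 0.5` that is `1.5x − 0.5`). On this scale the
two branches agree at the breakpoint (0.25); on a 0–100 position scale the
same coefficients would be discontinuous there, so the normalized reading is
the only self-consistent one and is the one used throughout. For other
breakpoints the upper branch keeps `f(1) = 1` and continuity at `b`.

The wedge profile of the slab-based technique was published only as
"optimised visually"; the default here is the identity ramp `f(x) = x`, with
`onset`/`plateau` parameters to shape it. This is a documented stand-in, not
a reconstruction of the original.

The rank-weighted techniques project HU shifted by +1024 (via the technique
dispatcher) so outputs are non-negative attenuation proxies; because weights
are normalized the shift is a pure offset and disappears in display
normalization. Whether the original SoftMip implementation projected HU or
attenuation coefficients is not recorded; projecting shifted HU is this
package's choice.

MIP and mean are exposed as degenerate weightings (top-position indicator and
constant weight). They equal the per-column maximum and mean *exactly*, which
the tests use as the sorted projector's oracle anchor.

## Point-source projector

One ray is cast per detector pixel from the focal spot to the pixel center.
The detector plane is perpendicular to y (PA view), SDD beyond the source,
centered on the source–volume axis; default SDD 1800 mm and SOD 1500 mm are a
plausible radiographic geometry (magnification 1.2). The default detector
has one pixel per `(z, x)` voxel with pitch equal to the magnified voxel
spacing, so the large-distance limit reproduces the parallel projection
pixel-for-pixel; at SDD 10⁶ mm the two agree to ~3·10⁻⁵ in intensity on a
64³ phantom.

Each ray is clipped analytically to the volume bounding box (slab test); the
chord is split into `n = round(chord/step)` equal sub-intervals and μ is
sampled by trilinear interpolation at the sub-interval midpoints
(`Σ μ·h` with `h = chord/n`). Rounding `n` rather than ceiling it keeps a
homogeneous medium exact regardless of step. The default step is
`min(spacing)/2`; a ten-times finer quadrature changes random-volume
integrals by well under 1%. Exact voxel traversal (Siddon) would remove the
residual quadrature error entirely and is a possible future optimization.
Points in the half-voxel rim between the outermost centers and the bounding
box use clamped (nearest) extension.

Noise is applied to intensity images in two stages. Scatter: a
mean-preserving mixture `I' = (1−s)·I + s·G_σ(I)` of the image with a
Gaussian-blurred copy, `s = scatter_fraction` (default 0.1), σ in mm
(default 10). This is an empirical surrogate for scatter estimation, not a
physics model. Photon noise: per-pixel counts `Poisson(N₀·I'/I₀)` rescaled
back, so the mean is preserved and the variance is `I'·I₀/N₀`; default
N₀ = 10⁵ photons/pixel. Both stages are deterministic under a fixed seed;
`photons_per_pixel=None` disables the Poisson stage.

## Display mapping and classifier preprocessing

`intensity_to_display` maps intensity to the attenuation scale `−ln(I/I₀)`
(line-integral inputs pass through), optionally windows, then min–max
normalizes to [0, 1] — denser anatomy renders brighter, the radiograph
convention, with an inversion flag. A constant image maps to all zeros by
convention. Intensities are floored at `I₀·10⁻¹²` before the log.

`resize_bicubic` pads non-square images symmetrically with the image minimum
(preserving anatomical proportions rather than distorting them), then
resamples to 224×224 — the canonical chest-classifier input size — with
Pillow's bicubic filter (Keys kernel a = −0.5, support scaled on reduction),
clipping to [0, 1]. The tests verify it against an independent
re-implementation of convolution-based bicubic resampling written from the
definition.

## Synthetic chest phantom

The phantom stands in for patient CT data and is built from geometric
primitives at HU scale: air background (−1000), an elliptic-cylinder
soft-tissue body (0), two lung ellipsoids (−850), a posterior spine cylinder
(700), eight elliptical rib arcs (500) with an anterior sternum gap, optional
spherical nodules written last (+50 HU — soft-tissue density, as real lung
nodules are), and additive white Gaussian texture noise, σ = 20 HU, to mimic
ultra-low-dose noisiness. Identical spec + seed gives bit-identical volumes.

Default grid 128³ at 1.5 mm isotropic spacing. The spacing matches thin-slice
reconstructions; the implied 19.2 cm field of view means the default anatomy
is a compact (pediatric-scale) thorax whose proportions are expressed as
fractions of the FOV, so any grid size yields the same anatomy. The choice is
driven by a resolvability argument: the evaluation task plants 8 mm nodules,
and at 1.5 mm such a nodule spans >5 voxels, giving a projected contrast of
roughly `900 HU × 8 mm / 192 mm ≈ 37 HU` in column-mean units against a
column-noise floor of `20/√128 ≈ 1.8 HU` — comfortably detectable. At the
~2.7 mm spacing a full adult FOV would need on a 128³ grid, the nodule spans
3 voxels and rib/edge clutter begins to dominate any scorer.

`generate_cohort` draws per-case anatomy jitter (±6% on body and lung
half-axes), a single nodule with the given prevalence at a uniform random
position within 55% of the (margin-shrunk) lung half-axes, and a distinct
per-case noise seed — all from one cohort seed. The label is 1 iff a nodule
is present.

What the phantom does *not* emulate: heterogeneous parenchyma and vasculature,
respiratory/cardiac structures, pathology other than spherical nodules,
scanner reconstruction kernels and correlated noise. Passing the cohort tests
therefore shows the *pipeline and statistics* behave correctly on a
detectability task of known ground truth; it says nothing about clinical
performance on real radiographs.

## Evaluation statistics

AUC is the Mann–Whitney pair statistic: over all positive/negative pairs, 1
for a concordant pair, 0.5 for a tie (the standard convention; the half-credit
choice matters because rank-weighted DRR scores can tie). The empirical ROC
curve is returned alongside and its trapezoidal area equals the pair
statistic to ~10⁻¹² (verified as an invariant).

The DeLong test computes placement values per case (for each positive, the
fraction of negatives it outranks, and vice versa), the 2×2 covariance of the
two techniques' placements, and `z = (AUC₁−AUC₂)/√var(diff)` with a
two-sided normal p — the test's own asymptotics, no multiplicity correction.
Implementation is verified to 10⁻⁹ against an independent statistical
package's DeLong routine on a frozen example, and the single-AUC variance is
checked against a case-resampling bootstrap (10⁵ replicates at n = 30,
agreement within 25%). Degenerate inputs are explicit: identical placement
structures return z = 0, p = 1 exactly; zero variance with differing AUCs
raises instead of dividing by zero. Paired t-tests are the classical
`t = d̄/(s_d/√n)`, df = n−1; an all-zero difference vector returns p = 1, a
constant nonzero one is flagged as p = 0 with infinite t.

## Surrogate scorers

The original evaluation design used a trained 14-label chest-radiograph
classifier; trained network weights are out of scope, so the harness takes
any callable from a 224×224 display image to a real score. Three reference
scorers ship:

* `conspicuity_scorer` (default): bilateral-asymmetry nodule conspicuity —
  subtract the left-right mirrored image, smooth at nodule scale, take the
  maximum absolute asymmetry inside the lung fields. Mirror subtraction is
  the classic chest-CAD symmetry heuristic; on this phantom, body outline,
  lungs, spine, and rib arcs are symmetric by construction and cancel, so the
  unilateral nodule dominates. Under the default cohort it separates classes
  essentially perfectly (AUC ≈ 1.0 for all four techniques). It would
  degrade on asymmetric anatomy — a stated limitation, not a hidden one.
* `roi_mean_scorer`: mean display intensity over the lung fields. Kept as a
  transparency baseline; it is a *weak* detector by design — an 8 mm nodule
  shifts the lung-field mean by ~0.4 HU (column-mean units) while per-case
  anatomy variation shifts it by tens of HU, so its AUC stays near chance.
  Local blob detectors without the symmetry prior (difference-of-Gaussians,
  median or morphological top-hats) were evaluated and also fail, because
  rib-arc shadows out-contrast the nodule at nodule scale.
* `make_null_scorer(seed)`: seeded uniform noise, for calibration — its AUC
  is chance-level on any cohort, which the tests assert.

## Problem sizes and tolerances used by the checks

Closed-form Beer–Lambert: 200-sample water column, 10⁻¹⁰ (parallel) and 0.5%
(point-source). Brute-force oracle: 20 random 8³ volumes, 10⁻¹⁰ relative.
Parallel-limit: 64³ phantom at SDD 1.2·10⁶ mm, max |ΔI| < 10⁻³. DeLong:
frozen reference example at 10⁻⁹; bootstrap 10⁵ × n=30 within 25%.
End-to-end: 60 cases at 128³, AUC > 0.9 per technique. Poisson moments:
50 pooled realizations of a 10⁴-pixel constant image (5·10⁵ samples, so the
Monte-Carlo error of the variance estimate, ~0.2%, sits below the 1%
tolerance being checked). Phantom and noise determinism are asserted
byte-for-byte.

## Known limitations

* Monoenergetic attenuation; no beam hardening, no spectral detector model.
* Scatter is a blurred additive fraction, not a transport simulation.
* Parallel projection is axis-aligned only; arbitrary view angles exist only
  through the point-source geometry (currently restricted to PA-oriented
  detector planes).
* The wedge profile is a stand-in for an unpublished, visually tuned curve.
* The conspicuity scorer exploits phantom symmetry and is not a general
  nodule detector; plug in a real classifier via the scorer interface for
  clinical images.
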