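# Methods

`datspect` implements an automatic semi-quantitative analysis pipeline for
dopamine-transporter SPECT (^123^I-FP-CIT), together with a synthetic cohort
generator that provides ground truth for every stage. This note records the
models, the parameters that matter, and the numerical choices, so that a
maintainer can tell which behaviors are design and which are incidental.

## Pipeline model

A reconstructed DAT-SPECT volume in native patient space is mapped to a
standard (MNI-like) template space by a 12-parameter affine transform
(3 translations, 3 rotations, 3 zooms, 3 shears; composition T·R·Z·S with
R = Rx·Ry·Rz, all pinned in `AffineTransform12`). No nonlinear warping is
used. The registration target is either

* a single template representative of normal striatal uptake, or
* a set of eight templates — normal, moderate deficit right, moderate
  deficit left, strong reduction, each with and without scalp signal — in
  which case the optimizer matches the best *linear combination* of the
  templates to the moved scan.

The normalized scan is scaled to distribution-volume-ratio (DVR) units by
dividing by the 75th percentile of the intensity in a reference region
(whole brain without striata, thalamus/brainstem placeholder, cerebellum,
ventricles). The putamen specific binding ratio (SBR = DVR − 1) is then
extracted per hemisphere in two ways:

* **Hottest voxels (HV):** mean of the n highest DVR values inside a
  generously oversized unilateral putamen mask, with n fixed by a total
  volume of 10 ml (n = 1250 at 2 mm isotropic voxels). Ties at the n-th
  value are resolved by descending value with deterministic index order.
* **Anatomical ROI:** mean DVR over a tight anatomical putamen mask.

SBR is computed after averaging DVR (equivalent to per-voxel SBR averaging
for means). Per scan we report left, right, minimum and mean putamen SBR
and the determinant (DET) of the linear part of the native→template
mapping; DET > 1 means the native brain was enlarged into template space.

## Cohort separation metric

The histogram of a cohort's minimum putamen SBR (bin width 0.1, half-open
bins anchored at zero, negative bins allowed) is fitted by the sum of two
Gaussians, A₁exp(−(x−M₁)²/2SD₁²) + A₂exp(−(x−M₂)²/2SD₂²), by Nelder–Mead
on the summed squared count residuals. SDs enter through their absolute
value; components are relabeled after the fit so M₁ ≤ M₂ (component 1 =
reduced group). Derived metrics:

* effect size d = (M₂ − M₁)/√((SD₁² + SD₂²)/2),
* cutoff c = (SD₂M₁ + SD₁M₂)/(SD₁ + SD₂), the point between the means at
  equal distance in units of each component's SD. Values below c are
  classified "reduced", values at or above c "normal" (at-cutoff pinned to
  normal).

Fit initialization (not fixed by the method's description): amplitudes and
means from the two dominant local histogram maxima with SD = 0.2, plus a
small grid of fallback starts; the lowest SSE wins. Stability of d is
assessed by refitting random 90% subsamples (CoV = SD/mean). Agreement
between two classifications is a 2×2 table with Cohen's kappa and the
large-sample SE √(p₀(1−p₀)/(n(1−p_e)²)). Regressions (SBR vs DET with
constant; DET vs DET through the origin) use OLS; the standardized
coefficient is slope·SD(x)/SD(y) for with-constant models. No
multiple-testing adjustment is applied (mirroring unadjusted reporting).

## Registration internals

The cost is the head-mask-weighted sum of squared differences between the
moved scan and the best linear template combination; the combination
coefficients (plus a constant offset column) are solved in closed form at
every evaluation. Concretely, the template columns on the level grid are
orthonormalized once (QR), so each evaluation is: interpolate the scan at
the in-mask voxels (trilinear, zero outside the field of view, no Jacobian
modulation — "preserve concentrations" semantics), project out the template
subspace, and take the residual norm. Weighting is the product of

* the template-space head mask (whole head minus cerebellum), padded
  outward by 8 mm so that the head–air boundary stays inside the cost
  support (otherwise inflating the zoom can push bright scalp outside the
  evaluated region and go unpunished), and
* a 200 mm axis-aligned cube centered on the scan's intensity center of
  mass, mapped into template space; its support is frozen at each pyramid
  level's starting transform.

Optimization runs over a coarse-to-fine schedule, default

| method | added fwhm | grid stride | free params | budget |
|--------|-----------|-------------|-------------|--------|
| Nelder–Mead, 3 zoom seeds | 8 mm | 3 | 9 (T, R, Z) | 300 |
| Nelder–Mead | 4 mm | 3 | 9 | 150 |
| Gauss–Newton (trf, finite differences) | 4 mm | 2 | 9 | 25 |
| Gauss–Newton | 0 mm | 2 | 12 (+shears) | 40 |

Parameters are internally scaled (5 mm, 0.05 rad, 0.02 log-zoom, 0.02
shear per unit) and the Nelder–Mead simplex is seeded explicitly with one
scaled unit per free parameter; zooms are optimized as log-zooms.
Initialization is center-of-mass alignment with unit zooms — deterministic
and seedless. The coarse level races three initial isotropic zooms (1.0,
0.93, 1.08) and keeps the lowest cost: an anisotropic zoom of the nearly
ellipsoidal head can masquerade as a large rotation, and the extra seeds
keep the search out of that basin. A level's result is accepted only if
it does not increase that level's cost.

Two small quadratic penalties stabilize the problem without biasing
realistic transforms: λ(‖log zoom‖² + ‖shear‖²) with λ = 1e−4, and a
rotation penalty λ_rot‖rotation‖² with λ_rot = 1e−2 rad⁻² that steers the
coarse search away from spurious ~90° orientations of the nearly
ellipsoidal head (a 10° rotation costs only ~3e−4, far below the data
term). Templates are additionally smoothed by 1.9 mm during cost
evaluation to compensate the resolution the moved image loses to one pass
of trilinear interpolation (a 2 mm linear kernel carries ≈ voxel²/6 of
variance).

With eight templates the coefficient vector is intentionally not fully
identifiable (the with/without-scalp pairs differ only in the scalp
shell), so only the combined prediction — and hence the transform — is
meaningful; the reported coefficients are the minimum-norm solution. With
the four scalp-free templates the coefficients are identifiable and are
recovered exactly for noise-free combinations.

## Template construction

Each category template is built from a set of scans of that category by
repeated (default 3 passes: initial + two repetitions) single-template
normalization to the current target, DVR scaling, and voxelwise averaging
("soft mean"). The normal template is additionally symmetrized,
0.5(img + flip(img)), making it an exact mirror fixed point; moderate
scans are left–right flipped before averaging so the deficit is always
right-hemispheric, and the left-deficit template is the exact mirror of
the right-deficit one; the strong template averages scans as-is (neither
orientation nor symmetrization — read as the faithful procedure for that
category; whether mixed-side strong scans were flipped is not documented,
and this implementation averages them unflipped). The bootstrap target is
the noise-free painted normal phantom (or any user-supplied volume); the
original clinical bootstrap template is not available. This module has no
randomness: building twice from the same scans is bit-reproducible.

## The phantom: what it emulates, and what it does not

The generator paints axis-aligned ellipsoids on a 64×72×64 grid of 2 mm
voxels (left–right axis first, mirror plane at the central sagittal
plane): brain background at DVR 1, bilateral caudate and putamen at
DVR = 1 + SBR, an optional 6 mm scalp shell (DVR drawn from 0.4–1.2,
emulating residual scalp uptake after attenuation/scatter correction), a
cerebellum, ventricles and a thalamus placeholder used only for mask
construction. The anatomical putamen mask is the painted putamen
(~10.6 ml); the oversized HV mask is the putamen dilated by 12 mm,
clipped at the midline and away from the caudate (~52 ml ≥ 3× the HV
volume). The reference region excludes all striatal envelopes.

A subject's native scan is painted *directly on the native grid* by
testing each native voxel against the template-space ellipsoids through
the subject's true affine (affines map ellipsoids to ellipsoids, so this
is exact and interpolation-free), then blurred with an isotropic 4 mm
point-spread function, degraded with additive zero-truncated Gaussian
noise (SD 5% of background), and scaled by an arbitrary global intensity
factor (0.5–2). The 4 mm PSF is an optimistic post-resolution-recovery
figure chosen so that the HV readout of a noise-free, perfectly aligned
normal phantom stays within 15% of the painted truth (the HV average
over 10 ml inevitably under-reads a ~10.6 ml structure once blurred; at
larger PSFs the bias grows past that bound). With the PSF off, HV
recovery is exact to machine precision because the painted putamen holds
more than the 1250 hottest voxels.

Cohort structure: subjects are reduced with probability 0.45 (matching
the published classification marginals); the *worse-side* minimum putamen
SBR is drawn from N(0.58, 0.15²) for reduced and N(1.57, 0.32²) for
normal subjects (the published fitted components for the multi-template
HV minimum SBR), truncated at SBR > −0.5 to keep DVR positive; the better
side sits a fixed asymmetry above it (0.2 reduced / 0.05 normal; no
asymmetry distribution is published, so a fixed offset with a uniformly
random worse side is used); reduced caudate SBR sits 0.5 above the
putamen (rostrocaudal gradient). Misalignments are drawn uniformly:
translations ±10 mm, rotations ±10°, zooms 0.9–1.1, shears ±0.05.
Category templates are painted from fixed levels (normal 1.896, moderate
0.663 with 0.3 asymmetry, strong 0.282) that follow the reported typical
values of template-building scans.

An optional "template-mismatch geometry" (`reduced_shrink_at_zero < 1`)
shrinks the painted striatal semi-axes linearly with decreasing SBR,
emulating the apparently smaller striatum of low-uptake scans. It is off
by default and switched on for the directional experiment in which
single-template normalization inflates reduced brains (larger DET and
blunted separation) while the multi-template mode does not.

What the phantom does **not** emulate: projection/sinogram physics,
attenuation maps, collimator and camera-specific effects, anatomical
variability beyond affine misalignment (no shape variability, so
registration accuracy here is an upper bound on clinical accuracy),
spatially correlated reconstruction noise, and atypical deficit patterns
(caudate-predominant reduction). Passing tests therefore demonstrate
internal consistency of the method and its implementation, not clinical
performance.

## Problem sizes and determinism

The test suite exercises the full imaging pipeline at desk scale: 50-scan
registration-recovery and a 24-scan two-mode directional cohort; the
cohort-statistics layer is exercised at the published cohort size (1702
mixture draws) because it needs no imaging. Subsample stability uses 200
replicates (the same bound as the published 1000). All randomness flows
through explicit `numpy` Generators with pinned seeds; registration and
template building are deterministic given their inputs.

## Known limitations

* The registration cost is least-squares intensity matching; it is not
  robust to gross artifacts (e.g. salivary-gland uptake) and, like the
  original, requires a visual-QC analogue in real use.
* The affine decomposition assumes rotations inside gimbal range (|ry| <
  90°), which the regularized optimizer guarantees in practice.
* The eight-template coefficient vector is reported as a minimum-norm
  solution (see above) and should not be interpreted component-wise.
* DVR intensity normalization assumes the reference region's 75th
  percentile is strictly positive; degenerate scans raise instead of
  returning silently wrong values.
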