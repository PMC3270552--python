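# Methods

## Problem and model

In image-guided neurosurgery, a preoperative T1-weighted MR volume must be
aligned rigidly with intraoperative 3D B-mode ultrasound before the dura is
opened (brain shift before dura opening is negligible, so a rigid model
suffices; the neuronavigation system supplies a rough initial alignment that
can be several millimetres off).  Classical intensity similarity measures
(SSD, mutual information, correlation ratio) fail across these modalities.
`echoreg` instead matches the *hyperechogenic* structures visible in both:
liquid interfaces (sulci, cerebral falx) and lesions whose tissue is
echogenic (cavernomas, low-grade gliomas).

Each modality is converted into a per-voxel probability map of belonging to
hyperechogenic structure:

* **US map** Φ_US: the B-mode intensity min-max rescaled to [0, 1] — high
  intensity *is* the evidence, no segmentation is needed.  Acoustic-shadow
  and out-of-field zeros map to probability 0.
* **MR map** Φ_MR: the positive part of the MLvv valley operator (below),
  min-max rescaled to [0, 1] over its strictly-positive support, merged with
  the segmented lesion at probability Ψ via a voxel-wise max.  Ψ = 1 by
  default, modelling homogeneous hyperechogenic lesions.

The estimated transform maximises the discretised correlation integral

    S(T) = (1/|Ω|) Σ_{X ∈ US grid} p_US(X) · p_MR(T(X)),

with T mapping US world coordinates into MR space, trilinear interpolation
of p_MR, and probability 0 outside the MR support.  Because only bright
structures carry weight, missing information (shadows, limited field of
view) degrades the score gracefully instead of corrupting it.

## The MLvv valley operator

With Gaussian-derivative estimates V_x, ..., V_yz of the image at scale σ
(in voxels),

    MLvv = [ V_x²(V_yy+V_zz) + V_y²(V_xx+V_zz) + V_z²(V_xx+V_yy)
             − 2(V_y V_z V_yz + V_x V_z V_xz + V_x V_y V_xy) ] / (2‖∇V‖²).

The sign convention is *valley-positive*: on the analytic valley
V = x² + y² the operator evaluates to exactly +1 (bracket 8r², ‖∇V‖² = 4r²),
and to −1 on the corresponding crest.  Sulci and the falx are valleys of
T1-w intensity, so only the positive part enters the MR map.  The
normalisation makes the operator invariant to additive intensity shifts and
linear in positive intensity scalings (MLvv(cV) = c·MLvv(V)).

Numerical choices:

* Derivatives use moment-normalised sampled Gaussian kernels (radius 4σ,
  zero sum, exact derivative moment), making them exact on polynomials up to
  the derivative order; plain sampled kernels leak a small multiple of the
  local intensity into second derivatives and break shift invariance.
* Where ‖∇V‖² < 1e-12 · (dynamic range)² the operator returns 0: flat
  regions carry no ridge information and the division is meaningless there.
* σ defaults to 2 voxels, the scale at which sulci of typical width respond
  most cleanly; derivatives are computed per voxel unit (volumes are assumed
  near-isotropic, which reconstructed 3D-US/MR pairs in this setting are).
* Rescaling of the positive part uses only strictly-positive voxels, so
  background stays at probability exactly 0; the lesion merge uses max
  rather than sum so overlapping supports cannot exceed probability 1.

## Preprocessing

Skull stripping is an input (a brain mask); the masked MR volume is denoised
with a non-local means filter before valley detection, since noise creates
spurious curvature.  The NLM is the plain formulation: weights
exp(−d̄²/h²) with d̄² the mean squared difference between 3³ patches over a
7³ search window, mask-aware (out-of-brain voxels are excluded from patch
statistics, avoiding halos at the mask edge).  The bandwidth defaults to
h = √2·σ̂ with σ̂ a pseudo-residual noise estimate, so two noisy
realisations of the same patch receive weight ≈ e⁻¹.  All parameters are
config-exposed (`nlm.patch_radius`, `nlm.search_radius`, `nlm.h`).

## Optimisation

Nelder-Mead simplex over the 6 rigid parameters (3 translations in mm, 3
intrinsic x-y-z Euler rotations in degrees, about the US volume's physical
center — a fixed convention that keeps rotation/translation coupling small),
inside a two-level pyramid: downsampling factor 3 (with Gaussian
anti-aliasing at σ = 0.5·factor voxels), then the original resolution, each
level starting from the previous level's optimum.

Defaults: tolerance 0.1, stepsize 1.5 (mm for translations, degrees for
rotations — the initial simplex perturbs one parameter per vertex), at most
100 iterations per level.  The tolerance is applied as a *relative*
function-value spread: a level stops when the spread across the simplex
falls below tolerance·10⁻³·|score at the level's start|.  The relative form
is scale-invariant — the correlation score's magnitude depends on map
sparsity (order 10⁻² on the synthetic phantoms), and an absolute spread
criterion of similar size would terminate the simplex before it has locally
converged, leaving millimetres of residual misalignment.  A literal
absolute spread can be set via `optimizer.absolute_tolerance`.

The optimiser is deterministic; identical inputs and settings reproduce the
transform bit for bit.

## Validation machinery

* **Initial error**: mean ± sample std (n−1 throughout) of Euclidean
  distances between homologous landmark pairs.
* **Rigid landmark fit**: closed-form least squares (centroid alignment +
  Kabsch rotation from the cross-covariance SVD, det = +1 enforced);
  collinear configurations are rejected.
* **Leave-one-out TRE**: for each of n ≥ 4 pairs, fit on the others, apply
  to the held-out source point, record the distance to its target.
* **Warping index**: ω(T₁, T₂) = mean over domain voxel positions X of
  ‖T₁(X) − T₂(X)‖₂ — a pseudo-metric on transforms over a fixed domain.
  Both transforms are compared in the same direction; mixing one transform
  with the other's inverse would double-count the error and violate
  ω(T, T) = 0.
* **Robustness study**: random rigid perturbations with each translation
  ~ Uniform[0, 5] mm and each rotation ~ Uniform[0, 5]° (a symmetric
  ±range mode is config-selectable) are applied to the pre-aligned MR map
  (by resampling), registration is re-run from the reference alignment, and
  a trial succeeds when ω against the composed ground truth stays below
  3.5 mm.  The success rate and the mean/std of ω (over finite values)
  are reported; failures inside the optimiser count as non-successes.

## Synthetic phantoms

The generator emulates the *appearance* the method relies on, not acoustic
physics.  MR side: background tissue at 100, 6 dark tubes (depth 60,
Gaussian cross-profile of 1.5 mm radius) following smooth sinusoidal
centerlines, a dark mid-plane sheet for the falx, a hypointense sphere
(level 40, radius 8 mm, placed off-center at ≈ (+8, −6, +5) mm in a 64 mm
cube) for the lesion, light global smoothing (σ = 0.6 voxels) and additive
Gaussian noise (σ = 2, i.e. ≈ 3% of the tissue-valley contrast).  US side:
an echogenicity field bright (1.0) on 1-voxel-dilated valley centerlines
and inside the lesion over a dim background (0.15), placed into the US
frame through the ground-truth transform, multiplied by unit-mean gamma
speckle (variance 0.25, a standard first-order speckle surrogate), with an
optional shadow slab zeroed and an optional field-of-view box crop.  The
canonical artifact setting keeps ≈ 57% of the volume in the field of view
and shadows ≈ 8% of it.

Because the US simulation uses ground-truth geometry rather than the MR
valley response, feature extraction and registration are validated
independently, not circularly.  What the phantoms do *not* model: real
speckle correlation, attenuation and reverberation, anatomical variability,
partial-volume effects, heterogeneous lesion echogenicity, and expert
landmark-picking error.  Passing the synthetic studies therefore
demonstrates correctness of the machinery and robustness of the objective
under the modelled artifacts — not clinical-grade accuracy on patient data.

## Problem sizes and defaults used in the studies

The parameter-recovery studies run 20 independently seeded 64³ phantoms at
1 mm spacing, one random perturbation each, with the default optimiser and
map settings; this keeps the full validation suite comfortably inside a
desktop-scale compute budget while leaving enough trials for a meaningful
success rate.  All randomness flows from a single integer seed
(fixture seeds are drawn below 2³¹ from the study generator; the phantom
generator derives independent streams for structure and speckle).

## Known limitations

* Rigid transforms only; brain-shift compensation after dura opening needs
  a nonrigid extension of the objective.
* Axis-aligned grids only (no oblique NIfTI orientations); resampling is
  trilinear with zero fill.
* The Euler parameterisation has the usual gimbal ambiguity at a middle
  angle of ±90°, far outside the capture range relevant here.
* The valley detector is tuned to T1-w appearance; other MR sequences would
  need a different mapping to hyperechogenicity probability.
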