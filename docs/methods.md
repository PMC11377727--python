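# Methods

## Scope and model

`wstomo` implements single-scattering optical diffraction tomography with
on-axis, wavelength-variable illumination, intensity-only detection on a
defocused sensor, pixel super-resolution (PSR), and hybrid missing-cone
regularization.  The model is scalar and first-order: the scattered field is
linked to the 3D scattering potential V(r) = (2π/λ)²(n² − n_m²) through the
Fourier diffraction theorem, and to the measured intensity through the Rytov
approximation I = |exp(U_s1)|².  Multiple scattering, partial coherence,
sensor angular response, absorption phantoms and polarization are out of
scope (absorption is *representable* — RI volumes are complex — but no
generator produces it and TV acts on the real part only).

## Conventions

* Reduced spatial frequencies everywhere: k_m = n_m/λ in cycles/μm, kernels
  exp(2πj k_z z).  One convention end to end removes silent 2π errors.
* All fields are envelope fields: the plane-wave carrier exp(2πj k_m z) is
  divided out, so U_s1 ≡ 0 means "no sample" and the diffraction prefactor
  reads j/(4π k_z)·exp(2πj(k_z − k_m) z_D).
* The sign of the prefactor is **+j**, required for consistency with
  angular-spectrum propagation under the exp(−jωt)/exp(+2πjν·r) convention
  pair used here; the forward model is validated against an independent
  angular-spectrum oracle on a thin weak phase slab (< 2% RMS intensity
  mismatch, observed ~4 × 10⁻⁶).  The opposite sign appears in texts using
  the conjugate convention.  The global sign cannot affect
  simulate-then-recover self-consistency, but it does fix which contrast
  sign a dense bead reconstructs with; an end-to-end test asserts positive.
* Axes (x, y, z), z toward the detector; array index i maps to coordinate
  (i − N//2)·Δ on every axis, in space and in frequency.

## Discretization

Each wavelength's Ewald cap is discretized with one sample per lateral
frequency voxel inside the propagating disk |k_T| < k_m; the target voxel is
the nearest neighbour of (k_x, k_y, k_z − k_m) (floor(x+0.5) rounding).
Evanescent samples are dropped; cap samples whose shifted axial index falls
outside the grid are truncated with a warning — physical for near-90°
scattering on short axial grids.  Nearest-voxel discretization is what makes
neighbouring wavelengths' caps share rim voxels, so a sufficiently fine
wavelength schedule yields a connected spectral support.  The wavelength
schedule is uniform over [λ_min, λ_max] by default (57 points over
430–1200 nm) and user-overridable; the acquisition source only fixes range
and count, not spacing.

## The solver

Per outer pass and per wavelength (ascending order):

1. extract the cap of V̂ and inverse-transform to U_s1 at the sensor plane;
2. intensity constraint with PSR: I_change = I_hr · replicate(I_meas /
   (bin(I_hr) + ε)), ε = 10⁻⁹ of the frame mean — a multiplicative block
   correction that matches block means while preserving intra-block
   structure — then Ū_s1 = ln(α√I_change·e^{j·arg U} + (1−α)U).  The log's
   imaginary part is unwrapped toward the current iterate (2π offset
   minimizing |Ū_s1 − U_s1|), which keeps optically thicker objects off the
   principal-branch cliff;
3. remap: divide by the prefactor, write back onto the cap (replacement;
   samples sharing a voxel are averaged; a weight mask counts insertions);
4. rescale the whole spectrum by (λ_i/λ_{i+1})² — exact, since V ∝ λ⁻².

Defaults: α = 0.5, 3 outer passes, early stop when the median per-wavelength
amplitude residual improves by < 10⁻³ between passes.  Binning uses the
block **mean** so a unit background stays 1 across scales.  Hermitian
symmetry is *not* enforced on V̂ (absorption would break it); the reality
ratio max|Im|/max|Re| of the recovered volume is reported as a diagnostic.
Before regularization it is large (~0.3 on the bead fixture — only the
negative-k_z half space is measured); the regularization passes, which zero
the imaginary part in real space while re-imposing measured voxels,
progressively restore reality.

## Missing-cone regularization

Gerchberg–Papoulis alternation (default 20 passes): inverse transform →
clip the real contrast at 0 (valid when the sample is at least as dense as
its medium, e.g. polystyrene in n = 1.58 oil; a flag disables it) →
isotropic 3D TV denoising (Chambolle dual projection, 10 inner iterations,
weight 2% of the maximum recovered contrast unless set) → forward transform
→ restore measured voxels bit-identically.  TV assumes piecewise-constant
samples; excessive weight flattens genuine internal structure.

## Preprocessing

Background normalization divides by the median of an 8-px border ring
(lens-free frames have object-free margins).  Autofocus back-propagates the
contrast hologram I/bg − 1 by the angular spectrum over a candidate z grid
and maximizes the Tamura coefficient of the gradient magnitude of the
refocused amplitude.  Back-propagating the amplitude √I instead carries a
systematic ≈ +10 μm bias on bead fixtures (the criterion valley sits behind
the object plane); the contrast-hologram variant is unbiased within ±5 μm
across the 400–630 μm defocus regimes.  One z_D serves the whole stack:
on-axis illumination produces no wavelength-dependent image shift.

## Synthetic data

Generators produce beads (polystyrene n = 1.594 in n = 1.58 oil by
default), USAF-1951 three-bar phase targets (line width
500·2^{−(G+(E−1)/6)} μm, bars 5w long, optional tilt about y with
nearest-voxel resampling), a two-bar resolution pair with controllable
sampling phase, and macrophage-like cell blobs in three growth stages
(round, pseudopod-bearing, elongated; body radius 3.0–4.5 μm; rejection-
sampled placement, deterministic per seed).  The simulator reproduces the
acquisition chain — potential → cap extraction → Rytov intensity → s×s
pixel binning → optional Poisson/read noise — with an optional guard band
cropped to suppress periodic wrap-around.

What the generator does *not* emulate: multiple scattering in thick dense
samples, source partial coherence (2–11 nm AOTF bandwidth), dispersion of
the RI over the scan range (≈1% for transparent media; the solver assumes a
wavelength-independent contrast), sensor angular response, and real sensor
PSFs.  Passing tests therefore demonstrate correctness of the algorithmic
chain under its own physical model, not robustness to those effects.

## Problem sizes

The validation suite scales the study down so everything is exactly
checkable: the bead recovery runs a 96³ volume at 0.4 μm voxels, 19
wavelengths, s = 2, z_D = 20 μm with no guard band (the reconstruction
model is periodic, so the scaled field must contain the diffraction
spread); the PSR demonstration uses a 128×128×32 grid, s = 4 vs s = 1 on a
bar pair whose peak separation is 1.2× the 1.6 μm sensor pitch — beyond the
sensor-grid Nyquist limit, inside the super-resolved band.  A gap that wide
*between wide bars* is within the sensor band and is recovered even without
PSR, consistent with the w/o-PSR line-width measurements of lens-free
systems; the separation-based phrasing is the meaningful sub-Nyquist claim.
Full-sensor work (9×7 tiles of 500×500 px, ≥50 px overlap, alpha-blended
with exact partition-of-unity linear ramps) is exercised at plan level and
on cut-and-reblend volumes.

## Morphology

Objects are voxels with RI contrast above a user threshold, 26-connected.
Axial lengths are divided by a correction factor (intended: the
axial/lateral FWHM ratio of a point-like calibration bead) before
measurement.  Volume is voxel-counted; surface area is boundary-face
counting divided by 1.5, the exact asymptotic overestimate of face counting
for smooth surfaces (configurable; set 1.0 for raw face counts).  Wadell
sphericity Ψ = π^{1/3}(6V)^{2/3}/A is capped at 1 because the bias
correction can overshoot by a few percent on near-spherical digital
objects.  Stage classification uses two Ψ cut points (defaults 0.85 and
0.60), exposed in configuration — they are operating points, not measured
constants.  Spreading area is the largest single-z-slice footprint.

## Known limitations

* Recovered RI contrast is underestimated (missing cone + half-space
  coverage); on the bead fixture the center contrast recovers ≈10% of truth
  before scaling by regularization.  Morphology thresholds must be chosen
  on the reconstructed scale, not the physical Δn.
* The Rytov link degrades for optically thick/dense objects; the phase
  unwrap in the constraint mitigates but does not remove this.
* Autofocus assumes a single dominant object plane.
* Tile stitching assumes one global z_D (per-tile override available for
  tilted samples).
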