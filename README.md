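# wstomo

Wavelength-scanning Fourier ptychographic diffraction tomography (wsFPDT)
for lens-free on-chip 3D microscopy.

Lens-free on-chip microscopes record in-line diffraction patterns of a
sample placed directly above a CMOS sensor: no lenses, the full sensor area
as field of view — but only intensities, at a resolution limited by the
sensor pixel pitch, and conventionally only for thin 2D samples.  `wstomo`
implements the non-interferometric tomography scheme that lifts all three
limits at once: the sample is illuminated on-axis at many wavelengths
(430–1200 nm), and an iterative ptychographic solver fills the 3D spectrum
of the scattering potential, one Ewald cap per wavelength, recovering the
volumetric refractive-index (RI) distribution n(**r**) with pixel
super-resolution.  It is aimed at computational-imaging researchers and
bioimaging groups who want a complete, testable reference pipeline —
forward simulator, inverse solver, and quantitative cell morphometry —
without hardware.

## The model

In reduced spatial frequencies (cycles/μm), an on-axis plane wave of vacuum
wavelength λ in a medium of index n_m constrains the spectrum V̂(**k**) of
the scattering potential

    V(r) = (2π/λ)² (n²(r) − n_m²)

on a cap of the Ewald sphere of radius k_m = n_m/λ, shifted so it touches
the origin (Fourier diffraction theorem):

    Û_s1(k_T; z_D) = j/(4π k_z) · exp(2πj (k_z − k_m) z_D) · V̂(k − k_in),
    k_z = √(k_m² − |k_T|²),   k_in = (0, 0, k_m).

Under the Rytov approximation the measured intensity at the defocused
sensor plane z_D is I = |exp(U_s1)|².  Scanning λ sweeps the cap radius;
each frame updates the spectrum through a relaxed amplitude constraint

    Ū_s1 = ln( α √I_change · e^{j·arg U} + (1 − α) U ),   U = exp(U_s1),

where I_change corrects the high-resolution model intensity by the ratio of
the measured frame to its pixel-binned model (the pixel-super-resolution
step: each sensor pixel is the mean of an s×s block of finer pixels).
Between wavelengths the spectrum is rescaled by (λ_i/λ_{i+1})², exact
because V ∝ λ⁻².  The transmission geometry leaves a missing cone of low
axial frequencies; a hybrid Gerchberg–Papoulis scheme (non-negativity of
the contrast alternated with 3D total-variation denoising, measured voxels
re-imposed) fills it.  Finally n(r) = √(n_m² + V(r)·(λ_ref/2π)²).

## Worked example

Simulate a 5 μm polystyrene bead (n = 1.594) in index-matching oil
(n_m = 1.58, so Δn = 0.014) on a 96³ grid at 0.4 μm voxels, scanned at 19
wavelengths from 430 to 1200 nm with upsampling factor s = 2, and
reconstruct it:

```python
import numpy as np, wstomo as w
from scipy import ndimage

vol = w.bead_phantom((96, 96, 96), (0.4, 0.4, 0.4),
                     [((0, 0, 0), 5.0, 1.594)], n_m=1.58)
cfg = w.ScanConfig(wavelengths=tuple(w.scan_schedule(0.43, 1.20, 19)),
                   n_m=1.58, z_D=20.0, sensor_pitch=0.8, upsample=2,
                   nz=96, dz=0.4, guard=0, passes=3, reg_passes=20, seed=1)
frames, _ = w.simulate_scan(vol, cfg)
out, diag = w.run_wsfpdt([w.normalize_intensity(f) for f in frames], cfg)

c = np.maximum(out.contrast(), 0)
print("median residuals per pass:", [f"{m:.2e}" for m in diag["median_residuals"]])
print("centroid (voxels):", [f"{x:.2f}" for x in ndimage.center_of_mass(c)])
print("contrast at bead center:", f"{out.data.real[48, 48, 48] - 1.58:.4f}")
```

prints

```
median residuals per pass: ['6.03e-03', '2.33e-03', '1.62e-03']
centroid (voxels): ['47.78', '47.78', '48.09']
contrast at bead center: 0.0013
```

The per-pass amplitude residual ‖√I_model − √I_meas‖/‖√I_meas‖ falls by 4×
over three passes; the bead is recovered within a quarter voxel of its true
center with positive contrast (the missing cone underestimates the contrast
magnitude — hybrid regularization reduces the accompanying axial elongation
of this bead from 1.65× to 1.04×, available in
`diag["ri_preregularization"]`).

The same pipeline is scriptable from the shell:

```sh
wstomo simulate --phantom bead --out bead.tiff --seed 7 --size 96 --n-wavelengths 19
wstomo focus --stack bead.tiff --z-search 10,60,2
wstomo reconstruct --stack bead.tiff --out bead_ri.h5 --upsample 2 --nz 96 --dz 0.4
wstomo morph --volume bead_ri.h5 --threshold 0.0005 --out morph.csv
wstomo report
```

`wstomo report` prints the throughput arithmetic of the full-sensor system
(3872 × 2764 px at 1.67 μm, 775 nm half-pitch lateral and 5.43 μm axial
resolution over a 200 μm depth):

```
USAF G9E3 line width  775 nm
USAF G8E3 line width  1.55 um
FOV                   29.85 mm^2
pixel/Nyquist ratio   2.15
effective voxel       3.26 um^3
imaged volume         5.97 mm^3
effective voxels      1.83e+09
```

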