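"""Iterative spectrum-filling inverse solver (wsFPDT).

The solver maintains the 3D scattering-potential spectrum V̂(k) and, for each
wavelength in the schedule, (i) extracts the first-order scattered field on
that wavelength's Ewald cap, (ii) replaces its modulus with the measured
intensity under a pixel-binning model and a relaxation factor α, (iii)
remaps the corrected field back onto the cap, and (iv) rescales the whole
spectrum by (λ_i/λ_{i+1})² — the scattering potential is proportional to
λ⁻², so this converts the stored spectrum to the next wavelength's scaling.
After the outer passes a hybrid non-negativity + total-variation scheme
fills the missing cone, and the RI volume is recovered as
n(r) = √(n_m² + V(r)·(λ_ref/2π)²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fft import fft2c, fft3c, ifft3c
from .config import ScanConfig
from .forward import (
    ComplexField,
    IntensityFrame,
    bin_pixels,
    first_order_field,
    replicate_pixels,
)
from .kspace import EwaldShell, FrequencyGrid, build_shell
from .phantoms import RIVolume
from .regularize import hybrid_fill

__all__ = [
    "PotentialSpectrum",
    "init_spectrum",
    "intensity_constraint",
    "remap_to_shell",
    "wavelength_transition",
    "run_wsfpdt",
]


@dataclass
class PotentialSpectrum:
    """Scattering-potential spectrum under iterative update.

    ``weights`` counts measured insertions per voxel (0 = never touched by
    any shell); ``wavelength_ref`` is the wavelength whose λ⁻² scaling the
    stored values currently carry.
    """

    data: np.ndarray
    grid: FrequencyGrid
    weights: np.ndarray
    wavelength_ref: float

    def imag_ratio(self) -> float:
        """max|Im|/max|Re| of the inverse transform — a reality diagnostic."""
        v = ifft3c(self.data, self.grid.voxel_volume)
        denom = float(np.max(np.abs(v.real)))
        if denom == 0:
            return 0.0
        return float(np.max(np.abs(v.imag)) / denom)


def init_spectrum(grid: FrequencyGrid, n_m: float, wavelength_ref: float) -> PotentialSpectrum:
    """All-zero spectrum: a uniform medium-filled volume has zero contrast."""
    return PotentialSpectrum(
        data=np.zeros(grid.shape, dtype=complex),
        grid=grid,
        weights=np.zeros(grid.shape, dtype=np.int32),
        wavelength_ref=float(wavelength_ref),
    )


def intensity_constraint(
    u_s1: ComplexField, i_meas: IntensityFrame, s: int, alpha: float
) -> ComplexField:
    """Relaxed amplitude replacement with a pixel-binning (PSR) model.

    Forms the corrected high-resolution intensity
    ``I_change = I_hr · replicate(I_meas / (bin(I_hr) + ε))`` — a
    multiplicative block correction that matches block means while keeping
    intra-block structure — then applies

        Ū_s1 = ln(α·√I_change·exp(j·arg U) + (1−α)·U),   U = exp(U_s1)

    with the log's imaginary part unwrapped against the current iterate to
    avoid 2π jumps for optically thicker objects.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    s = int(s)
    u = u_s1.data
    nx, ny = u.shape
    if (nx // s, ny // s) != i_meas.data.shape:
        raise ValueError(
            f"field shape {u.shape} and measurement shape {i_meas.data.shape} "
            f"are not related by s={s}"
        )
    U = np.exp(u)
    i_hr = np.abs(U) ** 2
    hr_frame = IntensityFrame(i_hr, u_s1.wavelength, u_s1.z, u_s1.pitch)
    i_bin = bin_pixels(hr_frame, s).data
    eps = 1e-9 * float(np.mean(i_meas.data))
    corr = i_meas.data / (i_bin + max(eps, 1e-300))
    i_change = i_hr * replicate_pixels(corr, s)

    w = alpha * np.sqrt(i_change) * np.exp(1j * np.angle(U)) + (1.0 - alpha) * U
    im = np.angle(w)
    im = im + 2.0 * np.pi * np.round((u.imag - im) / (2.0 * np.pi))
    ubar = np.log(np.abs(w)) + 1j * im
    return ComplexField(ubar, u_s1.pitch, u_s1.z, u_s1.wavelength)


def remap_to_shell(
    u_s1_bar: ComplexField, shell: EwaldShell, spectrum: PotentialSpectrum
) -> PotentialSpectrum:
    """Insert the corrected 2D field spectrum back onto the Ewald cap.

    Each cap sample's value (the 2D spectrum divided by the diffraction
    prefactor) replaces the stored spectrum at its target voxel; samples
    sharing one target voxel are averaged.  The fill-weight mask counts
    insertions.  Mutates and returns ``spectrum``.
    """
    if shell.grid.shape != spectrum.grid.shape:
        raise ValueError("shell and spectrum grids do not match")
    if u_s1_bar.data.shape != spectrum.grid.shape[:2]:
        raise ValueError("field shape does not match the lateral grid")
    spec2d = fft2c(u_s1_bar.data, spectrum.grid.pixel_area)
    vals = spec2d[shell.ix, shell.iy] / shell.prefactor

    flat = np.ravel_multi_index((shell.ix, shell.iy, shell.iz), spectrum.grid.shape)
    sums = np.zeros(flat.max() + 1, dtype=complex)
    counts = np.zeros(flat.max() + 1, dtype=np.int64)
    np.add.at(sums, flat, vals)
    np.add.at(counts, flat, 1)
    touched = np.nonzero(counts)[0]
    spectrum.data.ravel()[touched] = sums[touched] / counts[touched]
    w = spectrum.weights.ravel()
    w[touched] += counts[touched].astype(w.dtype)
    return spectrum


def wavelength_transition(
    spectrum: PotentialSpectrum, lambda_i: float, lambda_next: float
) -> PotentialSpectrum:
    """Rescale the spectrum to the next wavelength: V̂ ← (λ_i/λ_next)²·V̂.

    Exactly preserves the physical contrast spectrum V̂·λ² since the
    scattering potential scales as λ⁻².  Weights are unchanged.
    """
    if lambda_i <= 0 or lambda_next <= 0:
        raise ValueError("wavelengths must be positive")
    spectrum.data *= (lambda_i / lambda_next) ** 2
    spectrum.wavelength_ref = float(lambda_next)
    return spectrum


def _ri_from_spectrum(spectrum: PotentialSpectrum, n_m: float) -> np.ndarray:
    """Convert the spectrum to an RI volume (real part; radicand floored)."""
    v = ifft3c(spectrum.data, spectrum.grid.voxel_volume)
    lam = spectrum.wavelength_ref
    radicand = n_m * n_m + v.real * (lam / (2.0 * np.pi)) ** 2
    return np.sqrt(np.where(radicand < 0, n_m * n_m, radicand))


def run_wsfpdt(frames: list[IntensityFrame], cfg: ScanConfig):
    """Reconstruct a 3D RI volume from a normalized wavelength-scan stack.

    Returns ``(RIVolume, diagnostics)``.  ``diagnostics`` records the
    per-wavelength amplitude residual ‖√I_model − √I_meas‖₂/‖√I_meas‖₂ for
    every outer pass, the pre-regularization RI volume, and the reality
    ratio of the final spectrum.
    """
    if len(frames) != len(cfg.wavelengths):
        raise ValueError(
            f"{len(frames)} frames for {len(cfg.wavelengths)} scheduled wavelengths"
        )
    frames = sorted(frames, key=lambda f: f.wavelength)
    for f, lam in zip(frames, cfg.wavelengths):
        if not np.isclose(f.wavelength, lam):
            raise ValueError(
                f"frame wavelength {f.wavelength} does not match schedule entry {lam}"
            )

    s = int(cfg.upsample)
    nx, ny = frames[0].data.shape
    grid = FrequencyGrid(
        (nx * s, ny * s, int(cfg.nz)),
        (cfg.hires_pitch, cfg.hires_pitch, float(cfg.dz)),
    )
    shells = [build_shell(grid, lam, cfg.n_m, cfg.z_D) for lam in cfg.wavelengths]
    spectrum = init_spectrum(grid, cfg.n_m, cfg.wavelengths[0])

    residual_log: list[list[float]] = []
    medians: list[float] = []
    for outer in range(int(cfg.passes)):
        residuals = []
        for i, (lam, shell, frame) in enumerate(zip(cfg.wavelengths, shells, frames)):
            if not np.isclose(spectrum.wavelength_ref, lam):
                spectrum = wavelength_transition(spectrum, spectrum.wavelength_ref, lam)
            u = first_order_field(spectrum.data, shell)
            i_model = bin_pixels(
                IntensityFrame(np.exp(2.0 * u.data.real), lam, cfg.z_D, u.pitch), s
            ).data
            sqrt_meas = np.sqrt(frame.data)
            denom = float(np.linalg.norm(sqrt_meas))
            res = float(np.linalg.norm(np.sqrt(i_model) - sqrt_meas) / max(denom, 1e-300))
            if not np.isfinite(res):
                raise FloatingPointError(
                    f"divergence at pass {outer}, wavelength {lam}: residual={res}"
                )
            residuals.append(res)
            ubar = intensity_constraint(u, frame, s, cfg.alpha)
            spectrum = remap_to_shell(ubar, shell, spectrum)
        residual_log.append(residuals)
        medians.append(float(np.median(residuals)))
        if outer > 0 and medians[-2] > 0:
            if (medians[-2] - medians[-1]) / medians[-2] < 1e-3:
                break

    ri_preneg = _ri_from_spectrum(spectrum, cfg.n_m)

    if cfg.reg_passes > 0:
        tv_weight = cfg.tv_weight
        if tv_weight is None:
            v = ifft3c(spectrum.data, grid.voxel_volume)
            tv_weight = 0.02 * float(np.max(np.abs(v.real)))
        spectrum = hybrid_fill(
            spectrum, cfg.reg_passes, tv_weight, cfg.tv_iters, nonneg=cfg.nonneg
        )

    ri = _ri_from_spectrum(spectrum, cfg.n_m)
    vol = RIVolume(
        ri.astype(complex),
        grid.voxel_pitch,
        cfg.n_m,
        annotation={"kind": "reconstruction", "wavelength_ref": spectrum.wavelength_ref},
    )
    diagnostics = {
        "residuals": residual_log,
        "median_residuals": medians,
        "imag_ratio": spectrum.imag_ratio(),
        "ri_preregularization": ri_preneg,
        "wavelength_ref": spectrum.wavelength_ref,
        "fill_fraction": float(np.mean(spectrum.weights > 0)),
    }
    return vol, diagnostics
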