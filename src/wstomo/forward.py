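"""Forward model of the lens-free measurement.

Chain per wavelength: scattering potential → 3D spectrum → first-order
scattered field on the Ewald cap (Fourier diffraction theorem) → Rytov
intensity at the defocused detector plane → pixel binning to the sensor
pitch → optional shot/read noise.

All fields are *envelope* fields: the unit-amplitude on-axis plane-wave
carrier exp(2πj k_m z) is divided out, so a zero scattering potential gives
U_s1 ≡ 0 and unit intensity everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fft import fft3c, ifft2c
from .config import ScanConfig
from .kspace import EwaldShell, build_shell
from .phantoms import RIVolume

__all__ = [
    "ComplexField",
    "IntensityFrame",
    "scattering_potential",
    "first_order_field",
    "rytov_intensity",
    "bin_pixels",
    "replicate_pixels",
    "simulate_scan",
]


@dataclass
class ComplexField:
    """2D complex lateral field U(r_T; z) at one plane and wavelength."""

    data: np.ndarray
    pitch: float
    z: float
    wavelength: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("ComplexField data must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ComplexField contains non-finite entries")


@dataclass
class IntensityFrame:
    """One non-negative intensity image with its acquisition metadata."""

    data: np.ndarray
    wavelength: float
    z_D: float
    pitch: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("IntensityFrame data must be 2D")
        if np.min(self.data) < 0:
            raise ValueError("intensity must be non-negative")


def scattering_potential(vol: RIVolume, wavelength: float) -> np.ndarray:
    """Scattering potential V(r) = (2π/λ)²·(n(r)² − n_m²), units μm⁻².

    V vanishes where n = n_m and scales as λ⁻² at fixed contrast, which is
    what makes the (λ_i/λ_{i+1})² inter-wavelength spectrum transition exact.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    k0 = 2.0 * np.pi / wavelength
    return k0 * k0 * (vol.data**2 - vol.n_m**2)


def first_order_field(V_hat: np.ndarray, shell: EwaldShell) -> ComplexField:
    """First-order scattered envelope field at the detector plane.

    Reads the 3D potential spectrum on the shifted Ewald cap, applies the
    diffraction-theorem prefactor, and inverse-transforms the resulting 2D
    lateral spectrum (zero outside the cap support).
    """
    grid = shell.grid
    V_hat = np.asarray(V_hat)
    if V_hat.shape != grid.shape:
        raise ValueError(
            f"spectrum shape {V_hat.shape} does not match shell grid {grid.shape}"
        )
    spec2d = np.zeros(grid.shape[:2], dtype=complex)
    spec2d[shell.ix, shell.iy] = V_hat[shell.ix, shell.iy, shell.iz] * shell.prefactor
    u = ifft2c(spec2d, grid.pixel_area)
    return ComplexField(u, grid.voxel_pitch[0], shell.z_D, shell.wavelength)


def rytov_intensity(u_s1: ComplexField) -> IntensityFrame:
    """Intensity I = |exp(U_s1)|² = exp(2·Re U_s1) of the Rytov total field."""
    intensity = np.exp(2.0 * u_s1.data.real)
    return IntensityFrame(intensity, u_s1.wavelength, u_s1.z, u_s1.pitch)


def bin_pixels(frame: IntensityFrame, s: int) -> IntensityFrame:
    """Average s×s blocks down to the sensor pitch (mean, not sum).

    The mean keeps the unit background at 1 across scales and preserves the
    frame mean exactly.
    """
    s = int(s)
    if s == 1:
        return IntensityFrame(frame.data.copy(), frame.wavelength, frame.z_D,
                              frame.pitch, frame.bit_depth)
    nx, ny = frame.data.shape
    if nx % s or ny % s:
        raise ValueError(f"frame shape {(nx, ny)} not divisible by s={s}; pad first")
    binned = frame.data.reshape(nx // s, s, ny // s, s).mean(axis=(1, 3))
    return IntensityFrame(binned, frame.wavelength, frame.z_D,
                          frame.pitch * s, frame.bit_depth)


def replicate_pixels(arr: np.ndarray, s: int) -> np.ndarray:
    """Nearest-neighbour upsampling by s along both axes (bin adjoint)."""
    return np.repeat(np.repeat(arr, s, axis=0), s, axis=1)


def simulate_scan(vol: RIVolume, cfg: ScanConfig):
    """Simulate one wavelength-scanning acquisition of ``vol``.

    Returns ``(frames, truth)`` where frames are sensor-pitch
    :class:`IntensityFrame` objects, one per scheduled wavelength, and
    ``truth`` records the phantom annotation and effective geometry.
    Deterministic for a fixed ``cfg.seed``.
    """
    if len(cfg.wavelengths) == 0:
        raise ValueError("wavelength schedule is empty")
    grid = vol.grid
    s = int(cfg.upsample)
    g = int(cfg.guard)
    nx, ny = grid.shape[:2]
    if nx - 2 * g <= 0 or ny - 2 * g <= 0:
        raise ValueError("guard band swallows the whole frame")
    if (nx - 2 * g) % s or (ny - 2 * g) % s:
        raise ValueError(
            f"cropped lateral shape {(nx - 2 * g, ny - 2 * g)} must be divisible "
            f"by the upsampling factor {s}"
        )
    if not np.isclose(grid.voxel_pitch[0], cfg.hires_pitch):
        raise ValueError(
            f"volume lateral pitch {grid.voxel_pitch[0]} must equal "
            f"sensor_pitch/upsample = {cfg.hires_pitch}"
        )

    rng = cfg.rng()
    frames: list[IntensityFrame] = []
    for lam in cfg.wavelengths:
        V_hat = fft3c(scattering_potential(vol, lam), grid.voxel_volume)
        shell = build_shell(grid, lam, vol.n_m, cfg.z_D)
        u = first_order_field(V_hat, shell)
        hires = rytov_intensity(u)
        if g:
            hires = IntensityFrame(hires.data[g:-g, g:-g], lam, cfg.z_D, hires.pitch)
        frame = bin_pixels(hires, s)
        data = frame.data
        if cfg.photons is not None:
            data = rng.poisson(np.maximum(data, 0.0) * cfg.photons) / cfg.photons
        if cfg.read_noise > 0:
            data = data + rng.normal(0.0, cfg.read_noise, size=data.shape)
        frames.append(IntensityFrame(np.maximum(data, 0.0), lam, cfg.z_D,
                                     cfg.sensor_pitch))

    truth = {
        "annotation": vol.annotation,
        "n_m": vol.n_m,
        "voxel_pitch": vol.voxel_pitch,
        "shape": vol.shape,
        "z_D": cfg.z_D,
        "upsample": s,
        "guard": g,
        "seed": cfg.seed,
    }
    return frames, truth
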