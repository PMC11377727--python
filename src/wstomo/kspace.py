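"""Frequency-space bookkeeping for wavelength-scanning diffraction tomography.

Everything here uses *reduced* spatial frequencies in cycles/μm, so the
Ewald-sphere radius is k_m = n_m/λ and propagation kernels read
exp(2πj k_z z).  A single-wavelength, on-axis intensity measurement
constrains the 3D scattering-potential spectrum on a semi-spherical cap of
that sphere, shifted by the incident wavevector k_in = (0, 0, k_m) so the
cap touches the frequency origin and bends toward negative axial frequency.
Scanning the wavelength sweeps the cap radius and fills 3D k-space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyGrid",
    "EwaldShell",
    "ewald_radius",
    "axial_frequency",
    "build_shell",
    "scan_schedule",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Cartesian sampling grid shared by a volume and its spectrum.

    Axes are ordered (x, y, z); the frequency coordinate of index i along an
    axis of length N with pitch Δ is (i − N//2)/(N·Δ).
    """

    shape: tuple[int, int, int]
    voxel_pitch: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.voxel_pitch) != 3:
            raise ValueError("shape and voxel_pitch must be 3-tuples")
        if any(int(n) < 2 for n in self.shape):
            raise ValueError(f"all shape components must be >= 2, got {self.shape}")
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError(f"voxel pitches must be positive, got {self.voxel_pitch}")

    @property
    def freq_pitch(self) -> tuple[float, float, float]:
        """Frequency spacing (Δk_x, Δk_y, Δk_z) in cycles/μm."""
        return tuple(1.0 / (n * p) for n, p in zip(self.shape, self.voxel_pitch))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_pitch))

    @property
    def pixel_area(self) -> float:
        return self.voxel_pitch[0] * self.voxel_pitch[1]

    def freq_axis(self, axis: int) -> np.ndarray:
        """Frequency coordinates along one axis, zero at index N//2."""
        n = self.shape[axis]
        return (np.arange(n) - n // 2) * self.freq_pitch[axis]

    def space_axis(self, axis: int) -> np.ndarray:
        """Spatial coordinates along one axis, zero at index N//2."""
        n = self.shape[axis]
        return (np.arange(n) - n // 2) * self.voxel_pitch[axis]


@dataclass(frozen=True)
class EwaldShell:
    """Discretized Ewald cap for one wavelength on a fixed grid.

    Each entry corresponds to one lateral frequency voxel (ix, iy) inside the
    propagating-wave disk |k_T| < k_m.  ``iz`` is the axial index of the
    nearest spectrum voxel to k_z − k_m (the cap after the k − k_in shift);
    ``prefactor`` is the Fourier-diffraction-theorem factor
    j/(4π k_z)·exp(2πj (k_z − k_m) z_D) in the package's envelope convention
    (the incident plane-wave carrier is divided out of all fields).
    """

    wavelength: float
    n_m: float
    k_m: float
    z_D: float
    grid: FrequencyGrid
    ix: np.ndarray = field(repr=False)
    iy: np.ndarray = field(repr=False)
    iz: np.ndarray = field(repr=False)
    kx: np.ndarray = field(repr=False)
    ky: np.ndarray = field(repr=False)
    kz: np.ndarray = field(repr=False)
    prefactor: np.ndarray = field(repr=False)

    @property
    def n_samples(self) -> int:
        return int(self.ix.size)

    def target_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Index arrays addressing the shifted cap voxels in the 3D spectrum."""
        return self.ix, self.iy, self.iz


def ewald_radius(wavelength: float, n_m: float) -> float:
    """Ewald-sphere radius k_m = n_m/λ in cycles/μm.

    Parameters
    ----------
    wavelength : float
        Vacuum illumination wavelength in μm (> 0).
    n_m : float
        Refractive index of the surrounding medium (≥ 1).
    """
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength}")
    if n_m < 1:
        raise ValueError(f"medium refractive index must be >= 1, got {n_m}")
    return n_m / wavelength


def axial_frequency(k_T, k_m: float):
    """Axial frequency k_z = √(k_m² − k_T²) of an on-shell sample.

    Evanescent samples (k_T ≥ k_m) are flagged with NaN rather than raising:
    callers drop them from the shell support.  Accepts scalars or arrays.
    """
    k_T = np.asarray(k_T, dtype=float)
    if np.any(k_T < 0):
        raise ValueError("lateral frequency magnitude must be non-negative")
    rad = k_m * k_m - k_T * k_T
    out = np.where(rad > 0, np.sqrt(np.maximum(rad, 0.0)), np.nan)
    return out if out.ndim else float(out)


def scan_schedule(lambda_min: float, lambda_max: float, count: int) -> np.ndarray:
    """Uniform, inclusive, ascending wavelength schedule (μm)."""
    if count < 2:
        raise ValueError(f"schedule needs at least 2 wavelengths, got {count}")
    if not lambda_min < lambda_max:
        raise ValueError(f"need lambda_min < lambda_max, got {lambda_min}, {lambda_max}")
    if lambda_min <= 0:
        raise ValueError("wavelengths must be positive")
    return np.linspace(lambda_min, lambda_max, count)


def build_shell(
    grid: FrequencyGrid, wavelength: float, n_m: float, z_D: float
) -> EwaldShell:
    """Precompute the discretized Ewald cap for one wavelength.

    One sample per lateral frequency voxel with |k_T| < k_m; the target 3D
    voxel is the nearest voxel to (k_x, k_y, k_z − k_m).  Samples whose
    shifted axial index falls outside the grid are truncated with a warning.
    """
    k_m = ewald_radius(wavelength, n_m)
    dkx, dky, dkz = grid.freq_pitch
    if k_m < min(dkx, dky):
        raise ValueError(
            f"empty shell support: k_m={k_m:.4g} cycles/um is below the lateral "
            f"frequency pitch {min(dkx, dky):.4g}; enlarge the grid"
        )

    kx_ax = grid.freq_axis(0)
    ky_ax = grid.freq_axis(1)
    KX, KY = np.meshgrid(kx_ax, ky_ax, indexing="ij")
    kT2 = KX * KX + KY * KY
    support = kT2 < k_m * k_m

    ix, iy = np.nonzero(support)
    kx = KX[support]
    ky = KY[support]
    kz = np.sqrt(k_m * k_m - kT2[support])

    nz = grid.shape[2]
    iz = (nz // 2 + np.floor((kz - k_m) / dkz + 0.5)).astype(np.intp)
    inside = (iz >= 0) & (iz < nz)
    if not np.all(inside):
        warnings.warn(
            "Ewald cap truncated: the shifted shell does not fit inside the "
            "axial frequency extent; dropping out-of-range samples",
            stacklevel=2,
        )
        ix, iy, iz = ix[inside], iy[inside], iz[inside]
        kx, ky, kz = kx[inside], ky[inside], kz[inside]

    prefactor = (1j / (4.0 * np.pi * kz)) * np.exp(2j * np.pi * (kz - k_m) * z_D)

    return EwaldShell(
        wavelength=float(wavelength),
        n_m=float(n_m),
        k_m=float(k_m),
        z_D=float(z_D),
        grid=grid,
        ix=ix,
        iy=iy,
        iz=iz,
        kx=kx,
        ky=ky,
        kz=kz,
        prefactor=prefactor,
    )
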