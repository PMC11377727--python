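"""Scan and reconstruction configuration.

A single :class:`ScanConfig` carries everything a simulation or a
reconstruction needs: the wavelength schedule, medium index, defocus
distance, sensor geometry, the pixel-super-resolution upsampling factor,
solver relaxation/iteration settings, regularization settings, and the RNG
seed.  Defaults mirror a 57-wavelength 430–1200 nm acquisition on a 1.67 μm
sensor with upsampling factor 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kspace import scan_schedule

__all__ = ["ScanConfig", "ConfigError"]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


def _default_schedule() -> tuple[float, ...]:
    return tuple(scan_schedule(0.43, 1.20, 57))


@dataclass
class ScanConfig:
    """Study conditions for one wavelength-scanning acquisition.

    Attributes
    ----------
    wavelengths : tuple of float
        Ascending illumination schedule in μm.
    n_m : float
        Refractive index of the immersion/mounting medium.
    z_D : float
        Sample-to-sensor defocus distance in μm.
    sensor_pitch : float
        Physical sensor pixel pitch in μm.
    upsample : int
        Pixel-super-resolution factor s (reconstruction pitch = pitch/s).
    alpha : float
        Relaxation factor of the intensity constraint, in [0, 1].
    passes : int
        Outer iterations over the full wavelength schedule.
    nz, dz : int, float
        Axial voxel count and pitch (μm) of the reconstruction grid.
    reg_passes, tv_weight, tv_iters, nonneg
        Hybrid missing-cone regularization settings; ``tv_weight=None``
        scales the weight to 2% of the maximum recovered contrast.
    guard : int
        Guard band (high-resolution pixels per side) cropped from simulated
        frames to suppress periodic wrap-around; 0 keeps frames periodic.
    photons, read_noise
        Simulation noise model: Poisson photon budget per pixel (None =
        noiseless) and additive Gaussian read noise (std, intensity units).
    tile, min_overlap : int
        Full-field tiling defaults (pixels).
    """

    wavelengths: tuple[float, ...] = field(default_factory=_default_schedule)
    n_m: float = 1.33
    z_D: float = 400.0
    sensor_pitch: float = 1.67
    upsample: int = 4
    alpha: float = 0.5
    passes: int = 3
    nz: int = 64
    dz: float = 1.0
    reg_passes: int = 20
    tv_weight: float | None = None
    tv_iters: int = 10
    nonneg: bool = True
    guard: int = 32
    photons: float | None = None
    read_noise: float = 0.0
    tile: int = 500
    min_overlap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = tuple(float(w) for w in np.sort(np.asarray(self.wavelengths)))
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        if len(self.wavelengths) < 1:
            problems.append("wavelength schedule is empty")
        if any(w <= 0 for w in self.wavelengths):
            problems.append("wavelengths must be positive")
        if self.n_m < 1:
            problems.append(f"n_m must be >= 1, got {self.n_m}")
        if not (0.0 <= self.alpha <= 1.0):
            problems.append(f"alpha must lie in [0, 1], got {self.alpha}")
        if int(self.upsample) < 1 or self.upsample != int(self.upsample):
            problems.append(f"upsample must be an integer >= 1, got {self.upsample}")
        if self.sensor_pitch <= 0:
            problems.append("sensor_pitch must be positive")
        if self.passes < 1:
            problems.append("passes must be >= 1")
        if self.nz < 2 or self.dz <= 0:
            problems.append("reconstruction grid needs nz >= 2 and dz > 0")
        if self.reg_passes < 0 or self.tv_iters < 1:
            problems.append("regularization needs reg_passes >= 0 and tv_iters >= 1")
        if self.tv_weight is not None and self.tv_weight < 0:
            problems.append("tv_weight must be >= 0")
        if self.guard < 0:
            problems.append("guard must be >= 0")
        if not (0 <= self.min_overlap < self.tile):
            problems.append("need 0 <= min_overlap < tile")
        if problems:
            raise ConfigError("; ".join(problems))

    def with_(self, **kwargs) -> "ScanConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    @property
    def hires_pitch(self) -> float:
        """Lateral pitch of the super-resolved reconstruction grid (μm)."""
        return self.sensor_pitch / int(self.upsample)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
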