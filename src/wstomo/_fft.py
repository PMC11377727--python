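"""Centered discrete Fourier transforms approximating the continuous FT.

Conventions used throughout the package (reduced frequencies, cycles/μm):

    f̂(ν) = ∫ f(r) exp(−2πj ν·r) dr          (analysis)
    f(r) = ∫ f̂(ν) exp(+2πj ν·r) dν          (synthesis)

The spatial coordinate of array index i is (i − N//2)·Δ and the frequency
coordinate of index i is (i − N//2)·Δν with Δν = 1/(N·Δ); both origins sit
at index N//2, hence the fftshift/ifftshift sandwiches below.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c", "fft3c", "ifft3c"]


def fft3c(x: np.ndarray, voxel_volume: float) -> np.ndarray:
    """3D centered FT of a volume; ``voxel_volume`` = Δx·Δy·Δz (μm³)."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x))) * voxel_volume


def ifft3c(X: np.ndarray, voxel_volume: float) -> np.ndarray:
    """Inverse of :func:`fft3c` (divides by the voxel volume)."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(X))) / voxel_volume


def fft2c(x: np.ndarray, pixel_area: float) -> np.ndarray:
    """2D centered FT of a lateral field; ``pixel_area`` = Δx·Δy (μm²)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x))) * pixel_area


def ifft2c(X: np.ndarray, pixel_area: float) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(X))) / pixel_area
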