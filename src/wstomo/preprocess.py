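"""Raw-stack conditioning: background normalization and autofocus.

On-axis illumination means a single defocus distance z_D serves the whole
stack (no per-wavelength registration); z_D is estimated once from the
shortest-wavelength frame by scanning an angular-spectrum back-propagation
over candidate distances.
"""

from __future__ import annotations

import numpy as np

from .forward import IntensityFrame

__all__ = ["normalize_intensity", "autofocus", "tamura_of_gradient"]


def _border_median(data: np.ndarray, width: int = 8) -> float:
    w = min(width, min(data.shape) // 2)
    if w == 0:
        return float(np.median(data))
    ring = np.concatenate(
        [
            data[:w, :].ravel(),
            data[-w:, :].ravel(),
            data[w:-w, :w].ravel(),
            data[w:-w, -w:].ravel(),
        ]
    )
    return float(np.median(ring))


def normalize_intensity(frame: IntensityFrame) -> IntensityFrame:
    """Divide by the background estimate so the background level is 1.

    The background is the median of an 8-pixel border ring, which is robust
    to sample content concentrated in the frame interior.  Idempotent.
    """
    if np.mean(frame.data) <= 0:
        raise ValueError("frame has non-positive mean; cannot normalize")
    bg = _border_median(frame.data)
    if bg <= 0:
        raise ValueError("background estimate is non-positive; cannot normalize")
    return IntensityFrame(frame.data / bg, frame.wavelength, frame.z_D,
                          frame.pitch, frame.bit_depth)


def tamura_of_gradient(amplitude: np.ndarray) -> float:
    """Tamura coefficient √(σ/μ) of the gradient magnitude of an image.

    An edge-sparsity focus criterion: for in-line holograms of predominantly
    phase samples it exhibits a sharp valley at the true focus (the focused
    amplitude of a phase object is nearly flat), and a peak for absorbing
    samples.
    """
    gx, gy = np.gradient(amplitude)
    g = np.hypot(gx, gy)
    mu = float(np.mean(g))
    if mu <= 0:
        return 0.0
    return float(np.sqrt(np.std(g) / mu))


def _backpropagate(amplitude: np.ndarray, pitch: float, wavelength: float,
                   n_m: float, z: float) -> np.ndarray:
    """Angular-spectrum envelope propagation of a detector field by −z."""
    nx, ny = amplitude.shape
    kx = np.fft.fftfreq(nx, d=pitch)
    ky = np.fft.fftfreq(ny, d=pitch)
    KX, KY = np.meshgrid(kx, ky, indexing="ij")
    k_m = n_m / wavelength
    rad = k_m * k_m - KX * KX - KY * KY
    kz = np.sqrt(np.maximum(rad, 0.0))
    kernel = np.where(rad > 0, np.exp(-2j * np.pi * (kz - k_m) * z), 0.0)
    return np.fft.ifft2(np.fft.fft2(amplitude) * kernel)


def autofocus(frame: IntensityFrame, wavelength: float, n_m: float,
              z_range: tuple[float, float, float]) -> float:
    """Estimate the defocus distance z_D from one frame.

    Back-propagates the contrast hologram I/bg − 1 over the candidate grid
    and returns the distance maximizing the Tamura-of-gradient criterion of
    the refocused amplitude: the scattered field is sharpest (edge-sparsest)
    at the object plane.  Ties break toward smaller z.  Dividing by the
    border-median background makes the estimate invariant to global
    intensity scaling.
    """
    z_lo, z_hi, step = z_range
    if not (z_lo < z_hi) or step <= 0:
        raise ValueError(f"invalid search range {z_range}")
    bg = _border_median(frame.data)
    if bg <= 0:
        raise ValueError("non-positive background; normalize/check the frame")
    holo = (frame.data / bg - 1.0).astype(complex)
    candidates = np.arange(z_lo, z_hi + step / 2, step)
    scores = np.array(
        [
            tamura_of_gradient(np.abs(_backpropagate(holo, frame.pitch, wavelength, n_m, z)))
            for z in candidates
        ]
    )
    if np.max(scores) < 1e-9 or np.ptp(scores) < 1e-6 * np.max(scores):
        raise ValueError("no focus structure: criterion is flat on this frame")
    return float(candidates[int(np.argmax(scores))])
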