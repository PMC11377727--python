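"""Hybrid missing-cone completion.

Gerchberg–Papoulis-style alternation: inverse transform → non-negativity
projection of the real contrast → isotropic 3D total-variation denoising →
forward transform → re-imposition of the measured shell voxels.  Voxels the
scan never measured (fill weight 0) keep the regularized values; measured
voxels are restored bit-identically after every pass.
"""

from __future__ import annotations

import numpy as np
from skimage.restoration import denoise_tv_chambolle

from ._fft import fft3c, ifft3c

__all__ = ["nonneg_project", "tv_denoise", "hybrid_fill"]


def nonneg_project(v: np.ndarray) -> np.ndarray:
    """Clip the real contrast at zero from below (sample at least as dense
    as its medium).  Idempotent."""
    return np.maximum(np.asarray(v), 0.0)


def tv_denoise(vol: np.ndarray, weight: float, n_iter: int = 10) -> np.ndarray:
    """Isotropic 3D TV denoising (Chambolle dual projection).

    weight = 0 is the identity; the TV seminorm never increases and the mean
    is preserved (the update is a divergence field with zero mean).
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    vol = np.asarray(vol, dtype=float)
    if weight == 0:
        return vol.copy()
    return denoise_tv_chambolle(vol, weight=weight, max_num_iter=int(n_iter))


def hybrid_fill(spectrum, passes: int, tv_weight: float, tv_iters: int = 10,
                nonneg: bool = True):
    """Fill unmeasured spectrum voxels by alternating projections.

    Operates on a :class:`~wstomo.recon.PotentialSpectrum` in place and
    returns it.  Non-negativity acts on the real part of the scattering
    potential (the contrast n² − n_m² carries the same sign); the imaginary
    part is zeroed, appropriate when absorption is not modeled.
    """
    if passes == 0:
        return spectrum
    measured = spectrum.weights > 0
    saved = spectrum.data[measured].copy()
    voxvol = spectrum.grid.voxel_volume
    for _ in range(int(passes)):
        v = ifft3c(spectrum.data, voxvol).real
        if nonneg:
            v = nonneg_project(v)
        if tv_weight > 0:
            v = tv_denoise(v, tv_weight, tv_iters)
        spectrum.data = fft3c(v.astype(complex), voxvol)
        spectrum.data[measured] = saved
    return spectrum
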