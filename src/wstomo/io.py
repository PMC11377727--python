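"""File formats and configuration loading.

Raw stacks travel as multi-page 16-bit grayscale TIFF (one page per
wavelength, schedule order) plus a JSON sidecar carrying wavelengths (nm),
z_D, pixel pitch, medium RI, the quantization scale and the seed.  The
recorded scale makes 16-bit quantization exactly invertible.  3D volumes go
to HDF5 (complex RI stored as two real datasets with pitch/medium/wavelength
attributes); configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .config import ConfigError, ScanConfig
from .forward import IntensityFrame
from .kspace import EwaldShell, FrequencyGrid
from .phantoms import RIVolume

__all__ = [
    "write_stack",
    "read_stack",
    "save_volume",
    "load_volume",
    "load_config",
    "save_shell",
    "load_shell",
]

_SIDECAR_KEYS = ("wavelengths_nm", "z_D_um", "pixel_pitch_um", "n_m", "scale")


def write_stack(path, frames: list[IntensityFrame], n_m: float, seed: int = 0,
                sidecar: str | Path | None = None) -> Path:
    """Write frames as a multi-page 16-bit TIFF with a JSON sidecar.

    Intensities are quantized as round(I·scale) with one global scale chosen
    so the stack maximum maps to 60000 (headroom below the uint16 ceiling);
    the scale is recorded in the sidecar so reading is exactly invertible.
    """
    path = Path(path)
    stack = np.stack([f.data for f in frames])
    peak = float(stack.max())
    scale = 60000.0 / peak if peak > 0 else 1.0
    quantized = np.round(stack * scale).astype(np.uint16)
    tifffile.imwrite(path, quantized, photometric="minisblack")

    meta = {
        "wavelengths_nm": [float(f.wavelength * 1e3) for f in frames],
        "z_D_um": float(frames[0].z_D),
        "pixel_pitch_um": float(frames[0].pitch),
        "n_m": float(n_m),
        "scale": scale,
        "seed": int(seed),
        "bit_depth": 16,
    }
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path, sidecar=None):
    """Read a TIFF stack + sidecar back into frames and metadata.

    Sidecar wavelengths in nm are converted to μm on load; the page count
    must match the wavelength count.  Returns ``(frames, meta)``.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} is missing keys: {missing}")
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[None]
    wavelengths_um = [w / 1e3 for w in meta["wavelengths_nm"]]
    if raw.shape[0] != len(wavelengths_um):
        raise ValueError(
            f"{raw.shape[0]} TIFF pages but {len(wavelengths_um)} sidecar wavelengths"
        )
    frames = [
        IntensityFrame(page.astype(float) / meta["scale"], lam,
                       meta["z_D_um"], meta["pixel_pitch_um"])
        for page, lam in zip(raw, wavelengths_um)
    ]
    return frames, meta


def save_volume(path, vol: RIVolume) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("ri_real", data=vol.data.real)
        f.create_dataset("ri_imag", data=vol.data.imag)
        f.attrs["voxel_pitch_um"] = vol.voxel_pitch
        f.attrs["n_m"] = vol.n_m
        f.attrs["annotation_json"] = json.dumps(vol.annotation, default=str)
    return path


def load_volume(path) -> RIVolume:
    with h5py.File(path, "r") as f:
        data = f["ri_real"][()] + 1j * f["ri_imag"][()]
        pitch = tuple(float(p) for p in f.attrs["voxel_pitch_um"])
        n_m = float(f.attrs["n_m"])
        ann = json.loads(f.attrs.get("annotation_json", "{}"))
    return RIVolume(data, pitch, n_m, ann)


def load_config(path) -> ScanConfig:
    """Load a YAML config, filling defaults and validating invariants.

    Unknown keys raise; an unsorted schedule is sorted with a warning-level
    normalization inside ScanConfig.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} did not parse to a mapping")
    fields = set(ScanConfig.__dataclass_fields__)
    unknown = set(raw) - fields
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "wavelengths" in raw:
        raw["wavelengths"] = tuple(float(w) for w in raw["wavelengths"])
    return ScanConfig(**raw)


def _shell_key(shell: EwaldShell) -> str:
    g = shell.grid
    return (
        f"shape={g.shape}_pitch={tuple(round(p, 9) for p in g.voxel_pitch)}_"
        f"lam={shell.wavelength:.9g}_nm={shell.n_m:.9g}_zD={shell.z_D:.9g}"
    )


def save_shell(path, shell: EwaldShell) -> str:
    """Append a shell to an HDF5 cache; returns its key."""
    key = _shell_key(shell)
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        grp = f.create_group(key)
        for name in ("ix", "iy", "iz", "kx", "ky", "kz", "prefactor"):
            grp.create_dataset(name, data=getattr(shell, name))
        grp.attrs.update(
            wavelength=shell.wavelength, n_m=shell.n_m, k_m=shell.k_m,
            z_D=shell.z_D, shape=shell.grid.shape, pitch=shell.grid.voxel_pitch,
        )
    return key


def load_shell(path, key: str) -> EwaldShell:
    with h5py.File(path, "r") as f:
        grp = f[key]
        grid = FrequencyGrid(
            tuple(int(n) for n in grp.attrs["shape"]),
            tuple(float(p) for p in grp.attrs["pitch"]),
        )
        return EwaldShell(
            wavelength=float(grp.attrs["wavelength"]),
            n_m=float(grp.attrs["n_m"]),
            k_m=float(grp.attrs["k_m"]),
            z_D=float(grp.attrs["z_D"]),
            grid=grid,
            ix=grp["ix"][()],
            iy=grp["iy"][()],
            iz=grp["iz"][()],
            kx=grp["kx"][()],
            ky=grp["ky"][()],
            kz=grp["kz"][()],
            prefactor=grp["prefactor"][()],
        )
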