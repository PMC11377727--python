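"""Seeded 3D refractive-index phantoms with ground-truth annotations.

All generators return an :class:`RIVolume` whose annotation records the true
object parameters, so every downstream stage (forward model, solver,
morphology metrics) can be validated without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kspace import FrequencyGrid

__all__ = [
    "RIVolume",
    "bead_phantom",
    "usaf_phase_target",
    "bar_pair_phantom",
    "cell_phantom",
    "usaf_line_width",
]


@dataclass
class RIVolume:
    """Complex 3D refractive-index grid n(r), axes (x, y, z).

    Real part: refractive index (≥ 1 everywhere); imaginary part: absorption
    (≥ 0, zero by default).  Lateral pitches must be equal.
    """

    data: np.ndarray
    voxel_pitch: tuple[float, float, float]
    n_m: float
    annotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("RIVolume data must be 3D")
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError("voxel pitches must be strictly positive")
        if not np.isclose(self.voxel_pitch[0], self.voxel_pitch[1]):
            raise ValueError("lateral pitches must be equal")
        if np.min(self.data.real) < 1.0:
            raise ValueError("refractive index must be >= 1 everywhere")
        if np.min(self.data.imag) < 0.0:
            raise ValueError("absorption (imaginary part) must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def grid(self) -> FrequencyGrid:
        return FrequencyGrid(self.shape, self.voxel_pitch)

    def contrast(self) -> np.ndarray:
        """Real refractive-index contrast Re(n) − n_m."""
        return self.data.real - self.n_m


def _coordinate_grids(shape, pitch):
    axes = [(np.arange(n) - n // 2) * p for n, p in zip(shape, pitch)]
    return np.meshgrid(*axes, indexing="ij")


def bead_phantom(shape, pitch, beads, n_m, seed: int = 0) -> RIVolume:
    """Spherical-bead phantom (e.g. polystyrene in index-matching oil).

    Parameters
    ----------
    beads : list of (center, diameter, ri)
        ``center`` is an (x, y, z) position in μm relative to the volume
        center, ``diameter`` in μm, ``ri`` the bead refractive index.
    """
    shape = tuple(int(n) for n in shape)
    pitch = tuple(float(p) for p in pitch)
    n = np.full(shape, float(n_m), dtype=float)
    X, Y, Z = _coordinate_grids(shape, pitch)
    lo = [float(a.min()) for a in (X, Y, Z)]
    hi = [float(a.max()) for a in (X, Y, Z)]

    records = []
    for b, (center, diameter, ri) in enumerate(beads):
        r = diameter / 2.0
        if diameter < 2 * pitch[0]:
            raise ValueError(f"bead {b}: diameter {diameter} below 2 lateral voxels")
        for c, l, h in zip(center, lo, hi):
            if c - r < l or c + r > h:
                raise ValueError(
                    f"bead {b} at {tuple(center)} with diameter {diameter} "
                    "does not fit inside the volume"
                )
        inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 < r * r
        n[inside] = ri
        records.append(
            {
                "center_um": tuple(float(c) for c in center),
                "diameter_um": float(diameter),
                "ri": float(ri),
                "voxels": int(np.count_nonzero(inside)),
            }
        )

    ann = {"kind": "beads", "beads": records, "seed": seed}
    return RIVolume(n.astype(complex), pitch, float(n_m), ann)


def usaf_line_width(group: int, element: int) -> float:
    """USAF-1951 line width in μm: 500·2^{−(G+(E−1)/6)}."""
    if not 1 <= element <= 6:
        raise ValueError(f"element must be in 1..6, got {element}")
    return 500.0 * 2.0 ** (-(group + (element - 1) / 6.0))


def usaf_phase_target(
    shape,
    pitch,
    groups,
    thickness: float,
    dn: float,
    tilt_deg: float = 0.0,
    n_m: float = 1.0,
) -> RIVolume:
    """Tilted phase-resolution target with USAF-1951 three-bar elements.

    Each requested (group, element) becomes a three-bar pattern (bar width w,
    length 5w, spacing w), orientation alternating between elements, extruded
    to ``thickness`` μm and rotated about the y-axis by ``tilt_deg`` with
    nearest-voxel resampling.  RI is n_m + dn inside the bars.
    """
    shape = tuple(int(n) for n in shape)
    pitch = tuple(float(p) for p in pitch)
    if abs(tilt_deg) >= 45:
        raise ValueError("|tilt_deg| must be < 45")

    widths = []
    for g, e in groups:
        w = usaf_line_width(g, e)
        if w < 2 * pitch[0]:
            raise ValueError(
                f"element (G={g}, E={e}) line width {w:.4g} um is below the "
                f"2-voxel sampling limit at pitch {pitch[0]} um"
            )
        widths.append(w)

    mask = np.zeros(shape[:2], dtype=bool)
    x_ax = (np.arange(shape[0]) - shape[0] // 2) * pitch[0]
    y_ax = (np.arange(shape[1]) - shape[1] // 2) * pitch[1]
    X, Y = np.meshgrid(x_ax, y_ax, indexing="ij")

    # Pack elements along x, centered as a block.
    margin = max(widths)
    spans = [5 * w + margin for w in widths]
    total = sum(spans)
    x0 = -total / 2.0
    placed = []
    for idx, ((g, e), w) in enumerate(zip(groups, widths)):
        cx = x0 + sum(spans[:idx]) + spans[idx] / 2.0
        horizontal = idx % 2 == 0
        for bar in range(3):
            off = (bar - 1) * 2 * w  # bar centers separated by 2w (width + gap)
            if horizontal:
                sel = (np.abs(X - (cx + off)) < w / 2) & (np.abs(Y) < 2.5 * w)
            else:
                sel = (np.abs(Y - off) < w / 2) & (np.abs(X - cx) < 2.5 * w)
            mask |= sel
        placed.append({"group": g, "element": e, "line_width_um": w, "center_x_um": cx})

    nz = shape[2]
    z_ax = (np.arange(nz) - nz // 2) * pitch[2]
    slab = np.abs(z_ax) < thickness / 2.0
    if not slab.any():
        slab[nz // 2] = True  # thinner than one voxel: keep a single slice
    vol = np.zeros(shape, dtype=bool)
    vol[:, :, slab] = mask[:, :, None]

    if tilt_deg != 0.0:
        vol = ndimage.rotate(
            vol.astype(np.uint8), tilt_deg, axes=(0, 2), reshape=False, order=0
        ).astype(bool)

    n = np.full(shape, float(n_m), dtype=float)
    n[vol] = n_m + dn
    ann = {
        "kind": "usaf",
        "elements": placed,
        "thickness_um": float(thickness),
        "dn": float(dn),
        "tilt_deg": float(tilt_deg),
        "voxels": int(np.count_nonzero(vol)),
    }
    return RIVolume(n.astype(complex), pitch, float(n_m), ann)


def bar_pair_phantom(
    shape, pitch, bar_width: float, gap: float, thickness: float, dn: float,
    n_m: float, x_offset: float = 0.0
) -> RIVolume:
    """Two parallel bars separated by a narrow gap (resolution test object).

    Bars run along y with length 5×(width+gap); the gap center sits at
    ``x_offset`` μm so the sampling phase relative to the sensor grid can be
    controlled (a resolution claim should not hinge on a pixel boundary
    happening to fall inside the gap).
    """
    shape = tuple(int(n) for n in shape)
    pitch = tuple(float(p) for p in pitch)
    X, Y, Z = _coordinate_grids(shape, pitch)
    half_gap = gap / 2.0
    length = 5.0 * (bar_width + gap)
    xc = X - x_offset
    in_bar_x = (np.abs(xc) > half_gap) & (np.abs(xc) < half_gap + bar_width)
    sel = in_bar_x & (np.abs(Y) < length / 2.0) & (np.abs(Z) < thickness / 2.0)
    n = np.full(shape, float(n_m), dtype=float)
    n[sel] = n_m + dn
    ann = {
        "kind": "bar_pair",
        "bar_width_um": float(bar_width),
        "gap_um": float(gap),
        "x_offset_um": float(x_offset),
        "bar_centers_x_um": (x_offset - (half_gap + bar_width / 2),
                             x_offset + (half_gap + bar_width / 2)),
        "thickness_um": float(thickness),
        "dn": float(dn),
        "voxels": int(np.count_nonzero(sel)),
    }
    return RIVolume(n.astype(complex), pitch, float(n_m), ann)


# --- cell-like phantoms -----------------------------------------------------

_STAGES = ("I", "II", "III")


def _ellipsoid_mask(X, Y, Z, center, radii, rotation=None):
    d = np.stack([X - center[0], Y - center[1], Z - center[2]])
    if rotation is not None:
        d = np.einsum("ij,j...->i...", rotation, d)
    return (d[0] / radii[0]) ** 2 + (d[1] / radii[1]) ** 2 + (d[2] / radii[2]) ** 2 < 1.0


def _rot_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _analytic_ellipsoid(radii):
    """Volume and Knud-Thomsen approximate surface area of an ellipsoid."""
    a, b, c = radii
    vol = 4.0 / 3.0 * np.pi * a * b * c
    p = 1.6075
    area = 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)
    return vol, area


def cell_phantom(shape, pitch, n_cells: int, stage_mix, seed: int = 0,
                 n_m: float = 1.34, dn: float = 0.03) -> RIVolume:
    """Macrophage-like blob phantom with three morphological growth stages.

    Stage I: round/oval cells (near-unit sphericity).  Stage II: round body
    with short pseudopods.  Stage III: elongated, shuttle-shaped body with
    long pseudopods.  Placement is rejection-sampled without overlap;
    deterministic for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    stage_mix = np.asarray(stage_mix, dtype=float)
    if stage_mix.shape != (3,) or not np.isclose(stage_mix.sum(), 1.0):
        raise ValueError("stage_mix must be 3 fractions summing to 1")

    shape = tuple(int(n) for n in shape)
    pitch = tuple(float(p) for p in pitch)
    rng = np.random.default_rng(seed)
    X, Y, Z = _coordinate_grids(shape, pitch)
    occupied = np.zeros(shape, dtype=bool)
    n = np.full(shape, float(n_m), dtype=float)

    counts = np.floor(stage_mix * n_cells).astype(int)
    while counts.sum() < n_cells:  # remainder to the largest fractions
        counts[int(np.argmax(stage_mix * n_cells - counts))] += 1
    labels = [s for s, c in zip(_STAGES, counts) for _ in range(c)]

    half_extent = [(s // 2) * p for s, p in zip(shape, pitch)]
    cells = []
    for cid, stage in enumerate(labels, start=1):
        base_r = rng.uniform(3.0, 4.5)  # μm body radius, mononuclear scale
        placed_mask = None
        for _ in range(200):
            if stage == "I":
                radii = base_r * rng.uniform(0.95, 1.05, size=3)
                rot = None
            elif stage == "II":
                radii = base_r * rng.uniform(0.9, 1.1, size=3)
                rot = _rot_z(rng.uniform(0, np.pi))
            else:
                radii = np.array([2.2 * base_r, 0.55 * base_r, 0.55 * base_r])
                rot = _rot_z(rng.uniform(0, np.pi))
            pod_len = {"I": 0.0, "II": 0.8, "III": 1.4}[stage] * base_r
            # lateral footprint: body plus pseudopod reach, with one voxel slack
            reach = max(float(np.max(radii)),
                        0.7 * float(np.max(radii[:2])) + pod_len) + pitch[0]
            center = [
                rng.uniform(-h + reach, h - reach) if h > reach else 0.0
                for h in half_extent
            ]
            mask = _ellipsoid_mask(X, Y, Z, center, radii, rot)
            if stage in ("II", "III"):
                n_pods = rng.integers(3, 6)
                for _p in range(int(n_pods)):
                    theta = rng.uniform(0, 2 * np.pi)
                    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
                    tip = np.asarray(center) + direction * (
                        np.max(radii[:2]) * 0.7 + pod_len / 2
                    )
                    mask |= _ellipsoid_mask(
                        X, Y, Z, tip, (pod_len / 2, base_r * 0.22, base_r * 0.22),
                        _rot_z(theta),
                    )
            if not (mask & occupied).any() and mask.any():
                placed_mask = mask
                break
        if placed_mask is None:
            raise ValueError(
                f"could not place cell {cid} (stage {stage}) without overlap "
                "after 200 attempts; reduce n_cells or enlarge the volume"
            )
        occupied |= placed_mask
        n[placed_mask] = n_m + dn
        vox = int(np.count_nonzero(placed_mask))
        a_vol, a_area = _analytic_ellipsoid(radii)
        sph = np.pi ** (1 / 3) * (6 * a_vol) ** (2 / 3) / a_area
        cells.append(
            {
                "label": cid,
                "stage": stage,
                "center_um": tuple(float(c) for c in center),
                "radii_um": tuple(float(r) for r in radii),
                "voxels": vox,
                "volume_um3": vox * float(np.prod(pitch)),
                "body_volume_analytic_um3": float(a_vol),
                "body_surface_analytic_um2": float(a_area),
                "body_sphericity_analytic": float(sph),
            }
        )

    ann = {"kind": "cells", "cells": cells, "dn": float(dn), "seed": seed,
           "stage_mix": tuple(float(f) for f in stage_mix)}
    return RIVolume(n.astype(complex), pitch, float(n_m), ann)
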