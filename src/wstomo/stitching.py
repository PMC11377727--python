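"""Full-field tiling and alpha-blended recombination.

A large sensor frame is split into equal-sized overlapping tiles (the
defaults reproduce a 9×7 grid of 500×500 tiles with ≥50 px overlap on a
3872×2764 frame); per-tile reconstructions are recombined with separable
linear-ramp weights normalized to a partition of unity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TilePlan", "plan_tiles", "alpha_blend", "upsampled_output_shape"]


@dataclass(frozen=True)
class TilePlan:
    frame_shape: tuple[int, int]
    tile: int
    min_overlap: int
    offsets: tuple[tuple[int, int], ...]

    @property
    def grid_shape(self) -> tuple[int, int]:
        xs = sorted({o[0] for o in self.offsets})
        ys = sorted({o[1] for o in self.offsets})
        return len(xs), len(ys)

    def to_dict(self) -> dict:
        return {
            "frame_shape": list(self.frame_shape),
            "tile": self.tile,
            "min_overlap": self.min_overlap,
            "offsets": [list(o) for o in self.offsets],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TilePlan":
        return cls(
            tuple(d["frame_shape"]), int(d["tile"]), int(d["min_overlap"]),
            tuple(tuple(o) for o in d["offsets"]),
        )


def _axis_offsets(length: int, tile: int, min_overlap: int) -> list[int]:
    if tile > length:
        raise ValueError(f"tile {tile} exceeds frame dimension {length}")
    if length == tile:
        return [0]
    count = math.ceil((length - tile) / (tile - min_overlap)) + 1
    span = length - tile
    base, rem = divmod(span, count - 1)
    # Remainder spread as extra overlap; earlier gaps take the smaller step
    # (i.e. the extra pixel of overlap) — deterministic tie-break.
    steps = [base] * (count - 1 - rem) + [base + 1] * rem
    offsets = [0]
    for st in steps:
        offsets.append(offsets[-1] + st)
    return offsets


def plan_tiles(frame_shape, tile: int, min_overlap: int) -> TilePlan:
    """Plan equal-sized, axis-aligned tiles covering the frame.

    Per axis the tile count is ceil((L − tile)/(tile − min_overlap)) + 1;
    offsets spread evenly with the remainder distributed as extra overlap,
    and the last tile sits flush with the frame edge.
    """
    if not 0 <= min_overlap < tile:
        raise ValueError("need 0 <= min_overlap < tile")
    fx, fy = int(frame_shape[0]), int(frame_shape[1])
    ox = _axis_offsets(fx, tile, min_overlap)
    oy = _axis_offsets(fy, tile, min_overlap)
    offsets = tuple((x, y) for x in ox for y in oy)
    return TilePlan((fx, fy), int(tile), int(min_overlap), offsets)


def _axis_weight(offsets: list[int], origin: int, tile: int, length: int) -> np.ndarray:
    """Linear ramp over the overlap with each neighbour, flat 1 inside.

    Within an overlap of size r the two neighbours get weights
    (r−j)/(r+1) and (j+1)/(r+1), an exact partition of unity that is
    strictly monotone across the seam; a tile edge flush with the frame
    boundary keeps full weight.
    """
    w = np.ones(tile)
    idx = offsets.index(origin)
    if idx > 0:
        r = offsets[idx - 1] + tile - origin  # overlap with left neighbour
        r = max(min(r, tile), 0)
        if r > 0:
            j = np.arange(r)
            w[:r] = np.minimum(w[:r], (j + 1) / (r + 1))
    if idx < len(offsets) - 1:
        r = origin + tile - offsets[idx + 1]  # overlap with right neighbour
        r = max(min(r, tile), 0)
        if r > 0:
            j = np.arange(r)
            w[tile - r:] = np.minimum(w[tile - r:], (r - j) / (r + 1))
    return w


def alpha_blend(tiles, plan: TilePlan, out_shape) -> np.ndarray:
    """Recombine per-tile arrays into the full frame.

    ``tiles`` is a list of ``(array, origin)`` pairs whose first two axes are
    the lateral tile axes (extra trailing axes, e.g. z, pass through).
    Output = Σ w·tile / Σ w with separable linear-ramp weights.
    """
    out_shape = tuple(out_shape)
    first = np.asarray(tiles[0][0])
    tile_lat = first.shape[:2]
    extra = first.shape[2:]
    if tile_lat != (plan.tile, plan.tile):
        raise ValueError(
            f"tile arrays {tile_lat} do not match the plan tile size {plan.tile}"
        )
    acc = np.zeros(out_shape[:2] + extra, dtype=first.dtype)
    wsum = np.zeros(out_shape[:2])
    xs = sorted({o[0] for o in plan.offsets})
    ys = sorted({o[1] for o in plan.offsets})
    for arr, origin in tiles:
        arr = np.asarray(arr)
        ox, oy = origin
        wx = _axis_weight(xs, ox, plan.tile, plan.frame_shape[0])
        wy = _axis_weight(ys, oy, plan.tile, plan.frame_shape[1])
        w2 = np.outer(wx, wy)
        sl = (slice(ox, ox + plan.tile), slice(oy, oy + plan.tile))
        acc[sl] += arr * w2.reshape(w2.shape + (1,) * len(extra))
        wsum[sl] += w2
    if np.any(wsum == 0):
        holes = np.argwhere(wsum == 0)
        raise ValueError(
            f"coverage gap: {len(holes)} output pixels uncovered, first at "
            f"{tuple(holes[0])}"
        )
    return acc / wsum.reshape(wsum.shape + (1,) * len(extra))


def upsampled_output_shape(sensor_shape, s: int) -> tuple[int, ...]:
    """Lateral shape of the stitched super-resolved result (elementwise ×s)."""
    if int(s) < 1:
        raise ValueError("s must be >= 1")
    return tuple(int(n) * int(s) for n in sensor_shape)
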