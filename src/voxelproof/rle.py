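"""Run-length-encoded sparse volumes.

A body (one 3D segment of a segmentation) is transferred and manipulated as
its binary foreground mask, compressed by recording only foreground voxels as
maximal runs along the x axis. This keeps even multi-gigavoxel neurite masks
small enough to hold in memory and makes downsampling, block-cover analysis
and surface extraction cheap sparse operations.

Runs are kept sorted lexicographically by ``(z, y, x_start)``, pairwise
disjoint and maximal (no two runs on the same row touch or overlap); every
public constructor normalizes to that canonical form, so run-list equality is
set equality of voxels.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import DimensionalityError, ValidationError
from .geometry import ORIGIN, BlockSpec, BoundingBox, Coordinate

__all__ = [
    "RLESparseVolume",
    "SurfacePointSet",
    "rle_encode",
    "rle_decode",
    "rle_stats",
    "downsample_mask",
    "block_cover",
    "extract_surface_points",
    "write_rle_binary",
    "read_rle_binary",
    "rle_to_json",
    "rle_from_json",
]

_EMPTY_RUNS = np.empty((0, 4), dtype=np.int64)

# 6-connected structuring element shared by surface extraction and callers.
STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


def _normalize_runs(runs: np.ndarray) -> np.ndarray:
    """Sort runs by (z, y, x_start) and merge overlapping/adjacent runs."""
    if runs.size == 0:
        return _EMPTY_RUNS
    runs = np.asarray(runs, dtype=np.int64).reshape(-1, 4)
    order = np.lexsort((runs[:, 2], runs[:, 1], runs[:, 0]))
    r = runs[order]
    out: List[Tuple[int, int, int, int]] = []
    cz, cy, cs = int(r[0, 0]), int(r[0, 1]), int(r[0, 2])
    ce = cs + int(r[0, 3])
    for z, y, s, ln in r[1:]:
        z, y, s, e = int(z), int(y), int(s), int(s) + int(ln)
        if z == cz and y == cy and s <= ce:
            ce = max(ce, e)
        else:
            out.append((cz, cy, cs, ce - cs))
            cz, cy, cs, ce = z, y, s, e
    out.append((cz, cy, cs, ce - cs))
    return np.array(out, dtype=np.int64)


@dataclass
class RLESparseVolume:
    """Binary mask of one body at one pyramid scale, as maximal x-runs.

    Parameters
    ----------
    runs
        ``(n, 4)`` int64 array with columns ``(z, y, x_start, length)``.
    scale
        Pyramid level; level ``s`` is downsampled by ``2**s`` per axis.
    body_id
        The segment ID this mask belongs to, if known.
    """

    runs: np.ndarray = field(default_factory=lambda: _EMPTY_RUNS.copy())
    scale: int = 0
    body_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=np.int64).reshape(-1, 4)
        if self.runs.size and (self.runs[:, 3] < 1).any():
            raise ValidationError("run lengths must be >= 1")
        if self.scale < 0:
            raise ValidationError("scale must be non-negative")
        self.runs = _normalize_runs(self.runs)

    # -- basic queries ----------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return self.runs.shape[0] == 0

    @property
    def voxel_count(self) -> int:
        return int(self.runs[:, 3].sum()) if self.runs.size else 0

    @property
    def bounding_box(self) -> BoundingBox:
        if self.is_empty:
            return BoundingBox.empty()
        r = self.runs
        lo = Coordinate(int(r[:, 2].min()), int(r[:, 1].min()), int(r[:, 0].min()))
        hi = Coordinate(
            int((r[:, 2] + r[:, 3]).max()), int(r[:, 1].max()) + 1, int(r[:, 0].max()) + 1
        )
        return BoundingBox(lo, hi)

    def voxel_coordinates(self) -> np.ndarray:
        """Expand runs to an ``(n, 3)`` array of ``(z, y, x)`` voxel coordinates."""
        if self.is_empty:
            return np.empty((0, 3), dtype=np.int64)
        reps = self.runs[:, 3]
        z = np.repeat(self.runs[:, 0], reps)
        y = np.repeat(self.runs[:, 1], reps)
        base = np.repeat(self.runs[:, 2], reps)
        ramp = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
        return np.stack([z, y, base + ramp], axis=1)

    def contains(self, c: Coordinate) -> bool:
        r = self.runs
        row = r[(r[:, 0] == c.z) & (r[:, 1] == c.y)]
        return bool(((row[:, 2] <= c.x) & (c.x < row[:, 2] + row[:, 3])).any())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RLESparseVolume):
            return NotImplemented
        return (
            self.scale == other.scale
            and self.runs.shape == other.runs.shape
            and bool(np.array_equal(self.runs, other.runs))
        )


@dataclass(frozen=True)
class SurfacePointSet:
    """Foreground voxels with at least one background 6-neighbor.

    Rendered downstream as uniform spheres; here just the point list and the
    shared display radius in voxels.
    """

    points: Tuple[Coordinate, ...]
    radius: float = 1.0


# -- encoding / decoding --------------------------------------------------


def rle_encode(
    mask: np.ndarray,
    offset: Coordinate = ORIGIN,
    *,
    scale: int = 0,
    body_id: Optional[int] = None,
) -> RLESparseVolume:
    """Encode a dense binary ``[z, y, x]`` mask; ``offset`` locates ``mask[0,0,0]``."""
    a = np.asarray(mask)
    if a.ndim != 3:
        raise DimensionalityError(f"mask must be 3D, got {a.ndim}D")
    m = a.astype(bool)
    if not m.any():
        return RLESparseVolume(_EMPTY_RUNS.copy(), scale, body_id)
    edges = np.diff(np.pad(m, ((0, 0), (0, 0), (1, 1))).astype(np.int8), axis=2)
    z0, y0, xs = np.nonzero(edges == 1)
    _, _, xe = np.nonzero(edges == -1)
    runs = np.stack(
        [z0 + offset.z, y0 + offset.y, xs + offset.x, xe - xs], axis=1
    ).astype(np.int64)
    return RLESparseVolume(runs, scale, body_id)


def rle_decode(
    rle: RLESparseVolume, box: Optional[BoundingBox] = None
) -> Tuple[np.ndarray, Coordinate]:
    """Render to a dense boolean array; returns ``(array, offset_of_[0,0,0])``.

    If ``box`` is omitted the tight bounding box is used. Foreground outside
    a supplied box is clipped silently. An empty volume decodes to a
    zero-size array.
    """
    if box is None:
        box = rle.bounding_box
    out = np.zeros(box.shape_zyx, dtype=bool)
    if rle.is_empty or box.is_empty:
        return out, box.min
    oz, oy, ox = box.min.z, box.min.y, box.min.x
    for z, y, s, ln in rle.runs:
        if not (oz <= z < box.max.z and oy <= y < box.max.y):
            continue
        lo = max(int(s), ox)
        hi = min(int(s) + int(ln), box.max.x)
        if lo < hi:
            out[z - oz, y - oy, lo - ox : hi - ox] = True
    return out, box.min


def rle_stats(rle: RLESparseVolume) -> Tuple[int, BoundingBox]:
    """Foreground voxel count and tight bounding box."""
    return rle.voxel_count, rle.bounding_box


def downsample_mask(rle: RLESparseVolume, levels: int) -> RLESparseVolume:
    """OR-pool the mask down ``levels`` pyramid steps (factor ``2**levels``/axis).

    A coarse voxel is foreground iff any of its children is foreground, which
    preserves thin branches in coarse-scale previews. Coordinates are
    floor-divided.
    """
    if levels < 1:
        raise ValidationError("levels must be >= 1")
    if rle.is_empty:
        return RLESparseVolume(_EMPTY_RUNS.copy(), rle.scale + levels, rle.body_id)
    f = 1 << levels
    r = rle.runs
    z = r[:, 0] // f
    y = r[:, 1] // f
    xs = r[:, 2] // f
    xe = (r[:, 2] + r[:, 3] - 1) // f
    coarse = np.stack([z, y, xs, xe - xs + 1], axis=1)
    return RLESparseVolume(_normalize_runs(coarse), rle.scale + levels, rle.body_id)


def block_cover(rle: RLESparseVolume, spec: BlockSpec) -> List[Tuple[int, int, int]]:
    """Sorted, deduplicated ``(bz, by, bx)`` indices of blocks holding foreground."""
    e = spec.edge
    cover = set()
    for z, y, s, ln in rle.runs:
        bz, by = int(z) // e, int(y) // e
        for bx in range(int(s) // e, (int(s) + int(ln) - 1) // e + 1):
            cover.add((bz, by, bx))
    return sorted(cover)


def extract_surface_points(rle: RLESparseVolume, radius: float = 1.0) -> SurfacePointSet:
    """Foreground voxels with >= 1 background 6-neighbor (tight surface shell)."""
    if rle.is_empty:
        return SurfacePointSet((), radius)
    dense, off = rle_decode(rle)
    padded = np.pad(dense, 1)
    interior = ndimage.binary_erosion(padded, structure=STRUCTURE_6)[1:-1, 1:-1, 1:-1]
    zz, yy, xx = np.nonzero(dense & ~interior)
    pts = tuple(
        Coordinate(int(x + off.x), int(y + off.y), int(z + off.z))
        for z, y, x in zip(zz, yy, xx)
    )
    return SurfacePointSet(pts, radius)


# -- wire formats ---------------------------------------------------------
#
# Binary layout (little-endian): magic, scale, run count as unsigned 32-bit,
# then each run as four signed 32-bit integers (z, y, x_start, length). This
# is this package's own format; it is not wire-compatible with any external
# volume service.

_MAGIC = 0x454C5652  # "RVLE"
_HEADER = struct.Struct("<III")


def write_rle_binary(rle: RLESparseVolume, path) -> None:
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, rle.scale, rle.runs.shape[0]))
        fh.write(np.ascontiguousarray(rle.runs, dtype="<i4").tobytes())


def read_rle_binary(path) -> RLESparseVolume:
    with open(path, "rb") as fh:
        magic, scale, n = _HEADER.unpack(fh.read(_HEADER.size))
        if magic != _MAGIC:
            raise ValidationError(f"bad RLE magic 0x{magic:08X}")
        runs = np.frombuffer(fh.read(16 * n), dtype="<i4").reshape(n, 4)
    return RLESparseVolume(runs.astype(np.int64), scale)


def rle_to_json(rle: RLESparseVolume) -> str:
    return json.dumps({"scale": rle.scale, "runs": rle.runs.tolist()})


def rle_from_json(text: str) -> RLESparseVolume:
    d = json.loads(text)
    return RLESparseVolume(np.array(d["runs"], dtype=np.int64).reshape(-1, 4), d["scale"])
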