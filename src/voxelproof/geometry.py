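"""Voxel-grid primitives: 0-based coordinates, half-open boxes, cubic blocks.

Conventions used throughout the package:

* Dense arrays are indexed ``[z, y, x]`` (slice-major, matching multi-page
  TIFF / HDF5 storage order).
* Coordinates are 0-based integers. Stored voxels are non-negative; only
  transient geometry such as ray origins may go negative.
* Boxes are half-open ``[min, max)`` on every axis, so a box is empty iff
  ``min == max`` on any axis and there is never a ±1 ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence, Tuple

from .errors import ValidationError


class Coordinate(NamedTuple):
    """A voxel location on the global grid."""

    x: int
    y: int
    z: int

    @property
    def zyx(self) -> Tuple[int, int, int]:
        return (self.z, self.y, self.x)

    @classmethod
    def from_zyx(cls, zyx: Sequence[int]) -> "Coordinate":
        z, y, x = zyx
        return cls(int(x), int(y), int(z))

    def offset_by(self, dx: int, dy: int, dz: int) -> "Coordinate":
        return Coordinate(self.x + dx, self.y + dy, self.z + dz)


ORIGIN = Coordinate(0, 0, 0)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open box ``[min, max)`` in voxel coordinates."""

    min: Coordinate
    max: Coordinate

    def __post_init__(self) -> None:
        for lo, hi, axis in zip(self.min, self.max, "xyz"):
            if lo > hi:
                raise ValidationError(
                    f"box min.{axis}={lo} exceeds max.{axis}={hi}"
                )

    @classmethod
    def empty(cls) -> "BoundingBox":
        return cls(ORIGIN, ORIGIN)

    @classmethod
    def from_shape(cls, shape_zyx: Sequence[int], offset: Coordinate = ORIGIN) -> "BoundingBox":
        z, y, x = (int(v) for v in shape_zyx)
        return cls(offset, Coordinate(offset.x + x, offset.y + y, offset.z + z))

    @property
    def is_empty(self) -> bool:
        return any(lo >= hi for lo, hi in zip(self.min, self.max))

    @property
    def shape_zyx(self) -> Tuple[int, int, int]:
        if self.is_empty:
            return (0, 0, 0)
        return (self.max.z - self.min.z, self.max.y - self.min.y, self.max.x - self.min.x)

    @property
    def volume(self) -> int:
        sz, sy, sx = self.shape_zyx
        return sz * sy * sx

    def contains(self, c: Coordinate) -> bool:
        return all(lo <= v < hi for lo, v, hi in zip(self.min, c, self.max))

    def intersect(self, other: "BoundingBox") -> "BoundingBox":
        lo = Coordinate(*(max(a, b) for a, b in zip(self.min, other.min)))
        hi = Coordinate(*(min(a, b) for a, b in zip(self.max, other.max)))
        if any(l > h for l, h in zip(lo, hi)):
            return BoundingBox.empty()
        return BoundingBox(lo, hi)

    def union_bounds(self, other: "BoundingBox") -> "BoundingBox":
        """Smallest box containing both (empty operands are ignored)."""
        if self.is_empty:
            return other
        if other.is_empty:
            return self
        lo = Coordinate(*(min(a, b) for a, b in zip(self.min, other.min)))
        hi = Coordinate(*(max(a, b) for a, b in zip(self.max, other.max)))
        return BoundingBox(lo, hi)

    def dilate(self, margin: int) -> "BoundingBox":
        if margin < 0:
            raise ValidationError("margin must be non-negative")
        if self.is_empty:
            return self
        return BoundingBox(
            Coordinate(self.min.x - margin, self.min.y - margin, self.min.z - margin),
            Coordinate(self.max.x + margin, self.max.y + margin, self.max.z + margin),
        )


@dataclass(frozen=True)
class BlockSpec:
    """Cubic storage block geometry; edge must be a power of two (default 32)."""

    edge: int = 32

    def __post_init__(self) -> None:
        e = self.edge
        if e < 1 or (e & (e - 1)) != 0:
            raise ValidationError(f"block edge must be a positive power of two, got {e}")

    def block_index(self, c: Coordinate) -> Tuple[int, int, int]:
        """(bz, by, bx) index of the block containing voxel ``c``."""
        e = self.edge
        return (c.z // e, c.y // e, c.x // e)

    def block_box(self, index: Tuple[int, int, int]) -> BoundingBox:
        bz, by, bx = index
        e = self.edge
        lo = Coordinate(bx * e, by * e, bz * e)
        return BoundingBox(lo, Coordinate(lo.x + e, lo.y + e, lo.z + e))
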