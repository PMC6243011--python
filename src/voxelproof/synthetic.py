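"""Synthetic EM-like volumes for exercising the proofreading stack.

Real FIB-SEM fly-brain data is far beyond test scale, so the test bed is a
3D Voronoi partition of random cell sites: bright cytoplasm compartments
(default mean 200) separated by dark membrane walls (default mean 50) with
additive Gaussian noise — the intensity regime the grayscale-driven
watershed assumes (membranes darker than cytoplasm). Ground-truth labels
are the Voronoi cells themselves; membrane voxels keep the label of their
nearest site, so every voxel is labeled.

Scenario builders derive segmentation errors from the ground truth:
``make_false_merge`` unions adjacent cells under one ID (the splitting test
case), ``make_false_split`` cuts one cell in two (the merging test case).
No attempt is made at EM texture realism or anisotropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .geometry import Coordinate
from .rle import STRUCTURE_6
from .split import Seed, SeedSet

__all__ = [
    "FixtureSpec",
    "generate_cells",
    "make_false_merge",
    "make_false_split",
    "centroid_seed_set",
    "voxel_agreement",
]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic volume.

    Defaults give a comfortably separated intensity contract:
    (cytoplasm − membrane) / σ = (200 − 50) / 10 = 15σ.
    """

    shape: Tuple[int, int, int] = (40, 40, 40)  # (z, y, x)
    n_cells: int = 4
    membrane_width: int = 1
    cytoplasm_mean: int = 200
    membrane_mean: int = 50
    noise_sigma: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValidationError("need at least 2 cells")
        if self.membrane_width < 1:
            raise ValidationError("membrane_width must be >= 1")
        if not (0 <= self.membrane_mean < self.cytoplasm_mean <= 255):
            raise ValidationError("membranes must be darker than cytoplasm (both 8-bit)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        # ~8 voxels per axis per cell heuristic
        if int(np.prod(self.shape)) < self.n_cells * 8**3:
            raise ValidationError(
                f"shape {self.shape} too small for {self.n_cells} cells"
            )


def generate_cells(spec: FixtureSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Build ``(grayscale uint8, labels int64)`` volumes, both ``[z, y, x]``.

    Deterministic under ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    Z, Y, X = spec.shape
    # distinct random sites
    flat = rng.choice(Z * Y * X, size=spec.n_cells, replace=False)
    sites = np.stack(np.unravel_index(flat, (Z, Y, X)), axis=1).astype(float)

    grid = np.stack(
        np.meshgrid(np.arange(Z), np.arange(Y), np.arange(X), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    _, nearest = cKDTree(sites).query(grid)
    labels = (nearest + 1).reshape(Z, Y, X).astype(np.int64)

    # membrane: voxels near a face between different cells
    boundary = np.zeros(spec.shape, dtype=bool)
    for axis in range(3):
        diff = np.diff(labels, axis=axis) != 0
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        boundary[tuple(lo)] |= diff
        boundary[tuple(hi)] |= diff
    if spec.membrane_width > 1:
        dist = ndimage.distance_transform_edt(~boundary)
        membrane = dist < spec.membrane_width
    else:
        membrane = boundary

    gray = np.full(spec.shape, float(spec.cytoplasm_mean))
    gray[membrane] = float(spec.membrane_mean)
    if spec.noise_sigma > 0:
        gray = gray + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return gray, labels


def make_false_merge(
    labels: np.ndarray, ids: Sequence[int]
) -> Tuple[np.ndarray, Dict[int, int]]:
    """Union the listed cells under the first ID (synthetic false merge).

    Returns ``(new_labels, mapping old→merged)``. The caller keeps the
    original ``labels`` as ground truth for scoring a recovery split. A
    warning is emitted if some pair of listed cells is nowhere 6-adjacent
    (the merge is then implausible but still performed).
    """
    ids = [int(i) for i in ids]
    if len(ids) < 2:
        raise ValidationError("false merge needs >= 2 ids")
    present = set(np.unique(labels))
    for i in ids:
        if i not in present:
            raise ValidationError(f"id {i} not present in label volume")
    union = np.isin(labels, ids)
    ncomp = ndimage.label(union, structure=STRUCTURE_6)[1]
    if ncomp > 1:
        warnings.warn(
            f"merged ids {ids} do not form a single 6-connected component",
            stacklevel=2,
        )
    out = labels.copy()
    out[union] = ids[0]
    return out, {i: ids[0] for i in ids[1:]}


def make_false_split(
    labels: np.ndarray, cell_id: int, plane: Tuple[int, int]
) -> Tuple[np.ndarray, Dict[int, Tuple[int, int]]]:
    """Cut one cell by an axis-aligned plane into two IDs (synthetic false split).

    ``plane = (axis, position)`` with axis 0/1/2 = z/y/x: voxels of the cell
    with coordinate < position keep ``cell_id``; the rest get a fresh ID.
    Returns ``(new_labels, {cell_id: (cell_id, new_id)})``.
    """
    axis, position = plane
    if axis not in (0, 1, 2):
        raise ValidationError("plane axis must be 0 (z), 1 (y) or 2 (x)")
    sel = labels == cell_id
    if not sel.any():
        raise ValidationError(f"id {cell_id} not present in label volume")
    side_b = sel & (np.indices(labels.shape)[axis] >= position)
    side_a = sel & ~side_b
    if not side_a.any() or not side_b.any():
        raise ValidationError("degenerate cut: one side of the plane is empty")
    new_id = int(labels.max()) + 1
    out = labels.copy()
    out[side_b] = new_id
    return out, {cell_id: (cell_id, new_id)}


def centroid_seed_set(labels: np.ndarray, ids: Sequence[int]) -> SeedSet:
    """One seed per listed cell at (the cell voxel nearest to) its centroid.

    Seed labels are 1..k in the order of ``ids``; positions are array
    coordinates (z, y, x order in the volume, emitted as x/y/z Coordinates).
    """
    seeds = []
    for k, cid in enumerate(ids, start=1):
        zz, yy, xx = np.nonzero(labels == cid)
        if zz.size == 0:
            raise ValidationError(f"id {cid} not present in label volume")
        cz, cy, cx = zz.mean(), yy.mean(), xx.mean()
        j = int(np.argmin((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2))
        seeds.append(Seed(Coordinate(int(xx[j]), int(yy[j]), int(zz[j])), k))
    return SeedSet(seeds)


def voxel_agreement(
    result_regions: Dict[int, "object"], truth_labels: np.ndarray, ids: Sequence[int]
) -> float:
    """Fraction of the merged body's voxels assigned to the right cell.

    Region ``k`` (from :func:`centroid_seed_set` ordering) is scored against
    ground-truth cell ``ids[k-1]``; residual voxels count as wrong.
    """
    from .rle import rle_decode

    total = int(np.isin(truth_labels, list(ids)).sum())
    if total == 0:
        raise ValidationError("no body voxels to score")
    correct = 0
    for k, cid in enumerate(ids, start=1):
        reg = result_regions.get(k)
        if reg is None or reg.is_empty:
            continue
        dense, off = rle_decode(reg)
        sub = truth_labels[
            off.z : off.z + dense.shape[0],
            off.y : off.y + dense.shape[1],
            off.x : off.x + dense.shape[2],
        ]
        correct += int((dense & (sub == cid)).sum())
    return correct / total
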