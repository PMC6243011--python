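"""Versioned, block-based label store with a grayscale companion.

In-process emulation of the subset of an image data service that a
proofreading client needs: voxel→body-ID mapping stored as fixed-size cubic
blocks, per-body sparse retrieval at any pyramid scale, block-aligned
grayscale fetch, merge and split application, checkpoint/branch versioning
with copy-on-write layers, and per-body diffs between versions.

Versions form a tree. Committed versions are immutable; only the working tip
mutates. A tip's reads fall through to the nearest ancestor layer that holds
the addressed block, so a commit is O(1) and branches share storage.

Merging is voxel-relabeling only (no inter-voxel computation): all voxels of
the merged bodies receive the target ID. Splitting persists a partition
produced by the split engine; the largest region keeps the original ID so
that most body-keyed annotations stay attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Iterator, List, Mapping, NamedTuple, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .errors import (
    BodyNotFoundError,
    ConfigurationError,
    ConsistencyError,
    DimensionalityError,
    ImmutabilityError,
    ValidationError,
    VersionNotFoundError,
)
from .geometry import ORIGIN, BlockSpec, BoundingBox, Coordinate
from .librarian import Librarian
from .rle import (
    RLESparseVolume,
    _normalize_runs,
    block_cover,
    downsample_mask,
    rle_decode,
    rle_encode,
)

BlockIndex = Tuple[int, int, int]


class VersionID(NamedTuple):
    """Opaque committed-version identifier; ``parent`` is None at the root."""

    value: str
    parent: Optional[str] = None


@dataclass(frozen=True)
class GrayscalePatchSet:
    """Whole grayscale blocks intersecting one body's foreground.

    Fetching whole blocks (even where the body only partially fills them)
    mirrors block-aligned retrieval from a block-indexed image service, where
    it avoids server-side slicing.
    """

    spec: BlockSpec
    patches: Tuple[Tuple[BlockIndex, np.ndarray], ...]

    def assemble(self, box: BoundingBox) -> np.ndarray:
        """Paste patches into a dense uint8 array covering ``box`` (zeros elsewhere)."""
        out = np.zeros(box.shape_zyx, dtype=np.uint8)
        for idx, arr in self.patches:
            bbox = self.spec.block_box(idx).intersect(box)
            if bbox.is_empty:
                continue
            bo = self.spec.block_box(idx).min
            out[
                bbox.min.z - box.min.z : bbox.max.z - box.min.z,
                bbox.min.y - box.min.y : bbox.max.y - box.min.y,
                bbox.min.x - box.min.x : bbox.max.x - box.min.x,
            ] = arr[
                bbox.min.z - bo.z : bbox.max.z - bo.z,
                bbox.min.y - bo.y : bbox.max.y - bo.y,
                bbox.min.x - bo.x : bbox.max.x - bo.x,
            ]
        return out


@dataclass(frozen=True)
class BodyDiff:
    """Three-way decomposition of one body across two versions.

    ``added`` = in B only (displayed green), ``removed`` = in A only (red),
    ``unchanged`` = in both (gray).
    """

    added: RLESparseVolume
    removed: RLESparseVolume
    unchanged: RLESparseVolume

    DISPLAY_CODING = {"added": "green", "removed": "red", "unchanged": "gray"}

    def summary(self) -> Dict[str, int]:
        return {
            "added": self.added.voxel_count,
            "removed": self.removed.voxel_count,
            "unchanged": self.unchanged.voxel_count,
        }


VersionLike = Union[VersionID, str, None]
SyncHook = Callable[[Mapping[int, int]], None]

_TIP = object()  # sentinel: address the mutable working tip


class VersionedLabelStore:
    """Block-based voxel→body mapping with copy-on-write version layers."""

    def __init__(
        self,
        block_spec: Optional[BlockSpec] = None,
        *,
        max_scale: int = 5,
        librarian: Optional[Librarian] = None,
    ) -> None:
        self.block_spec = block_spec or BlockSpec()
        self.max_scale = int(max_scale)
        self.librarian = librarian
        self._layers: Dict[str, Dict[BlockIndex, np.ndarray]] = {}
        self._parents: Dict[str, Optional[str]] = {}
        self._order: List[str] = []
        self._tip: Dict[BlockIndex, np.ndarray] = {}
        self._tip_parent: Optional[str] = None
        self._next_version = 0
        self._next_id = 1
        self._grayscale: Optional[np.ndarray] = None
        self._gray_origin = ORIGIN
        self._sync_hooks: List[SyncHook] = []

    # -- version plumbing -------------------------------------------------

    def _resolve(self, version: VersionLike) -> Union[str, None, object]:
        if version is None:
            return _TIP
        val = version.value if isinstance(version, VersionID) else str(version)
        if val not in self._layers:
            raise VersionNotFoundError(val)
        return val

    def _chain(self, version) -> List[Dict[BlockIndex, np.ndarray]]:
        """Layers newest-first starting at ``version`` (tip sentinel allowed)."""
        chain: List[Dict[BlockIndex, np.ndarray]] = []
        if version is _TIP:
            chain.append(self._tip)
            v = self._tip_parent
        else:
            v = version
        while v is not None:
            chain.append(self._layers[v])
            v = self._parents[v]
        return chain

    def _blocks_view(self, version=_TIP) -> Dict[BlockIndex, np.ndarray]:
        view: Dict[BlockIndex, np.ndarray] = {}
        for layer in reversed(self._chain(version)):
            view.update(layer)
        return view

    def _tip_block(self, idx: BlockIndex) -> np.ndarray:
        """Copy-on-write fetch of a tip block for mutation."""
        blk = self._tip.get(idx)
        if blk is None:
            base = None
            v = self._tip_parent
            while v is not None:
                base = self._layers[v].get(idx)
                if base is not None:
                    break
                v = self._parents[v]
            e = self.block_spec.edge
            blk = base.copy() if base is not None else np.zeros((e, e, e), dtype=np.uint64)
            self._tip[idx] = blk
        return blk

    def versions(self) -> List[VersionID]:
        return [VersionID(v, self._parents[v]) for v in self._order]

    def commit(self) -> VersionID:
        """Freeze the working tip as an immutable version; start a fresh tip on it."""
        vid = f"v{self._next_version}"
        self._next_version += 1
        self._layers[vid] = self._tip
        self._parents[vid] = self._tip_parent
        self._order.append(vid)
        self._tip = {}
        self._tip_parent = vid
        return VersionID(vid, self._parents[vid])

    def branch(self, parent: VersionLike) -> None:
        """Point the working tip at ``parent``; uncommitted tip edits are discarded."""
        val = self._resolve(parent)
        if val is _TIP:
            raise ValidationError("branch requires a committed parent version")
        self._tip = {}
        self._tip_parent = val  # type: ignore[assignment]

    # -- ingest & voxel reads --------------------------------------------

    def allocate_id(self) -> int:
        """Monotone ID allocator; never reissues within a store lifetime."""
        bid = self._next_id
        self._next_id += 1
        return bid

    def put_labels(
        self, array: np.ndarray, offset: Coordinate = ORIGIN, version: VersionLike = None
    ) -> None:
        """Write a dense label array into the working tip at ``offset``."""
        if version is not None:
            raise ImmutabilityError("committed versions are immutable; write to the tip")
        arr = np.asarray(array)
        if arr.ndim != 3:
            raise DimensionalityError(f"label array must be 3D, got {arr.ndim}D")
        if min(offset) < 0:
            raise ValidationError("stored voxels must have non-negative coordinates")
        e = self.block_spec.edge
        Z, Y, X = arr.shape
        z0, y0, x0 = offset.z, offset.y, offset.x
        for bz in range(z0 // e, (z0 + Z - 1) // e + 1):
            for by in range(y0 // e, (y0 + Y - 1) // e + 1):
                for bx in range(x0 // e, (x0 + X - 1) // e + 1):
                    oz, oy, ox = bz * e, by * e, bx * e
                    lz, hz = max(oz, z0), min(oz + e, z0 + Z)
                    ly, hy = max(oy, y0), min(oy + e, y0 + Y)
                    lx, hx = max(ox, x0), min(ox + e, x0 + X)
                    if lz >= hz or ly >= hy or lx >= hx:
                        continue
                    blk = self._tip_block((bz, by, bx))
                    blk[lz - oz : hz - oz, ly - oy : hy - oy, lx - ox : hx - ox] = arr[
                        lz - z0 : hz - z0, ly - y0 : hy - y0, lx - x0 : hx - x0
                    ]
        if arr.size:
            self._next_id = max(self._next_id, int(arr.max()) + 1)

    def label_at(self, c: Coordinate, version: VersionLike = None) -> int:
        idx = self.block_spec.block_index(c)
        for layer in self._chain(self._resolve(version)):
            blk = layer.get(idx)
            if blk is not None:
                o = self.block_spec.block_box(idx).min
                return int(blk[c.z - o.z, c.y - o.y, c.x - o.x])
        return 0

    def bodies(self, version: VersionLike = None) -> Set[int]:
        ids: Set[int] = set()
        for blk in self._blocks_view(self._resolve(version)).values():
            ids.update(int(v) for v in np.unique(blk))
        ids.discard(0)
        return ids

    # -- body retrieval ---------------------------------------------------

    def get_body_sparse(
        self, body: int, scale: int = 0, version: VersionLike = None
    ) -> RLESparseVolume:
        """RLE mask of all voxels labeled ``body``, OR-downsampled to ``scale``."""
        if body <= 0:
            raise ValidationError("body IDs are positive integers")
        pieces = []
        for idx, blk in self._blocks_view(self._resolve(version)).items():
            sub = blk == body
            if sub.any():
                pieces.append(rle_encode(sub, self.block_spec.block_box(idx).min).runs)
        if not pieces:
            raise BodyNotFoundError(body)
        rle = RLESparseVolume(_normalize_runs(np.concatenate(pieces)), 0, body)
        if scale > 0:
            rle = downsample_mask(rle, scale)
        return rle

    def progressive_fetch(
        self, body: int, size_threshold: int, version: VersionLike = None
    ) -> Iterator[RLESparseVolume]:
        """Yield the body coarse→fine, stopping after the first scale whose
        voxel count exceeds ``size_threshold`` (or at scale 0)."""
        base = self.get_body_sparse(body, 0, version)
        for s in range(self.max_scale, -1, -1):
            rle = downsample_mask(base, s) if s else base
            yield rle
            if rle.voxel_count > size_threshold:
                return

    # -- grayscale companion ---------------------------------------------

    def set_grayscale(self, array: np.ndarray, origin: Coordinate = ORIGIN) -> None:
        arr = np.asarray(array)
        if arr.ndim != 3:
            raise DimensionalityError("grayscale must be 3D")
        self._grayscale = arr.astype(np.uint8)
        self._gray_origin = origin

    def fetch_body_grayscale(self, body: int, version: VersionLike = None) -> GrayscalePatchSet:
        """Whole grayscale blocks for exactly the body's block cover."""
        if self._grayscale is None:
            raise ConfigurationError("no grayscale companion volume loaded")
        mask = self.get_body_sparse(body, 0, version)
        e = self.block_spec.edge
        g = self._grayscale
        go = self._gray_origin
        patches = []
        for idx in block_cover(mask, self.block_spec):
            patch = np.zeros((e, e, e), dtype=np.uint8)
            bo = self.block_spec.block_box(idx).min
            lz, hz = max(bo.z, go.z), min(bo.z + e, go.z + g.shape[0])
            ly, hy = max(bo.y, go.y), min(bo.y + e, go.y + g.shape[1])
            lx, hx = max(bo.x, go.x), min(bo.x + e, go.x + g.shape[2])
            if lz < hz and ly < hy and lx < hx:
                patch[lz - bo.z : hz - bo.z, ly - bo.y : hy - bo.y, lx - bo.x : hx - bo.x] = g[
                    lz - go.z : hz - go.z, ly - go.y : hy - go.y, lx - go.x : hx - go.x
                ]
            patches.append((idx, patch))
        return GrayscalePatchSet(self.block_spec, tuple(patches))

    # -- mutations --------------------------------------------------------

    def add_sync_hook(self, hook: SyncHook) -> None:
        """Register a callback fired with a retired→target ID mapping after
        merges and splits (annotation re-association)."""
        self._sync_hooks.append(hook)

    def _fire_sync(self, mapping: Mapping[int, int]) -> None:
        for hook in self._sync_hooks:
            hook(dict(mapping))

    def _guard(self, body: int, user: str) -> None:
        if self.librarian is not None:
            self.librarian.guard(body, user)

    def merge_bodies(self, ids: Sequence[int], user: str = "") -> int:
        """Relabel all voxels of ``ids[1:]`` to ``ids[0]``; returns the target ID.

        Requires the user to hold locks on every participant body when a
        librarian is attached; a refused merge changes nothing.
        """
        ids = [int(i) for i in ids]
        if len(ids) < 2 or len(set(ids)) != len(ids):
            raise ValidationError("merge needs >= 2 distinct body IDs")
        existing = self.bodies()
        for b in ids:
            if b not in existing:
                raise BodyNotFoundError(b)
        for b in ids:
            self._guard(b, user)
        target, retired = ids[0], ids[1:]
        view = self._blocks_view()
        for idx, blk in view.items():
            sel = np.isin(blk, retired)
            if sel.any():
                tip = self._tip_block(idx)
                tip[np.isin(tip, retired)] = target
        self._fire_sync({r: target for r in retired})
        return target

    def apply_split(self, body: int, result, user: str = "") -> Dict[int, int]:
        """Persist a split partition; returns split-label → body ID.

        The largest region keeps the original ID (ties broken toward the
        smallest split label); other regions get fresh allocator IDs. Voxels
        not covered by any region stay with the original body.
        """
        self._guard(body, user)
        body_rle = self.get_body_sparse(body, 0)
        regions = result.regions if hasattr(result, "regions") else dict(result)
        if not regions:
            return {}
        box = body_rle.bounding_box
        for reg in regions.values():
            box = box.union_bounds(reg.bounding_box)
        body_dense, _ = rle_decode(body_rle, box)
        covered = np.zeros_like(body_dense)
        for label in regions:
            reg_dense, _ = rle_decode(regions[label], box)
            if (reg_dense & ~body_dense).any():
                raise ConsistencyError(f"region {label} contains voxels outside body {body}")
            if (reg_dense & covered).any():
                raise ConsistencyError("split regions overlap")
            covered |= reg_dense
        order = sorted(regions, key=lambda l: (-regions[l].voxel_count, l))
        mapping: Dict[int, int] = {order[0]: body}
        for label in order[1:]:
            mapping[label] = self.allocate_id()
        for label in order[1:]:
            self._set_voxels(regions[label], mapping[label])
        self._fire_sync({})
        return mapping

    def _set_voxels(self, rle: RLESparseVolume, value: int) -> None:
        e = self.block_spec.edge
        for z, y, s, ln in rle.runs:
            z, y, s, ln = int(z), int(y), int(s), int(ln)
            bz, by = z // e, y // e
            x, end = s, s + ln
            while x < end:
                bx = x // e
                xe = min(end, (bx + 1) * e)
                blk = self._tip_block((bz, by, bx))
                blk[z - bz * e, y - by * e, x - bx * e : xe - bx * e] = value
                x = xe
        self._next_id = max(self._next_id, value + 1)

    # -- diffs & integrity ------------------------------------------------

    def body_diff(self, version_a: VersionLike, version_b: VersionLike, body: int) -> BodyDiff:
        """Added/removed/unchanged decomposition of ``body`` from A to B at scale 0."""

        def mask_of(v):
            try:
                return self.get_body_sparse(body, 0, v)
            except BodyNotFoundError:
                return RLESparseVolume()

        a, b = mask_of(version_a), mask_of(version_b)
        if a.is_empty and b.is_empty:
            raise BodyNotFoundError(body)
        box = a.bounding_box.union_bounds(b.bounding_box)
        da, _ = rle_decode(a, box)
        db, _ = rle_decode(b, box)
        return BodyDiff(
            added=rle_encode(db & ~da, box.min, body_id=body),
            removed=rle_encode(da & ~db, box.min, body_id=body),
            unchanged=rle_encode(da & db, box.min, body_id=body),
        )

    def state_hash(self, version: VersionLike = None) -> str:
        """SHA-256 over the effective block view (mutation-atomicity checks)."""
        h = hashlib.sha256()
        view = self._blocks_view(self._resolve(version))
        for idx in sorted(view):
            h.update(repr(idx).encode())
            h.update(np.ascontiguousarray(view[idx]).tobytes())
        return h.hexdigest()

    def total_foreground(self, version: VersionLike = None) -> int:
        return sum(
            int((blk != 0).sum()) for blk in self._blocks_view(self._resolve(version)).values()
        )

    # -- persistence ------------------------------------------------------
    #
    # One HDF5 file per version layer plus the tip, a grayscale file, and a
    # JSON manifest; enough to round-trip a store through the CLI.

    def save(self, path) -> None:
        import h5py

        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        meta = {
            "edge": self.block_spec.edge,
            "max_scale": self.max_scale,
            "next_id": self._next_id,
            "next_version": self._next_version,
            "order": self._order,
            "parents": self._parents,
            "tip_parent": self._tip_parent,
            "gray_origin": list(self._gray_origin),
        }
        (root / "manifest.json").write_text(json.dumps(meta, indent=1))

        def dump(name: str, layer: Dict[BlockIndex, np.ndarray]) -> None:
            with h5py.File(root / f"layer_{name}.h5", "w") as fh:
                for (bz, by, bx), blk in layer.items():
                    fh.create_dataset(f"b_{bz}_{by}_{bx}", data=blk)

        for vid, layer in self._layers.items():
            dump(vid, layer)
        dump("TIP", self._tip)
        if self._grayscale is not None:
            with h5py.File(root / "grayscale.h5", "w") as fh:
                fh.create_dataset("data", data=self._grayscale)

    @classmethod
    def load(cls, path, *, librarian: Optional[Librarian] = None) -> "VersionedLabelStore":
        import h5py

        root = Path(path)
        meta = json.loads((root / "manifest.json").read_text())
        store = cls(BlockSpec(meta["edge"]), max_scale=meta["max_scale"], librarian=librarian)
        store._next_id = meta["next_id"]
        store._next_version = meta["next_version"]
        store._order = list(meta["order"])
        store._parents = {k: v for k, v in meta["parents"].items()}
        store._tip_parent = meta["tip_parent"]
        store._gray_origin = Coordinate(*meta["gray_origin"])

        def slurp(name: str) -> Dict[BlockIndex, np.ndarray]:
            layer: Dict[BlockIndex, np.ndarray] = {}
            fp = root / f"layer_{name}.h5"
            if fp.exists():
                with h5py.File(fp, "r") as fh:
                    for key in fh:
                        _, bz, by, bx = key.split("_")
                        layer[(int(bz), int(by), int(bx))] = fh[key][()]
            return layer

        for vid in store._order:
            store._layers[vid] = slurp(vid)
        store._tip = slurp("TIP")
        gp = root / "grayscale.h5"
        if gp.exists():
            with h5py.File(gp, "r") as fh:
                store._grayscale = fh["data"][()]
        return store
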