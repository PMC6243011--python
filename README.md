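# voxelproof

A headless Python toolkit for **segmentation-based connectome proofreading**:
the computational core of correcting automated EM segmentations by merging
false splits and splitting false merges, at the scale where a single neuron
("body") can span gigavoxels and several proofreaders work on the same
volume at once.

It is a library first (plus a thin `voxelproof` CLI) and runs entirely on
synthetic data, so every mechanism can be exercised and tested on a laptop:

* **Sparse volumes** — a body travels as a run-length-encoded binary mask
  (x-runs keyed by `(z, y, x_start)`), with OR-pooled multi-scale pyramids
  (level *s* = downsampled by 2^*s* per axis), block covers over cubic
  32³-voxel storage blocks, and surface-point extraction (foreground voxels
  with a background 6-neighbor) for sphere-based 3D display.
* **Versioned label store** — a block-based voxel→body-ID map with
  copy-on-write version layers: commit checkpoints, branch, progressive
  coarse→fine body fetch up to a size threshold, block-aligned grayscale
  retrieval, merge (pure relabeling), split persistence, and per-body
  added/removed/unchanged (green/red/gray) diffs between versions.
* **Seeded-watershed splitting** — false merges are fixed by painting
  labeled seeds and flooding the body's grayscale with priority
  `255 − intensity` (bright cytoplasm floods before dark membrane, so
  competing fronts meet at the membrane ridge), 6-connected and confined to
  the body's foreground. Includes per-component flooding with same-label
  joining, a user bounding box with connected-component reattachment of
  outside pieces, seed-local previews, ray-shot 3D seed painting, and
  coarse-scale splitting for bodies whose bounding box exceeds a voxel
  budget (default 10⁹).
* **Annotations** — body names and the seven-value status vocabulary
  (`not examined`, `traced`, `traced in ROI`, `partially traced`, `orphan`,
  `hard to trace`, `finalized`), owner-private bookmarks, shared to-do
  marks, synapse elements with directed pre→post links, region/body
  queries, and a filterable, sortable "sequencer" body table. Marks follow
  voxels through merges and splits automatically.
* **Librarian** — per-body exclusive locks gating every mutation, with
  deny-on-conflict semantics; a refused operation changes nothing.
* **Synthetic data** — 3D Voronoi-cell volumes with bright cytoplasm
  (mean 200), dark membranes (mean 50) and Gaussian noise, plus
  false-merge/false-split scenario builders with ground truth for scoring.

## Worked example

Split a synthetic false merge (`python examples/02_false_merge_split.py`):

```
fixture: 3 cells in (40, 40, 40); cells 1+2 merged -> body 1
  merged body: 47102 voxels (truth: 26080 + 21022)
seeds: one per true cell at [(16, 10, 24), (27, 21, 9)] (x,y,z)
split regions: {1: 26073, 2: 21029} voxels (0 seeds dropped)
voxel agreement with ground truth: 0.9998
persisted as bodies [1, 4]; bodies now [1, 3, 4]
```

Two cells totalling 47 102 voxels were merged under one ID; one centroid
seed per true cell drives the watershed, and 99.98 % of voxels return to
the correct cell. On persisting, the largest region keeps the original ID 1
(so its annotations stay attached) and the other region receives the fresh
ID 4. The other scripts in `examples/` walk through sparse volumes and
pyramids, version diffs, lock-based collaboration, and the annotation
system, each printing the quantities it computes.

The same flow from the shell:

```sh
voxelproof --store demo fixtures generate --out fix --merge 1,2
voxelproof --store demo store ingest --labels fix/labels.h5 --grayscale fix/grayscale.h5
voxelproof --store demo split run --body 1 --seeds seeds.json --out result
```

Exit codes: 0 success, 1 validation error, 2 lock/consistency refusal.

## Scope

Rendering (spheres, meshes, shading), GUI interaction, skeletonization, and
network protocol compatibility with any particular volume database are out
of scope; this package is the data and algorithm layer such a client sits
on. See `docs/methods.md` for the model, determinization choices, and known
limitations.
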