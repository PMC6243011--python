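# Methods

This note records the models and procedures voxelproof implements, the
conventions and tie-breaks it fixes where the underlying ideas leave
freedom, and what its synthetic test bed does and does not demonstrate.

## Data model

**Grids and boxes.** Volumes are functions on a 3D voxel grid, stored
`[z, y, x]` (slice-major). Coordinates are 0-based; boxes are half-open
`[min, max)` on every axis, so emptiness is `min == max` on any axis and no
±1 conventions are needed. Stored voxels are non-negative; only ray origins
may be negative.

**Sparse volumes.** A body's binary mask is kept as maximal runs along x,
keyed `(z, y, x_start, length)` and sorted lexicographically. Runs on one
row never touch or overlap, so the run list is a canonical form: two masks
are equal iff their run lists are equal, which the round-trip and wire
format tests exploit. The choice of x as the run axis matches row-major
slice storage; the on-disk format (little-endian magic/scale/count header,
four signed 32-bit words per run) is this package's own and deliberately
not wire-compatible with any external service.

**Pyramids.** Level *s*+1 halves every axis of level *s*. Binary masks are
downsampled by OR pooling — a coarse voxel is foreground iff *any* child
is — because a coarse preview must not lose thin neurites; a 64³ body at
level 5 therefore spans exactly 1/32 of its extent per axis. OR pooling
makes downsampling monotone (`A ⊆ B ⇒ down(A) ⊆ down(B)`) and
compositional (`down(down(m,1),1) = down(m,2)`), both property-tested.

**Blocks.** Labels and grayscale are managed in cubic blocks (edge a power
of two, default 32 voxels — the typical granularity of block-indexed volume
services). Grayscale for a body is fetched as *whole* blocks covering its
mask: slightly more bytes, no server-side slicing.

**Versions.** The label store keeps one block-map layer per committed
version plus one mutable tip; reads fall through to the nearest ancestor
layer holding the addressed block. Commits are therefore O(1), branches
share storage, and committed layers are immutable by construction (the
mutation API only touches the tip; `state_hash` lets tests verify this).
`branch(parent)` discards uncommitted tip edits — the tip is a workspace,
not a version. The ID allocator is a monotone counter and never reissues.

## Splitting false merges

The split engine floods the body's grayscale from user-labeled seeds.
Because EM membranes image darker than cytoplasm, flooding priority is
`255 − intensity`: bright voxels flood first and competing fronts meet at
the dark membrane ridge. No edge enhancement or boundary map is computed —
running directly on grayscale trades a little accuracy (dark organelles can
attract a boundary) for a much cheaper pipeline.

Determinization, where the physics does not decide:

* **priority queue** — ascending priority; FIFO within one priority level;
  all seeds enqueued first, in seed-set order. Implemented as a 256-bucket
  FIFO queue over the flattened volume, which realizes exactly the same pop
  order as a heap keyed `(priority, enqueue counter)`; the test suite and
  the acceptance script verify voxel-for-voxel equality against an
  independent naive heap implementation on hundreds of random instances.
* **connectivity** — 6-connected flooding and component analysis, which
  stops leaks through voxel corners across one-voxel membranes.
* **masking** — computation runs over the body's bounding box with
  out-of-body voxels masked; a voxel unreachable from any seed is label 0.

**Disconnected bodies.** Each 6-connected component floods independently
from the seeds it contains; output regions with equal seed labels are
joined across components; a component with no seed stays with the origin
body. A component whose seeds carry one label is assigned wholesale without
flooding. The operation as a whole still requires ≥ 2 surviving distinct
labels — with fewer, there is nothing to split.

**Bounded splitting.** A user box restricts the watershed to `mask ∩ box`.
Afterwards each 6-connected component of `mask \ box` is attached to the
in-box region it touches; if it touches several, the one with the largest
face-contact count wins (ties → smallest label); if none, it joins the
residual. When the box contains the whole merging border (every voxel
6-adjacent to a different region), each outside component touches exactly
one region, and the bounded result reproduces the unbounded one — verified
exactly over 100+ random border-containing boxes on noisy fixtures.
*Known limitation:* on an exactly constant intensity plateau (noise-free
synthetic data), the FIFO tie order inside the box can differ from the
unbounded run and swap individual membrane voxels between regions;
measured ≈ 15 % of boxes on noiseless fixtures, 0 % at the default noise
level. Real EM grayscale has no exact plateaus.

**Previews.** `local_preview` is bounded splitting with box = the seeds'
tight bounding box dilated by a margin, minus the reattachment step:
everything outside the box stays residual. It is a seed-quality check, not
a final result; preview regions are always subsets of the corresponding
bounded regions.

**Ray seeds.** Painting a single point in 3D shoots a ray (3D DDA voxel
traversal) through the body; seeds are the foreground voxels between the
first and last hits inclusive, with gap voxels along the ray excluded. A
miss yields an empty seed set (a warning, not an error).

**Giant bodies.** If a body's bounding box exceeds the configured budget
(default 10⁹ voxels), mask and grayscale are downsampled by 2^k until it
fits, the split runs at that scale, and each full-resolution voxel inherits
its parent coarse voxel's region. Boundary refinement at full resolution is
deliberately out of scope; the budget and the coarse assignment keep worst
cases responsive at the cost of a blocky boundary.

**Retention.** When a split is persisted, the largest region keeps the
original body ID (most annotations stay attached); other regions receive
fresh sequential IDs; uncovered voxels stay with the original body. Merge
retains the *first* ID in the user's list, matching merge-onto-anchor
interaction. Both retention rules are this package's explicit conventions.

## Annotations and coordination

Body-to-annotation association is position-based and resolved against the
current label volume at query time, so point marks (bookmarks, to-dos,
synapses) survive merges and splits without rewriting. Body-keyed records
(name, status) are rewritten through a sync hook when merges retire IDs;
on a name conflict the surviving body's record wins and the absorbed name
is appended to a comment log. The status vocabulary is closed at exactly
seven values. Synapse links are directed pre→post and structurally cannot
dangle: moving an element rewrites its link endpoints, deleting an element
(or overwriting one with a different kind) deletes its incident links.

The librarian is an in-process lock table: at most one holder per body,
re-entrant grants, denial as a return value, no lease expiry. Mutating
store operations guard on the lock *before* touching anything, so a refused
mutation provably changes nothing (hash-checked). Merging requires locks on
all participant bodies.

## Synthetic test bed

`generate_cells` builds a 3D Voronoi partition of random sites: labels are
nearest-site indices (ties resolved deterministically by the KD-tree), and
voxels within `membrane_width` of an inter-cell face get membrane intensity
(default mean 50) while the rest get cytoplasm intensity (default mean
200), plus clipped i.i.d. Gaussian noise. Defaults — 40³ voxels, 4 cells,
width-1 membranes, σ = 10 — give a 15σ intensity separation, comfortably
inside the regime the watershed assumes (membranes darker than cytoplasm).
Scenario builders create false merges (union of cells under one ID) and
false splits (plane cut through one cell), returning ground truth for
scoring; `voxel_agreement` scores a split against the generating cells via
the centroid-seed correspondence.

What this emulates: the intensity ordering, closed membranes, compact
convex-ish compartments, block-scale geometry. What it does not: EM
texture, organelles, anisotropy, staining gradients, open or ambiguous
membranes. Passing here shows the machinery is correct and deterministic
under the stated model, not that segmentation of real tissue reaches the
same agreement.

## Problem sizes and numerical choices

The test suite and acceptance script use volumes of 32³–64³ voxels, 2–6
cells, 500 random watershed instances up to 12³, 100+ random bounded-split
boxes, 20 recovery fixtures at 36³, 1 000-operation bookkeeping fuzz runs,
and a 4-user × 200-step lock harness — sizes chosen so the whole suite runs
in well under a minute on one CPU while exercising every code path,
including multi-block bodies and multi-level pyramids. Grayscale is fixed
8-bit (priorities are exact integers; no floating-point ties). All
randomness flows from explicit integer seeds; fixture generation is
bit-reproducible.
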