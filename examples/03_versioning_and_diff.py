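"""Checkpoints, branches, and green/red/gray body diffs.

The store keeps committed versions immutable and lets the working tip
mutate; a body's change between two versions decomposes into added (green),
removed (red) and unchanged (gray) voxel sets.
"""

import numpy as np

import voxelproof as vp

store = vp.VersionedLabelStore()
labels = np.zeros((16, 16, 16), np.uint64)
labels[:, :, :8] = 1
labels[:, :, 8:] = 2
store.put_labels(labels)
v0 = store.commit()
print(f"committed {v0.value}: bodies {sorted(store.bodies(v0))}")

store.merge_bodies([1, 2], "")  # no librarian attached -> unguarded demo merge
v1 = store.commit()
print(f"after merge, committed {v1.value}: bodies {sorted(store.bodies(v1))}")

diff = store.body_diff(v0, v1, 1)
print(f"body 1 diff {v0.value} -> {v1.value}: {diff.summary()}")
print(f"  display coding: {diff.DISPLAY_CODING}")
print("  -> body 1 gained body 2's 2048 voxels (green); its original half is gray")

# the committed past is immutable: v0 still sees the pre-merge body
print(f"body 1 in {v0.value}: {store.get_body_sparse(1, version=v0).voxel_count} voxels;"
      f" in {v1.value}: {store.get_body_sparse(1, version=v1).voxel_count}")

# branch from v0 and proofread differently
store.branch(v0)
store.put_labels(np.full((4, 4, 4), 9, np.uint64))
v2 = store.commit()
print(f"branch from {v0.value} -> {v2.value}: bodies {sorted(store.bodies(v2))}")
print(f"  {v1.value} is untouched: bodies {sorted(store.bodies(v1))}")
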