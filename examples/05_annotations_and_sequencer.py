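"""Workflow annotations: statuses, marks, synapses, and the sequencer table.

Annotations organize the proofreading effort: body statuses track progress,
to-dos form a shared checklist, bookmarks are private notes, and synapses
(pre -> post links) carry the connectome itself. Point marks follow voxels
through merges automatically because body association is resolved against
the current labels at query time.
"""

import numpy as np

import voxelproof as vp
from voxelproof.geometry import Coordinate

spec = vp.FixtureSpec(shape=(32, 32, 32), n_cells=3, noise_sigma=5.0, rng_seed=8)
gray, labels = vp.generate_cells(spec)
lib = vp.Librarian()
store = vp.VersionedLabelStore(librarian=lib)
store.put_labels(labels.astype(np.uint64))
annot = vp.AnnotationStore(store)

annot.set_body_name(1, "KC-a")
annot.set_body_name(2, "KC-b")
annot.set_body_name(3, "MBON-1")
annot.set_body_status(3, "hard to trace")
print(f"statuses: {[annot.get_body_status(b) for b in (1, 2, 3)]}")

# a pre->post synapse from body 1 into body 2
p1 = Coordinate(*(int(v) for v in np.argwhere(labels == 1)[0][::-1]))
p2 = Coordinate(*(int(v) for v in np.argwhere(labels == 2)[0][::-1]))
annot.add_synapse(p1, "pre", confidence=0.9)
annot.add_synapse(p2, "post", confidence=0.8)
annot.link_synapses(p1, p2)
print(f"synapse link {tuple(p1)} -> {tuple(p2)} (directed pre->post)")

annot.add_todo(p2, action="to merge")
annot.add_bookmark(p1, "false merge", "looks suspicious", owner="alice")
print("bob sees", len(annot.query_annotations(user='bob')["bookmarks"]),
      "bookmarks; alice sees", len(annot.query_annotations(user='alice')["bookmarks"]))

print("\nsequencer (names matching 'KC.*', most synapses first):")
print(annot.sequencer_query("KC.*", sort_key="synapse_count", descending=True).to_string(index=False))

# merge: annotations of the absorbed body follow the surviving ID
for b in (1, 2):
    lib.acquire(b, "alice")
store.merge_bodies([1, 2], "alice")
print(f"\nafter merging 2 into 1: body-1 todos={len(annot.query_annotations(body=1)['todos'])},"
      f" name={annot.get_body_name(1)!r}")
print("  -> the to-do placed on body 2 now answers to body 1; no stale IDs remain")
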