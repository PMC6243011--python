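"""Two proofreaders, one body: lock-based coordination.

Every mutating operation must hold the body's exclusive lock; a conflicting
request is denied (a value, not a crash) and a denied client cannot change
the store at all.
"""

import numpy as np

import voxelproof as vp

lib = vp.Librarian()
store = vp.VersionedLabelStore(librarian=lib)
labels = np.zeros((8, 8, 8), np.uint64)
labels[:4], labels[4:] = 5, 9
store.put_labels(labels)

print("alice locks body 5:", lib.acquire(5, "alice"))
print("bob asks for body 5:", lib.acquire(5, "bob"))
print("  -> denial names the holder so bob can move on to another body")

h = store.state_hash()
try:
    store.merge_bodies([5, 9], "bob")
except vp.LockError as exc:
    print(f"bob's merge refused: {exc}")
print(f"store unchanged after refusal: {store.state_hash() == h}")

lib.acquire(9, "alice")
target = store.merge_bodies([5, 9], "alice")
print(f"alice (holding both locks) merges -> body {target}; bodies now {sorted(store.bodies())}")

lib.release(5, "alice")
print("alice releases; bob retries:", lib.acquire(5, "bob"))
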