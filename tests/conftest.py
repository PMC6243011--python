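import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `reference` importable

import voxelproof as vp


@pytest.fixture
def rng():
    return np.random.default_rng(20240914)


@pytest.fixture
def random_mask(rng):
    """Random 8x8x8 binary mask with moderate fill."""
    return rng.random((8, 8, 8)) < 0.35


@pytest.fixture
def voronoi_fixture():
    """3-cell volume at the default noise regime plus its 1–2 false merge."""
    spec = vp.FixtureSpec(shape=(32, 32, 32), n_cells=3, noise_sigma=10.0, rng_seed=11)
    gray, labels = vp.generate_cells(spec)
    merged, mapping = vp.make_false_merge(labels, [1, 2])
    return gray, labels, merged, mapping


@pytest.fixture
def loaded_store():
    """Store + librarian + annotations over a 4-cell fixture volume."""
    spec = vp.FixtureSpec(shape=(32, 32, 32), n_cells=4, noise_sigma=5.0, rng_seed=5)
    gray, labels = vp.generate_cells(spec)
    lib = vp.Librarian()
    store = vp.VersionedLabelStore(librarian=lib)
    store.put_labels(labels.astype(np.uint64))
    store.set_grayscale(gray)
    annot = vp.AnnotationStore(store)
    return store, lib, annot, gray, labels
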