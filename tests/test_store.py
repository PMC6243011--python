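"""Versioned label store: ingest, retrieval, merge/split, versions, diffs."""

import numpy as np
import pytest

import voxelproof as vp
from voxelproof.geometry import Coordinate


def make_store(labels=None, gray=None, librarian=None):
    store = vp.VersionedLabelStore(librarian=librarian)
    if labels is not None:
        store.put_labels(labels.astype(np.uint64))
    if gray is not None:
        store.set_grayscale(gray)
    return store


class TestIngest:
    def test_zero_array_is_semantically_background(self):
        store = make_store()
        store.put_labels(np.zeros((32, 32, 32), np.uint64))
        assert store.bodies() == set()
        assert store.total_foreground() == 0

    def test_read_back_any_voxel(self, rng):
        labels = rng.integers(0, 4, size=(16, 16, 16)).astype(np.uint64)
        store = make_store(labels)
        for _ in range(20):
            z, y, x = (int(v) for v in rng.integers(0, 16, size=3))
            assert store.label_at(Coordinate(x, y, z)) == labels[z, y, x]

    def test_offset_ingest_populates_expected_block_column(self):
        store = vp.VersionedLabelStore(vp.BlockSpec(32))
        store.put_labels(np.ones((32, 32, 32), np.uint64), Coordinate(32, 0, 0))
        cover = vp.block_cover(store.get_body_sparse(1), vp.BlockSpec(32))
        assert cover == [(0, 0, 1)]

    def test_write_to_committed_version_refused(self):
        store = make_store(np.ones((8, 8, 8), np.uint64))
        vid = store.commit()
        with pytest.raises(vp.ImmutabilityError):
            store.put_labels(np.zeros((8, 8, 8), np.uint64), version=vid)

    def test_negative_offset_rejected(self):
        with pytest.raises(vp.ValidationError):
            make_store().put_labels(np.ones((4, 4, 4), np.uint64), Coordinate(-1, 0, 0))


class TestBodyRetrieval:
    def test_one_voxel_body_single_run(self):
        labels = np.zeros((8, 8, 8), np.uint64)
        labels[3, 4, 5] = 7
        rle = make_store(labels).get_body_sparse(7)
        assert rle.runs.tolist() == [[3, 4, 5, 1]] and rle.body_id == 7

    def test_scale5_extent_ratio_is_32(self):
        rle5 = make_store(np.ones((64, 64, 64), np.uint64)).get_body_sparse(1, scale=5)
        assert rle5.bounding_box.shape_zyx == (2, 2, 2)
        assert rle5.voxel_count == 8

    def test_scale0_mask_equals_per_voxel_scan(self, rng):
        labels = rng.integers(0, 3, size=(20, 20, 20)).astype(np.uint64)
        labels[0, 0, 0] = 1  # ensure body 1 exists
        store = make_store(labels)
        dense, off = vp.rle_decode(
            store.get_body_sparse(1), vp.BoundingBox.from_shape(labels.shape)
        )
        assert np.array_equal(dense, labels == 1)

    def test_scale_s_equals_downsampled_scale_0(self, rng):
        labels = (rng.random((40, 40, 40)) < 0.2).astype(np.uint64) * 3
        store = make_store(labels)
        for s in (1, 2, 4):
            assert store.get_body_sparse(3, s) == vp.downsample_mask(
                store.get_body_sparse(3, 0), s
            )

    def test_unknown_body_not_found(self):
        with pytest.raises(vp.BodyNotFoundError):
            make_store(np.ones((4, 4, 4), np.uint64)).get_body_sparse(99)


class TestProgressiveFetch:
    def test_tiny_body_yields_every_scale(self):
        labels = np.zeros((8, 8, 8), np.uint64)
        labels[0, 0, :10] = 2
        store = make_store(labels)
        scales = [r.scale for r in store.progressive_fetch(2, 10**6)]
        assert scales == [5, 4, 3, 2, 1, 0]

    def test_stops_after_first_scale_exceeding_threshold(self):
        store = make_store(np.ones((64, 64, 64), np.uint64))
        fetched = list(store.progressive_fetch(1, 100))
        assert [r.scale for r in fetched] == [5, 4, 3]
        assert fetched[-1].voxel_count == 512  # 8^3 > 100

    def test_zero_threshold_yields_only_coarsest(self):
        store = make_store(np.ones((16, 16, 16), np.uint64))
        fetched = list(store.progressive_fetch(1, 0))
        assert len(fetched) == 1 and fetched[0].scale == 5

    def test_scales_strictly_decrease(self):
        store = make_store(np.ones((32, 32, 32), np.uint64))
        scales = [r.scale for r in store.progressive_fetch(1, 10)]
        assert scales == sorted(scales, reverse=True) and len(set(scales)) == len(scales)


class TestGrayscaleFetch:
    def test_one_voxel_body_fetches_one_whole_block(self, rng):
        labels = np.zeros((64, 64, 64), np.uint64)
        labels[5, 6, 7] = 1
        gray = rng.integers(0, 256, size=(64, 64, 64)).astype(np.uint8)
        patches = make_store(labels, gray).fetch_body_grayscale(1).patches
        assert len(patches) == 1
        idx, arr = patches[0]
        assert idx == (0, 0, 0) and arr.shape == (32, 32, 32)
        assert np.array_equal(arr, gray[:32, :32, :32])

    def test_body_straddling_two_blocks_fetches_two(self, rng):
        labels = np.zeros((64, 64, 64), np.uint64)
        labels[0, 0, 30:34] = 1
        gray = rng.integers(0, 256, size=(64, 64, 64)).astype(np.uint8)
        patches = make_store(labels, gray).fetch_body_grayscale(1).patches
        assert [p[0] for p in patches] == [(0, 0, 0), (0, 0, 1)]

    def test_assembled_patches_match_masked_dense_grayscale(self, rng):
        labels = (rng.random((48, 48, 48)) < 0.1).astype(np.uint64)
        labels[0, 0, 0] = 1
        gray = rng.integers(0, 256, size=(48, 48, 48)).astype(np.uint8)
        store = make_store(labels, gray)
        rle = store.get_body_sparse(1)
        box = vp.BoundingBox.from_shape(labels.shape)
        assembled = store.fetch_body_grayscale(1).assemble(box)
        mask = labels == 1
        assert np.array_equal(assembled[mask], gray[mask])

    def test_missing_grayscale_is_configuration_error(self):
        with pytest.raises(vp.ConfigurationError):
            make_store(np.ones((8, 8, 8), np.uint64)).fetch_body_grayscale(1)


class TestMerge:
    def three_body_store(self):
        labels = np.zeros((12, 12, 12), np.uint64)
        labels[:4] = 5
        labels[4:8] = 9
        labels[8:] = 12
        lib = vp.Librarian()
        store = make_store(labels, librarian=lib)
        return store, lib

    def test_merge_assigns_target_id_and_retires_others(self):
        store, lib = self.three_body_store()
        for b in (5, 9, 12):
            lib.acquire(b, "alice")
        target = store.merge_bodies([5, 9, 12], "alice")
        assert target == 5
        assert store.bodies() == {5}
        assert store.get_body_sparse(5).voxel_count == 12 * 12 * 12

    def test_merged_mask_is_union(self):
        store, lib = self.three_body_store()
        a = store.get_body_sparse(5)
        b = store.get_body_sparse(9)
        lib.acquire(5, "u")
        lib.acquire(9, "u")
        store.merge_bodies([5, 9], "u")
        assert store.get_body_sparse(5).voxel_count == a.voxel_count + b.voxel_count

    def test_voxel_count_conserved(self):
        store, lib = self.three_body_store()
        before = store.total_foreground()
        for b in (5, 9):
            lib.acquire(b, "u")
        store.merge_bodies([5, 9], "u")
        assert store.total_foreground() == before

    def test_unlocked_merge_refused_and_store_unchanged(self):
        store, lib = self.three_body_store()
        lib.acquire(5, "alice")  # 9 not locked
        h = store.state_hash()
        with pytest.raises(vp.LockError):
            store.merge_bodies([5, 9], "alice")
        assert store.state_hash() == h

    def test_unknown_id_not_found(self):
        store, lib = self.three_body_store()
        with pytest.raises(vp.BodyNotFoundError):
            store.merge_bodies([5, 77], "u")


class TestApplySplit:
    def split_fixture(self):
        labels = np.zeros((10, 10, 10), np.uint64)
        labels[:, :, :] = 4
        lib = vp.Librarian()
        store = make_store(labels, librarian=lib)
        lib.acquire(4, "u")
        return store, lib

    def regions_from(self, store, frac):
        """Partition body 4 by an x-plane at ``frac`` of its width."""
        rle = store.get_body_sparse(4)
        dense, off = vp.rle_decode(rle)
        cut = int(dense.shape[2] * frac)
        r1 = vp.rle_encode(np.pad(dense[:, :, :cut], ((0, 0), (0, 0), (0, dense.shape[2] - cut))), off)
        r2 = vp.rle_encode(
            np.pad(dense[:, :, cut:], ((0, 0), (0, 0), (cut, 0))), off
        )
        return {1: r1, 2: r2}

    def test_whole_body_single_region_is_identity(self):
        store, _ = self.split_fixture()
        ids_before = store.bodies()
        mapping = store.apply_split(4, vp.SplitResult({1: store.get_body_sparse(4)}, vp.RLESparseVolume()), "u")
        assert mapping == {1: 4}
        assert store.bodies() == ids_before

    def test_largest_region_keeps_original_id(self):
        store, _ = self.split_fixture()
        regions = self.regions_from(store, 0.6)  # region 1 has 60%
        mapping = store.apply_split(4, vp.SplitResult(regions, vp.RLESparseVolume()), "u")
        assert mapping[1] == 4 and mapping[2] != 4
        assert store.get_body_sparse(mapping[2]).voxel_count == 400

    def test_voxel_conservation_with_residual(self):
        store, _ = self.split_fixture()
        regions = self.regions_from(store, 0.5)
        # shrink region 2 so some voxels stay with the origin body
        dense, off = vp.rle_decode(regions[2])
        dense[:, :5, :] = False
        regions[2] = vp.rle_encode(dense, off)
        before = store.total_foreground()
        mapping = store.apply_split(4, vp.SplitResult(regions, vp.RLESparseVolume()), "u")
        assert store.total_foreground() == before
        sizes = sum(store.get_body_sparse(b).voxel_count for b in store.bodies())
        assert sizes == before

    def test_region_outside_body_is_consistency_error(self):
        store, _ = self.split_fixture()
        bad = vp.RLESparseVolume(np.array([[50, 50, 50, 3]]))
        with pytest.raises(vp.ConsistencyError):
            store.apply_split(4, vp.SplitResult({1: bad, 2: store.get_body_sparse(4)}, vp.RLESparseVolume()), "u")

    def test_unlocked_split_refused(self):
        labels = np.full((6, 6, 6), 3, np.uint64)
        lib = vp.Librarian()
        store = make_store(labels, librarian=lib)
        h = store.state_hash()
        with pytest.raises(vp.LockError):
            store.apply_split(3, vp.SplitResult({1: store.get_body_sparse(3)}, vp.RLESparseVolume()), "nobody")
        assert store.state_hash() == h


class TestVersions:
    def test_committed_version_immutable_under_tip_edits(self):
        labels = np.full((8, 8, 8), 2, np.uint64)
        store = make_store(labels)
        v0 = store.commit()
        h0 = store.state_hash(v0)
        store.put_labels(np.full((8, 8, 8), 6, np.uint64))
        assert store.get_body_sparse(2, version=v0).voxel_count == 512
        assert store.state_hash(v0) == h0
        with pytest.raises(vp.BodyNotFoundError):
            store.get_body_sparse(2)  # tip overwritten

    def test_two_branches_diverge_independently(self):
        store = make_store(np.full((8, 8, 8), 2, np.uint64))
        v0 = store.commit()
        store.put_labels(np.full((8, 8, 8), 3, np.uint64))
        va = store.commit()
        store.branch(v0)
        store.put_labels(np.full((8, 8, 8), 4, np.uint64))
        vb = store.commit()
        assert store.bodies(va) == {3}
        assert store.bodies(vb) == {4}
        assert store.bodies(v0) == {2}

    def test_read_through_returns_nearest_ancestor(self):
        """Chain of commits behaves like layered maps over block writes."""
        store = vp.VersionedLabelStore(vp.BlockSpec(8))
        store.put_labels(np.full((8, 8, 8), 1, np.uint64))  # block (0,0,0)
        store.put_labels(np.full((8, 8, 8), 2, np.uint64), Coordinate(8, 0, 0))
        v0 = store.commit()
        store.put_labels(np.full((8, 8, 8), 3, np.uint64), Coordinate(8, 0, 0))
        v1 = store.commit()
        store.put_labels(np.full((8, 8, 8), 4, np.uint64))
        v2 = store.commit()
        # reference model: dict updated layer by layer
        assert store.bodies(v0) == {1, 2}
        assert store.bodies(v1) == {1, 3}
        assert store.bodies(v2) == {4, 3}
        assert store.label_at(Coordinate(0, 0, 0), v1) == 1  # from v0 layer
        assert store.label_at(Coordinate(8, 0, 0), v2) == 3  # from v1 layer

    def test_branch_from_unknown_version_not_found(self):
        with pytest.raises(vp.VersionNotFoundError):
            make_store().branch("v99")


class TestBodyDiff:
    def test_identical_versions_all_unchanged(self):
        store = make_store(np.full((6, 6, 6), 5, np.uint64))
        v0 = store.commit()
        v1 = store.commit()
        diff = store.body_diff(v0, v1, 5)
        assert diff.summary() == {"added": 0, "removed": 0, "unchanged": 216}

    def test_one_row_interval_shift(self):
        store = vp.VersionedLabelStore()
        row = np.zeros((1, 1, 8), np.uint64)
        row[0, 0, 0:5] = 9
        store.put_labels(row)
        va = store.commit()
        row2 = np.zeros((1, 1, 8), np.uint64)
        row2[0, 0, 2:7] = 9
        store.put_labels(row2)
        vb = store.commit()
        diff = store.body_diff(va, vb, 9)
        assert diff.removed.runs.tolist() == [[0, 0, 0, 2]]
        assert diff.unchanged.runs.tolist() == [[0, 0, 2, 3]]
        assert diff.added.runs.tolist() == [[0, 0, 5, 2]]

    def test_random_pair_matches_set_oracle(self, rng):
        store = vp.VersionedLabelStore()
        a = (rng.random((10, 10, 10)) < 0.4).astype(np.uint64) * 7
        b = (rng.random((10, 10, 10)) < 0.4).astype(np.uint64) * 7
        store.put_labels(a)
        va = store.commit()
        store.put_labels(b)
        vb = store.commit()
        diff = store.body_diff(va, vb, 7)
        box = vp.BoundingBox.from_shape((10, 10, 10))
        added, _ = vp.rle_decode(diff.added, box)
        removed, _ = vp.rle_decode(diff.removed, box)
        unchanged, _ = vp.rle_decode(diff.unchanged, box)
        assert np.array_equal(added, (b == 7) & ~(a == 7))
        assert np.array_equal(removed, (a == 7) & ~(b == 7))
        assert np.array_equal(unchanged, (a == 7) & (b == 7))
        # pairwise disjoint partition identities
        assert not (added & removed).any()
        assert not (added & unchanged).any()
        assert np.array_equal(added | unchanged, b == 7)
        assert np.array_equal(removed | unchanged, a == 7)

    def test_body_in_neither_version_not_found(self):
        store = make_store(np.full((4, 4, 4), 1, np.uint64))
        v0 = store.commit()
        with pytest.raises(vp.BodyNotFoundError):
            store.body_diff(v0, v0, 42)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        labels = rng.integers(0, 4, size=(20, 20, 20)).astype(np.uint64)
        gray = rng.integers(0, 256, size=(20, 20, 20)).astype(np.uint8)
        store = make_store(labels, gray)
        v0 = store.commit()
        store.put_labels(np.full((4, 4, 4), 9, np.uint64))
        store.save(tmp_path / "store")
        again = vp.VersionedLabelStore.load(tmp_path / "store")
        assert again.state_hash() == store.state_hash()
        assert again.state_hash(v0.value) == store.state_hash(v0)
        assert again.bodies() == store.bodies()
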