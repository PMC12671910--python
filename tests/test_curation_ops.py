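"""Editing-operator contracts: conservation, idempotence, exact diffs."""

import numpy as np
import pytest
from skimage.morphology import ball as digital_ball

from segcurate import (
    Dataset,
    IntensityVolume,
    LabeledVolume,
    Selection,
    SynthConfig,
    copy_paste_label,
    delete_labels,
    fuse_labels,
    generate_nuclei_timelapse,
    gmm_split,
    inject_errors,
    morphology_transform,
    remove_small_labels,
    split_along_axis,
    split_disconnected,
    threshold_segment,
)
from segcurate.curation_ops import diff_labels, rotation_matrix

from conftest import ball_volume


def foreground(vol):
    return int((vol.data > 0).sum())


@pytest.fixture
def two_touching():
    data = np.zeros((8, 8, 12), dtype=int)
    data[2:6, 2:6, 2:5] = 1   # 48 voxels
    data[2:6, 2:6, 5:10] = 2  # 80 voxels
    return LabeledVolume(data)


class TestFuseDelete:
    def test_fuse_conserves_foreground_into_smallest_id(self, two_touching):
        res = fuse_labels(two_touching, [1, 2])
        assert foreground(res.volume) == foreground(two_touching)
        assert set(res.volume.labels()) == {1}
        assert res.changed_labels == {1, 2}

    def test_fuse_single_label_is_noop_with_warning(self, two_touching):
        res = fuse_labels(two_touching, [1])
        assert np.array_equal(res.volume.data, two_touching.data)
        assert res.warnings

    def test_fuse_groups_apply_per_time(self):
        frames = []
        for t in range(3):
            data = np.zeros((6, 6, 10), dtype=int)
            data[1:5, 1:5, 1:4] = 1
            data[1:5, 1:5, 4:8] = 2
            frames.append(LabeledVolume(data, time=t))
        sel = Selection(groups={"A": {(t, 0, 1) for t in range(3)}
                                | {(t, 0, 2) for t in range(3)}})
        for vol in frames:
            res = fuse_labels(vol, sel)
            assert set(res.volume.labels()) == {1}

    def test_delete_shrinks_foreground_exactly(self, two_touching):
        res = delete_labels(two_touching, [1])
        assert foreground(res.volume) == foreground(two_touching) - 48
        assert 2 in res.volume.data

    def test_delete_all_empties_volume(self, two_touching):
        res = delete_labels(two_touching, [1, 2])
        assert foreground(res.volume) == 0

    def test_delete_absent_id_warns_without_change(self, two_touching):
        res = delete_labels(two_touching, [99])
        assert np.array_equal(res.volume.data, two_touching.data)
        assert res.warnings


class TestRemoveSmall:
    def test_delete_mode_keeps_only_large_objects(self):
        data = np.zeros((16, 16, 16), dtype=int)
        data[1:3, 1:3, 1:3] = 1                     # 8 voxels
        data[3:15, 3:15, 3:15] = 2                  # 1728 voxels
        res = remove_small_labels(LabeledVolume(data), 1000, mode="delete")
        assert set(res.volume.labels()) == {2}
        assert foreground(res.volume) == 1728

    def test_fuse_mode_goes_to_largest_contact_surface(self):
        data = np.zeros((10, 10, 14), dtype=int)
        data[2:8, 2:8, 2:5] = 1
        data[2:8, 2:8, 7:11] = 2
        # small object bridges the gap: 2x2 face against label 1 (4 contacts),
        # 3x3 face against label 2 (9 contacts)
        data[3:5, 3:5, 5] = 3
        data[3:6, 3:6, 6] = 3
        vol = LabeledVolume(data)
        res = remove_small_labels(vol, 30, mode="fuse_to_max_contact")
        assert 3 not in res.volume.data
        assert foreground(res.volume) == foreground(vol)
        assert np.all(res.volume.data[3:6, 3:6, 6] == 2)

    def test_fuse_mode_deletes_isolated_small_object(self):
        data = np.zeros((10, 10, 10), dtype=int)
        data[1:3, 1:3, 1:3] = 1
        data[6:9, 6:9, 6:9] = 2
        res = remove_small_labels(LabeledVolume(data), 10, mode="fuse_to_max_contact")
        assert set(res.volume.labels()) == {2}
        assert res.warnings


class TestSplits:
    def test_disconnected_components_get_distinct_ids(self):
        data = np.zeros((6, 6, 12), dtype=int)
        data[1:5, 1:5, 1:4] = 7
        data[1:5, 1:5, 8:11] = 7
        res = split_disconnected(LabeledVolume(data))
        assert len(res.volume.labels()) == 2
        assert 7 in res.volume.labels()  # largest (or first) keeps the id

    def test_connected_label_unchanged_and_idempotent(self, cube_volume):
        res = split_disconnected(cube_volume)
        assert np.array_equal(res.volume.data, cube_volume.data)
        data = np.zeros((6, 6, 12), dtype=int)
        data[1:5, 1:5, 1:4] = 7
        data[1:5, 1:5, 8:11] = 7
        once = split_disconnected(LabeledVolume(data))
        twice = split_disconnected(once.volume)
        assert np.array_equal(once.volume.data, twice.volume.data)

    def test_splax_even_bar_splits_in_equal_halves(self):
        bar = np.zeros((5, 5, 12), dtype=int)
        bar[1:4, 1:4, 1:11] = 1
        res = split_along_axis(LabeledVolume(bar), [1], axis="x")
        sizes = sorted(
            int((res.volume.data == l).sum()) for l in res.volume.labels()
        )
        assert sizes == [45, 45]

    def test_splax_odd_bar_gives_lower_half_smaller(self):
        bar = np.zeros((5, 5, 13), dtype=int)
        bar[1:4, 1:4, 1:12] = 1  # length 11 along x
        res = split_along_axis(LabeledVolume(bar), [1], axis="x")
        low = int((res.volume.data[:, :, 1:6] > 0).sum())
        high = int((res.volume.data[:, :, 6:12] > 0).sum())
        lab_low = res.volume.data[2, 2, 1]
        lab_high = res.volume.data[2, 2, 11]
        assert (res.volume.data == lab_low).sum() == 45   # 5 slabs
        assert (res.volume.data == lab_high).sum() == 54  # 6 slabs

    def test_splax_ball_hemispheres_balanced(self):
        vol = ball_volume(7)
        res = split_along_axis(vol, [1], axis="z")
        sizes = sorted(int((res.volume.data == l).sum()) for l in res.volume.labels())
        assert abs(sizes[0] - sizes[1]) <= (vol.data > 0).sum() * 0.2
        assert sum(sizes) == (vol.data > 0).sum()

    def test_splax_thin_object_is_noop(self):
        data = np.zeros((5, 5, 5), dtype=int)
        data[2, 1:4, 1:4] = 1
        res = split_along_axis(LabeledVolume(data), [1], axis="z")
        assert np.array_equal(res.volume.data, data)
        assert res.warnings


class TestGmmSplit:
    def test_two_separated_blobs_recovered_near_kmeans_oracle(self):
        from sklearn.cluster import KMeans

        data = np.zeros((16, 16, 34), dtype=int)
        b = digital_ball(6)
        data[2:15, 2:15, 2:15][b > 0] = 1
        data[2:15, 2:15, 19:32][b > 0] = 1
        img = np.full(data.shape, 20.0)
        zz, yy, xx = np.indices(data.shape)
        for cx in (8, 25):
            img += 180 * np.exp(-(((zz - 8) ** 2 + (yy - 8) ** 2
                                   + (xx - cx) ** 2) / (2 * 9.0)))
        vol = LabeledVolume(data)
        res = gmm_split(vol, IntensityVolume(img), [1], n_components=2, seed=0)
        assert len(res.volume.labels()) == 2
        coords = np.argwhere(data == 1).astype(float)
        km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(coords)
        oracle_centers = sorted(map(tuple, km.cluster_centers_))
        got_centers = sorted(
            tuple(np.argwhere(res.volume.data == l).mean(axis=0))
            for l in res.volume.labels()
        )
        for g, o in zip(got_centers, oracle_centers):
            assert np.linalg.norm(np.array(g) - np.array(o)) < 1.0

    def test_homogeneous_ball_still_partitions(self):
        vol = ball_volume(6)
        img = IntensityVolume(np.full(vol.shape, 50.0))
        res = gmm_split(vol, img, [1], n_components=2, seed=1)
        labs = res.volume.labels()
        assert len(labs) == 2
        assert foreground(res.volume) == foreground(vol)

    def test_object_smaller_than_components_is_skipped(self):
        data = np.zeros((4, 4, 4), dtype=int)
        data[1, 1, 1] = 1
        res = gmm_split(LabeledVolume(data), None, [1], n_components=2, seed=0)
        assert np.array_equal(res.volume.data, data)
        assert res.warnings


class TestMorphology:
    def test_erode_subset_original_subset_dilate(self):
        vol = ball_volume(6)
        ero = morphology_transform(vol, [1], "erode", 2).volume
        dil = morphology_transform(vol, [1], "dilate", 2).volume
        assert np.all((ero.data > 0) <= (vol.data > 0))
        assert np.all((vol.data > 0) <= (dil.data > 0))

    @pytest.mark.parametrize("op", ["open", "close"])
    def test_open_close_idempotent(self, op):
        rng = np.random.default_rng(3)
        vol = ball_volume(7)
        noisy = vol.data.copy()
        coords = np.argwhere(noisy > 0)
        drop = coords[rng.choice(len(coords), 60, replace=False)]
        noisy[tuple(drop.T)] = 0
        vol = LabeledVolume(noisy)
        once = morphology_transform(vol, [1], op, 2).volume
        twice = morphology_transform(once, [1], op, 2).volume
        assert np.array_equal(once.data, twice.data)

    def test_convex_of_box_unchanged(self):
        data = np.zeros((10, 10, 10), dtype=int)
        data[2:8, 2:8, 2:8] = 1
        res = morphology_transform(LabeledVolume(data), [1], "convex")
        assert np.array_equal(res.volume.data, data)

    def test_dilation_never_overwrites_neighbors(self, two_touching):
        res = morphology_transform(two_touching, [1], "dilate", 2)
        assert np.array_equal(res.volume.data == 2, two_touching.data == 2)

    def test_erosion_to_nothing_deletes_and_warns(self):
        data = np.zeros((6, 6, 6), dtype=int)
        data[2:4, 2:4, 2:4] = 1
        res = morphology_transform(LabeledVolume(data), [1], "erode", 3)
        assert foreground(res.volume) == 0
        assert res.warnings


class TestThreshold:
    def test_two_bright_blobs_become_two_labels(self):
        img = np.full((12, 12, 20), 10.0)
        img[3:7, 3:7, 3:7] = 200
        img[3:7, 3:7, 12:16] = 200
        vol = LabeledVolume(np.zeros(img.shape, int))
        res = threshold_segment(vol, IntensityVolume(img), 100)
        assert len(res.volume.labels()) == 2

    def test_threshold_above_max_warns_and_creates_nothing(self):
        img = np.full((6, 6, 6), 10.0)
        vol = LabeledVolume(np.zeros(img.shape, int))
        res = threshold_segment(vol, IntensityVolume(img), 999)
        assert len(res.volume.labels()) == 0
        assert res.warnings

    def test_per_object_scope_restricts_to_selected_mask(self):
        # membrane-channel cell with a bright nuclear-channel blob inside it
        # and another bright blob outside it
        data = np.zeros((14, 14, 24), dtype=int)
        data[2:12, 2:12, 2:12] = 5
        nuclear = np.full(data.shape, 15.0)
        nuclear[5:9, 5:9, 5:9] = 220      # inside cell 5
        nuclear[5:9, 5:9, 16:20] = 220    # outside
        vol = LabeledVolume(data)
        res = threshold_segment(vol, IntensityVolume(nuclear), 100,
                                scope="per_object", selection=[5])
        new = set(res.volume.labels()) - {5}
        assert len(new) == 1
        new_mask = res.volume.data == new.pop()
        assert np.all(data[new_mask] == 5)


class TestCopyPaste:
    def make_ds(self):
        ds = Dataset()
        data = np.zeros((26, 26, 26), dtype=int)
        b = digital_ball(6)
        data[3:16, 3:16, 3:16][b > 0] = 1
        ds.add(LabeledVolume(data, time=0))
        ds.add(LabeledVolume(np.zeros_like(data), time=1))
        return ds, data

    def test_identity_transform_copies_exactly(self):
        ds, data = self.make_ds()
        res = copy_paste_label(ds, (0, 1), 1)
        assert (ds.label_volume(1).data > 0).sum() == (data == 1).sum()

    def test_rotation_of_symmetric_object_preserves_volume(self):
        ds, data = self.make_ds()
        res = copy_paste_label(
            ds, (0, 1), 1, rotation=rotation_matrix("z", 180.0),
            translation=(4.0, 4.0, 4.0),
        )
        vol_in = (data == 1).sum()
        vol_out = (ds.label_volume(1).data > 0).sum()
        assert abs(vol_out - vol_in) / vol_in <= 0.02

    def test_paste_fully_onto_existing_label_is_error(self):
        ds, data = self.make_ds()
        ds.labels[(1, 0)] = LabeledVolume(np.full_like(data, 3), time=1)
        with pytest.raises(ValueError, match="collision"):
            copy_paste_label(ds, (0, 1), 1)


class TestChangedLabelDiffs:
    """changed_labels must equal the exhaustive voxel-set diff for every op."""

    @pytest.fixture(scope="class")
    @staticmethod
    def fixture_volume():
        cfg = SynthConfig(seed=9, n_objects=6, shape=(32, 40, 40),
                          radius_mean=5.0, n_touching_pairs=1)
        ds, _ = generate_nuclei_timelapse(cfg)
        return ds

    @pytest.mark.parametrize(
        "make_op",
        [
            lambda v, i: fuse_labels(v, [1, 2]),
            lambda v, i: delete_labels(v, [3]),
            lambda v, i: remove_small_labels(v, 200, mode="fuse_to_max_contact"),
            lambda v, i: split_along_axis(v, [4], axis="major"),
            lambda v, i: morphology_transform(v, [5], "dilate", 2),
            lambda v, i: gmm_split(v, i, [1], n_components=2, seed=0),
        ],
        ids=["fuse", "delete", "remove_small", "splax", "dilate", "gmm"],
    )
    def test_changed_labels_match_exhaustive_diff(self, fixture_volume, make_op):
        vol = fixture_volume.label_volume(0)
        res = make_op(vol, fixture_volume.intensity_volume(0))
        assert res.changed_labels == diff_labels(vol, res.volume)
        before = {
            int(l): set(map(tuple, np.argwhere(vol.data == l)))
            for l in vol.labels()
        }
        after = {
            int(l): set(map(tuple, np.argwhere(res.volume.data == l)))
            for l in res.volume.labels()
        }
        truly_changed = {
            l for l in set(before) | set(after)
            if before.get(l, set()) != after.get(l, set())
        }
        assert res.changed_labels == truly_changed
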