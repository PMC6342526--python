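"""Attractor labeling and label refinement: hand fixtures, oracle, invariants."""

import numpy as np
import pytest

from nucratio.segmentation import (
    LabelMap,
    Neighborhood,
    merge_by_depth,
    merge_by_distance,
    merge_small_to_closest,
    morph_labels,
    remove_by_intensity,
    remove_by_size,
    steepest_ascent_label,
)
from nucratio.stack import make_toy_volume


def brute_force_label(img, mask, offsets, spacing):
    """Independent parent-scan oracle: exhaustive neighbour loop per voxel,
    then flooding of the parent trees. Pure python, no vectorization."""
    shape = img.shape
    parents = {}
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        best_slope = 0.0
        best = idx
        for off in offsets:
            nb = tuple(i + o for i, o in zip(idx, off))
            if any(v < 0 or v >= s for v, s in zip(nb, shape)):
                continue
            if not mask[nb]:
                continue
            dist = float(np.linalg.norm(np.asarray(off) * np.asarray(spacing)))
            slope = (img[nb] - img[idx]) / dist
            if slope > best_slope:
                best_slope = slope
                best = nb
        parents[idx] = best

    def root(v):
        while parents[v] != v:
            v = parents[v]
        return v

    labels = np.zeros(shape, dtype=int)
    lut = {}
    for idx in parents:
        r = root(idx)
        if r not in lut:
            lut[r] = len(lut) + 1
        labels[idx] = lut[r]
    return labels


def assert_same_partition(a, b):
    """Label arrays equal up to relabeling (bijection between ids)."""
    assert a.shape == b.shape
    assert np.array_equal(a > 0, b > 0)
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    assert len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


def label_1d(values, **kw):
    return steepest_ascent_label(make_toy_volume(values), **kw)


class TestSteepestAscent:
    def test_single_monotone_peak_is_one_object(self):
        lm = label_1d([1, 2, 3, 2, 1])
        assert lm.n_objects == 1
        assert np.all(lm.labels > 0)
        assert lm.attractors[1] == 2  # flat index of the peak

    def test_valley_splits_by_steepest_slope(self):
        # voxel 1 ascends toward 5 (slope 4) not 4 (slope 3)
        lm = label_1d([5, 1, 4])
        assert lm.n_objects == 2
        assert lm.labels[0, 0, 0] == lm.labels[0, 0, 1]
        assert lm.labels[0, 0, 2] != lm.labels[0, 0, 0]
        attr = set(lm.attractors.values())
        assert attr == {0, 2}

    def test_plateau_fragments_into_singletons(self):
        lm = label_1d([2, 2, 2])
        assert lm.n_objects == 3

    def test_empty_mask_yields_empty_labelmap(self):
        stack = make_toy_volume([1, 2, 3])
        lm = steepest_ascent_label(stack, mask=np.zeros((1, 1, 3), dtype=bool))
        assert lm.n_objects == 0
        assert np.all(lm.labels == 0)

    def test_nonfinite_intensity_rejected(self):
        img = np.ones((2, 2, 2))
        img[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            steepest_ascent_label(img)

    def test_attractor_is_basin_maximum(self, rng):
        img = rng.uniform(0, 100, (6, 8, 8))
        lm = steepest_ascent_label(img)
        flat = img.ravel()
        for lab in lm.ids:
            basin_max = img[lm.labels == lab].max()
            assert flat[lm.attractors[int(lab)]] == basin_max

    def test_flip_equivariance(self, rng):
        # parents are pointwise, so mirroring the volume mirrors the labels
        img = rng.uniform(0, 50, (5, 7, 7))
        a = steepest_ascent_label(img).labels
        b = steepest_ascent_label(img[::-1, ::-1, ::-1]).labels[::-1, ::-1, ::-1]
        assert_same_partition(a, b)

    @pytest.mark.parametrize("kind", ["cross", "cubical", "spherical"])
    def test_matches_brute_force_oracle(self, rng, kind):
        hood = Neighborhood(kind, 1)
        spacing = (1.0, 0.5, 0.5)
        offsets = hood.offsets(spacing)
        for _ in range(10):
            shape = tuple(rng.integers(3, 8, size=3))
            img = rng.integers(0, 20, size=shape).astype(float)
            mask = rng.random(shape) < 0.8
            got = steepest_ascent_label(
                make_toy_volume(img, spacing=spacing), mask=mask, neighborhood=hood
            ).labels
            want = brute_force_label(img, mask, offsets, spacing)
            assert_same_partition(got, want)


class TestMergeByDistance:
    def _two_attractor_map(self, gap_vox):
        vals = np.ones(2 + gap_vox)
        vals[0] = 10.0
        vals[-1] = 8.0
        lm = label_1d(list(vals))
        return lm

    def test_within_threshold_merges(self):
        lm = label_1d([10, 1, 1, 8])  # attractors 3 um apart (unit spacing)
        assert lm.n_objects == 2
        merged = merge_by_distance(lm, 3.5)
        assert merged.n_objects == 1
        # merged attractor is the brighter one
        assert list(merged.attractors.values()) == [0]

    def test_beyond_threshold_unchanged(self):
        lm = label_1d([10, 1, 1, 8])
        merged = merge_by_distance(lm, 1.0)
        assert merged.n_objects == 2

    def test_transitive_chain_merges(self):
        # three peaks at x = 0, 2, 4 um with threshold 2.5: all merge
        lm = label_1d([9, 1, 8, 1, 7])
        assert lm.n_objects == 3
        merged = merge_by_distance(lm, 2.5)
        assert merged.n_objects == 1

    def test_idempotent(self):
        lm = label_1d([9, 1, 8, 1, 7])
        once = merge_by_distance(lm, 2.5)
        twice = merge_by_distance(once, 2.5)
        assert_same_partition(once.labels, twice.labels)


class TestMergeByDepth:
    def test_shallow_valley_merges(self):
        img = make_toy_volume([10, 2, 8])
        lm = steepest_ascent_label(img)
        assert lm.n_objects == 2
        # depth = min(10, 8) - 2 = 6 < 7 -> merge; attractor at index 0
        merged = merge_by_depth(lm, img, 7)
        assert merged.n_objects == 1
        assert list(merged.attractors.values()) == [0]

    def test_deep_valley_survives(self):
        img = make_toy_volume([10, 2, 8])
        lm = steepest_ascent_label(img)
        merged = merge_by_depth(lm, img, 5)
        assert merged.n_objects == 2

    def test_zero_threshold_never_merges(self, rng):
        img = rng.uniform(0, 30, (4, 6, 6))
        lm = steepest_ascent_label(img)
        merged = merge_by_depth(lm, img, 0)
        assert merged.n_objects == lm.n_objects

    def test_max_mode_uses_stronger_peak(self):
        # depth_max = max(10, 8) - 2 = 8, merges only at threshold > 8
        img = make_toy_volume([10, 2, 8])
        lm = steepest_ascent_label(img)
        assert merge_by_depth(lm, img, 7, mode="max").n_objects == 2
        assert merge_by_depth(lm, img, 9, mode="max").n_objects == 1

    def test_multiple_shallow_pairs_merge_in_one_call(self):
        # depths: left pair min(10,9)-3 = 6, right pair min(9,8)-5 = 3
        img = make_toy_volume([10, 3, 9, 5, 8])
        lm = steepest_ascent_label(img)
        assert lm.n_objects == 3
        assert merge_by_depth(lm, img, 7).n_objects == 1
        # threshold 6 only merges the shallow right pair (depth 3 < 6)
        assert merge_by_depth(lm, img, 6).n_objects == 2


class TestMergeSmallToClosest:
    def _map_with_sizes(self):
        # object A: 5 voxels around a 10-peak; object B: single 8-voxel
        img = make_toy_volume([1, 2, 10, 2, 1, 0, 0, 8])
        mask = np.array([[[1, 1, 1, 1, 1, 0, 0, 1]]], dtype=bool)
        return img, steepest_ascent_label(img, mask=mask)

    def test_small_absorbed_by_nearest_large(self):
        img, lm = self._map_with_sizes()
        assert lm.n_objects == 2
        merged = merge_small_to_closest(lm, size_threshold=3, max_merge_distance=10)
        assert merged.n_objects == 1
        assert merged.volumes_voxels()[1] == 6

    def test_distance_cap_blocks_merge(self):
        img, lm = self._map_with_sizes()
        merged = merge_small_to_closest(lm, size_threshold=3, max_merge_distance=1)
        assert merged.n_objects == 2

    def test_all_large_is_identity(self):
        img, lm = self._map_with_sizes()
        merged = merge_small_to_closest(lm, size_threshold=0.5)
        assert_same_partition(lm.labels, merged.labels)

    def test_no_large_object_leaves_all_unchanged(self):
        img, lm = self._map_with_sizes()
        merged = merge_small_to_closest(lm, size_threshold=100)
        assert_same_partition(lm.labels, merged.labels)


class TestRemove:
    def test_remove_by_size_keeps_large(self):
        img = make_toy_volume([1, 2, 10, 2, 1, 0, 0, 8])
        mask = np.array([[[1, 1, 1, 1, 1, 0, 0, 1]]], dtype=bool)
        lm = steepest_ascent_label(img, mask=mask)
        out = remove_by_size(lm, min_volume=2)
        assert out.n_objects == 1
        assert out.volumes_voxels()[1] == 5

    def test_remove_by_size_extremes(self):
        img = make_toy_volume([1, 2, 10, 2, 1])
        lm = steepest_ascent_label(img)
        assert remove_by_size(lm, 0).n_objects == lm.n_objects
        assert remove_by_size(lm, 1e9).n_objects == 0

    def test_remove_by_intensity(self):
        img = make_toy_volume([100, 90, 0, 20, 15])  # means 95 and 17.5
        mask = np.array([[[1, 1, 0, 1, 1]]], dtype=bool)
        lm = steepest_ascent_label(img, mask=mask)
        assert lm.n_objects == 2
        out = remove_by_intensity(lm, img, 50)
        assert out.n_objects == 1
        flat = np.asarray(img.voxels).ravel()
        assert flat[out.attractors[1]] == 100

    def test_remove_by_intensity_zero_threshold_is_identity(self):
        img = make_toy_volume([1, 5, 1])
        lm = steepest_ascent_label(img)
        assert remove_by_intensity(lm, img, 0).n_objects == lm.n_objects


class TestMorphLabels:
    def test_single_voxel_erodes_away(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        lm = LabelMap(labels, attractors={1: 62}, attractor_intensity={1: 1.0})
        out = morph_labels(lm, "erode", 1)
        assert out.n_objects == 0

    def test_close_is_superset_of_convex_label(self):
        labels = np.zeros((7, 7, 7), dtype=np.int32)
        labels[2:5, 2:5, 2:5] = 1
        flat = np.flatnonzero(labels.ravel())[0]
        lm = LabelMap(labels, attractors={1: int(flat)}, attractor_intensity={1: 1.0})
        out = morph_labels(lm, "close", 1)
        assert np.all(out.labels[labels == 1] == 1)

    def test_dilation_never_steals_voxels_from_neighbor(self):
        labels = np.zeros((3, 5, 5), dtype=np.int32)
        labels[1, 1:4, 1] = 1
        labels[1, 1:4, 2] = 2  # touching columns
        lm = LabelMap(
            labels,
            attractors={1: int(np.flatnonzero((labels == 1).ravel())[0]),
                        2: int(np.flatnonzero((labels == 2).ravel())[0])},
            attractor_intensity={1: 1.0, 2: 1.0},
        )
        out = morph_labels(lm, "dilate", 1)
        assert np.all(out.labels[labels == 1] == 1)
        assert np.all(out.labels[labels == 2] == 2)


class TestRefinementInvariants:
    def test_merges_never_increase_object_count(self, rng):
        img = rng.uniform(0, 40, (5, 8, 8))
        lm = steepest_ascent_label(img)
        n0 = lm.n_objects
        assert merge_by_distance(lm, 1.5).n_objects <= n0
        assert merge_by_depth(lm, img, 5).n_objects <= n0
        assert merge_small_to_closest(lm, 3, 5).n_objects <= n0
        assert remove_by_size(lm, 2).n_objects <= n0

    def test_merge_changes_assignment_only_by_union(self, rng):
        img = rng.uniform(0, 40, (4, 7, 7))
        lm = steepest_ascent_label(img)
        merged = merge_by_distance(lm, 2.0)
        # every original object maps wholly into a single merged object
        for lab in lm.ids:
            targets = np.unique(merged.labels[lm.labels == lab])
            assert len(targets) == 1
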