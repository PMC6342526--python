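"""Ratio extraction: normalization, records, filtering, domains, projection."""

import numpy as np
import pytest

from nucratio.quantify import (
    ROI,
    ROISet,
    assign_domains,
    crop_volume,
    downproject,
    extract_nuclei,
    filter_nuclei,
    normalize_dii,
    NucleusRecord,
)
from nucratio.segmentation import LabelMap
from nucratio.stack import ImageStack


def square_roi(tag, y0, y1, x0, x1):
    return ROI(tag=tag, polygon_yx=((y0, x0), (y0, x1), (y1, x1), (y1, x0)))


def single_label(shape=(4, 4, 4), where=None, spacing=(1.0, 1.0, 1.0)):
    labels = np.zeros(shape, dtype=np.int32)
    sl = where or (slice(1, 3),) * 3
    labels[sl] = 1
    flat = int(np.flatnonzero(labels.ravel())[0])
    return LabelMap(labels, attractors={1: flat}, attractor_intensity={1: 1.0},
                    spacing=spacing)


class TestCropVolume:
    def test_full_cover_roi_is_identity(self):
        stack = ImageStack(np.full((3, 8, 8), 5.0))
        rs = ROISet(rois=[square_roi("adaxial", -1, 9, -1, 9)])
        out = crop_volume(stack, rs, "adaxial")
        assert np.array_equal(out.voxels, stack.voxels)

    def test_missing_tag_rejected(self):
        stack = ImageStack(np.ones((2, 4, 4)))
        rs = ROISet(rois=[square_roi("adaxial", 0, 4, 0, 4)])
        with pytest.raises(KeyError):
            crop_volume(stack, rs, "abaxial")

    def test_half_plane_roi_keeps_exact_pixel_count(self):
        stack = ImageStack(np.ones((2, 8, 8)))
        # pixel centers at y = 0..7; polygon covers y in [-0.5, 3.5] -> 4 rows
        rs = ROISet(rois=[square_roi("abaxial", -0.5, 3.5, -0.5, 7.5)])
        out = crop_volume(stack, rs, "abaxial")
        assert out.voxels.sum() == 2 * 4 * 8


class TestNormalizeDii:
    def test_scale_forced_by_max_matching(self):
        labels = single_label()
        dii = np.zeros((4, 4, 4))
        mdii = np.zeros((4, 4, 4))
        dii[labels.labels == 1] = 500.0
        mdii[labels.labels == 1] = 2000.0
        out, s = normalize_dii(dii, mdii, labels)
        assert s == 4.0
        fg = labels.labels > 0
        assert out[fg].max() == mdii[fg].max()

    def test_equal_maxima_is_identity(self):
        labels = single_label()
        img = np.random.default_rng(0).uniform(1, 10, (4, 4, 4))
        out, s = normalize_dii(img, img, labels)
        assert s == 1.0
        assert np.allclose(out, img)

    def test_normalized_mean_ratio_arithmetic(self):
        labels = single_label()
        dii = np.zeros((4, 4, 4))
        mdii = np.zeros((4, 4, 4))
        dii[labels.labels == 1] = 100.0
        mdii[labels.labels == 1] = 800.0
        # labeled max mDII / max DII = 8; but scale by construction: use
        # a second brighter reference voxel to pin s = 4
        dii[1, 1, 1] = 500.0
        mdii[1, 1, 1] = 2000.0
        out, s = normalize_dii(dii, mdii, labels)
        assert s == 4.0
        rec = extract_nuclei(labels, out, mdii)[0]
        # mean over 8 voxels: dii (7*100 + 500)*4 / (7*800 + 2000)
        assert rec.ratio == pytest.approx((7 * 100 + 500) * 4 / (7 * 800 + 2000))

    def test_scale_invariance_of_ratios(self, rng):
        labels = single_label()
        dii = rng.uniform(1, 100, (4, 4, 4))
        mdii = rng.uniform(1, 100, (4, 4, 4))
        r1 = extract_nuclei(labels, normalize_dii(dii, mdii, labels)[0], mdii)[0].ratio
        r2 = extract_nuclei(labels, normalize_dii(dii * 37.5, mdii, labels)[0], mdii)[0].ratio
        assert r1 == pytest.approx(r2)

    def test_background_only_labelmap_rejected(self):
        empty = LabelMap(np.zeros((2, 2, 2), dtype=np.int32))
        with pytest.raises(ValueError):
            normalize_dii(np.ones((2, 2, 2)), np.ones((2, 2, 2)), empty)

    def test_zero_dii_maximum_rejected(self):
        labels = single_label()
        with pytest.raises(ValueError):
            normalize_dii(np.zeros((4, 4, 4)), np.ones((4, 4, 4)), labels)


class TestExtractNuclei:
    def test_uniform_cube_ratio_and_centroid(self):
        labels = single_label(spacing=(2.0, 1.0, 1.0))
        dii = np.where(labels.labels == 1, 2.0, 0.0)
        mdii = np.where(labels.labels == 1, 4.0, 0.0)
        (rec,) = extract_nuclei(labels, dii, mdii)
        assert rec.ratio == 0.5
        # cube spans voxels 1..2 per axis; center 2.0 in index -> *spacing
        assert rec.centroid == pytest.approx((4.0, 2.0, 2.0))
        assert rec.volume_voxels == 8
        assert rec.volume_um3 == pytest.approx(16.0)

    def test_empty_labelmap_gives_no_records(self):
        empty = LabelMap(np.zeros((2, 2, 2), dtype=np.int32))
        assert extract_nuclei(empty, np.ones((2, 2, 2)), np.ones((2, 2, 2))) == []

    def test_two_voxel_object_means(self):
        labels = np.zeros((1, 1, 2), dtype=np.int32)
        labels[0, 0, :] = 1
        lm = LabelMap(labels, attractors={1: 0}, attractor_intensity={1: 4.0})
        (rec,) = extract_nuclei(lm, np.array([[[2.0, 4.0]]]), np.array([[[4.0, 4.0]]]))
        assert rec.mean_dii == 3.0
        assert rec.ratio == 0.75

    def test_zero_mdii_flags_low_signal(self):
        labels = single_label()
        dii = np.where(labels.labels == 1, 2.0, 0.0)
        (rec,) = extract_nuclei(labels, dii, np.zeros((4, 4, 4)))
        assert rec.low_signal
        assert np.isnan(rec.ratio)

    def test_ratio_above_one_flagged_not_clipped(self):
        labels = single_label()
        dii = np.where(labels.labels == 1, 8.0, 0.0)
        mdii = np.where(labels.labels == 1, 4.0, 0.0)
        (rec,) = extract_nuclei(labels, dii, mdii)
        assert rec.ratio == 2.0
        assert rec.ratio_gt_one


def _rec(ratio=0.5, mdii=100.0, vol=10.0):
    return NucleusRecord(
        id=1, centroid=(1, 1, 1), volume_voxels=int(vol), volume_um3=vol,
        mean_dii=ratio * mdii, mean_mdii=mdii, ratio=ratio,
    )


class TestFilterNuclei:
    def test_low_signal_dropped(self):
        recs = [_rec(mdii=5.0), _rec(mdii=100.0)]
        out = filter_nuclei(recs, min_mean_mdii=50.0)
        assert len(out) == 1 and out[0].mean_mdii == 100.0

    def test_fused_oversized_dropped(self):
        recs = [_rec(vol=1000.0), _rec(vol=10.0)]
        out = filter_nuclei(recs, min_mean_mdii=0.0, max_volume_um3=500.0)
        assert len(out) == 1 and out[0].volume_um3 == 10.0

    def test_extreme_thresholds_are_identity(self):
        recs = [_rec(), _rec(mdii=1.0, vol=1.0)]
        out = filter_nuclei(recs, min_mean_mdii=0.0, min_volume_um3=0.0,
                            max_volume_um3=np.inf)
        assert len(out) == 2

    def test_quantile_default_drops_dimmest_fraction(self, rng):
        recs = [_rec(mdii=m) for m in rng.uniform(10, 1000, size=100)]
        out = filter_nuclei(recs, mdii_quantile=0.05)
        assert 90 <= len(out) <= 96


class TestAssignDomains:
    def _roiset(self):
        return ROISet(rois=[
            square_roi("adaxial", 0.0, 4.0, 0.0, 8.0),
            square_roi("abaxial", 4.5, 8.0, 0.0, 8.0),
        ])

    def _rec_at(self, y, x):
        r = _rec()
        r.centroid = (1.0, y, x)
        return r

    def test_inside_polygon_gets_its_tag(self):
        (rec,) = assign_domains([self._rec_at(2.0, 3.0)], self._roiset())
        assert rec.domain == "adaxial"
        (rec,) = assign_domains([self._rec_at(6.0, 3.0)], self._roiset())
        assert rec.domain == "abaxial"

    def test_outside_all_polygons_discarded(self):
        (rec,) = assign_domains([self._rec_at(4.2, 3.0)], self._roiset())
        assert rec.domain == "discarded"

    def test_on_edge_belongs_to_polygon(self):
        (rec,) = assign_domains([self._rec_at(4.0, 3.0)], self._roiset())
        assert rec.domain == "adaxial"


class TestDownproject:
    def test_single_record_paints_one_pixel(self):
        r = _rec(ratio=0.7)
        r.centroid = (2.0, 3.5, 5.5)
        out = downproject([r], (8, 8))
        assert out[3, 5] == pytest.approx(0.7)
        assert np.count_nonzero(out) == 1

    def test_empty_records_all_zero(self):
        assert np.all(downproject([], (4, 4)) == 0)

    def test_collision_keeps_smaller_z(self):
        a = _rec(ratio=0.3)
        a.centroid = (3.0, 1.2, 1.2)
        b = _rec(ratio=0.9)
        b.centroid = (7.0, 1.2, 1.2)
        out = downproject([b, a], (4, 4))
        assert out[1, 1] == pytest.approx(0.3)


class TestROISetIO:
    def test_json_round_trip(self, tmp_path):
        rs = ROISet(rois=[square_roi("adaxial", 0, 4, 0, 4)], note="test")
        rs.to_json(tmp_path / "roi.json")
        back = ROISet.from_json(tmp_path / "roi.json")
        assert back.note == "test"
        assert back.rois[0].tag == "adaxial"
        assert back.rois[0].polygon_yx == rs.rois[0].polygon_yx

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            ROI(tag="adaxial", polygon_yx=((0, 0), (2, 2), (0, 2), (2, 0)))

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="tag"):
            ROI(tag="dorsal", polygon_yx=((0, 0), (0, 1), (1, 1)))
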