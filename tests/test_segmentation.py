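import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import petmtv as pm
from petmtv.segmentation import DegenerateRegionError, SeedError

from oracles import all_components, flood_fill


class TestSegmentFixed:
    def test_uniform_cube_all_voxels(self):
        img = pm.SUVImage(np.full((2, 2, 2), 3.0), spacing=(10, 10, 10))
        m = pm.segment_fixed(img, pm.SeedPoint((0, 0, 0)))
        assert m.voxel_count == 8
        assert pm.mask_volume_cm3(m, img) == pytest.approx(8.0)

    def test_two_blobs_only_seeded_one(self, two_blob_image):
        m = pm.segment_fixed(two_blob_image, pm.SeedPoint((0, 0, 0)))
        expected = flood_fill(two_blob_image.values >= 2.5, (0, 0, 0), 26)
        assert np.array_equal(m.mask, expected)
        assert not m.mask[6, 4, 4]  # blob B untouched

    def test_seed_below_threshold_raises(self, unit_image):
        with pytest.raises(SeedError):
            pm.segment_fixed(unit_image, pm.SeedPoint((0, 0, 0)))

    @given(threshold=st.floats(0.5, 6.0))
    def test_volume_monotone_in_threshold(self, threshold):
        rng = np.random.default_rng(5)
        img = pm.SUVImage(rng.uniform(0, 8, (6, 6, 6)), spacing=(4, 4, 4))
        seed = pm.SeedPoint(tuple(np.unravel_index(np.argmax(img.values), img.shape)))
        lo = pm.segment_fixed(img, seed, pm.SegmentationConfig(fixed_threshold=threshold))
        hi = pm.segment_fixed(
            img, seed, pm.SegmentationConfig(fixed_threshold=threshold + 0.5)
        )
        assert hi.voxel_count <= lo.voxel_count
        assert np.all(img.values[lo.mask] >= threshold)


class TestSegmentPctMax:
    def box_over(self, img):
        ext = (np.asarray(img.shape) - 1) * np.asarray(img.spacing)
        return pm.BoxVOI(center=tuple(ext / 2), size=tuple(ext + 1))

    def test_uniform_lesion_whole_box(self):
        img = pm.SUVImage(np.full((3, 3, 3), 10.0), spacing=(10, 10, 10))
        m = pm.segment_pct_max(img, self.box_over(img))
        assert m.voxel_count == 27  # threshold 4.1, all voxels qualify

    def test_hot_core_excludes_warm_rim(self):
        v = np.full((5, 5, 5), 3.0)
        v[2, 2, 2] = 10.0
        img = pm.SUVImage(v, spacing=(10, 10, 10))
        m = pm.segment_pct_max(img, self.box_over(img))
        assert m.voxel_count == 1  # rim 3 < 0.41*10

    def test_fixed_includes_rim_pct41_does_not(self):
        v = np.full((5, 5, 5), 3.0)
        v[2, 2, 2] = 10.0
        img = pm.SUVImage(v, spacing=(10, 10, 10))
        m_fixed = pm.segment_fixed(img, pm.SeedPoint((0, 0, 0)))
        m_pct = pm.segment_pct_max(img, self.box_over(img))
        assert m_pct.voxel_count < m_fixed.voxel_count
        assert m_fixed.voxel_count == 125

    def test_flat_zero_box_raises(self, unit_image):
        with pytest.raises(DegenerateRegionError):
            pm.segment_pct_max(unit_image, self.box_over(unit_image))

    def test_component_restricted_to_box_and_argmax(self):
        # two islands in the box; only the one holding the maximum is kept
        v = np.zeros((7, 3, 3))
        v[0:2] = 8.0
        v[5:7] = 6.0
        img = pm.SUVImage(v, spacing=(10, 10, 10))
        m = pm.segment_pct_max(img, self.box_over(img))
        assert m.mask[:2].all() and not m.mask[5:].any()


class TestHeterogeneityCheck:
    def make(self, maxima):
        v = np.zeros((len(maxima) * 3, 3, 3))
        boxes = []
        for i, m in enumerate(maxima):
            v[3 * i + 1, 1, 1] = m
            boxes.append(pm.BoxVOI(center=((3 * i + 1) * 10, 10, 10), size=(25, 25, 25)))
        return pm.SUVImage(v, spacing=(10, 10, 10)), boxes

    @pytest.mark.parametrize(
        "maxima, flag", [((10, 10), False), ((10, 8), True), ((10, 9.5), False)]
    )
    def test_relative_difference_rule(self, maxima, flag):
        img, boxes = self.make(maxima)
        assert pm.heterogeneity_check(img, boxes) == [(0, 1, flag)]

    def test_needs_two_boxes(self, unit_image):
        with pytest.raises(ValueError):
            pm.heterogeneity_check(unit_image, [pm.BoxVOI((0, 0, 0), (5, 5, 5))])


class TestPercistTumorFinder:
    def test_three_blobs(self, two_blob_image):
        labels = pm.percist_tumor_finder(two_blob_image, threshold=0.5)
        # two avid blobs + the bridge voxel at SUV 1.0
        assert labels.n_regions == 3
        comps = all_components(two_blob_image.values >= 0.5, 26)
        assert sorted(int(c.sum()) for c in comps) == sorted(
            labels.region(k).voxel_count for k in range(1, 4)
        )

    def test_labels_sorted_by_volume(self, two_blob_image):
        labels = pm.percist_tumor_finder(two_blob_image, threshold=0.5)
        counts = [labels.region(k).voxel_count for k in range(1, labels.n_regions + 1)]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_above_max_gives_empty(self, two_blob_image):
        labels = pm.percist_tumor_finder(two_blob_image, threshold=100.0)
        assert labels.n_regions == 0

    def test_brain_analogue_appears_as_label(self, core_rim_phantom):
        image, truth, ann = core_rim_phantom
        spec_img, _, _ = core_rim_phantom
        labels = pm.percist_tumor_finder(image, threshold=2.5)
        assert labels.n_regions >= 1


class TestEditLabels:
    def grid_labels(self):
        lab = np.zeros((6, 3, 3), dtype=np.int32)
        lab[0:2] = 1  # tumour, 18 voxels
        lab[4:6] = 2  # brain analogue
        return pm.LabelMap(lab)

    def test_exclude_removes_label_keeps_others(self):
        out = pm.edit_labels(self.grid_labels(), excluded={2})
        assert out.n_regions == 1
        assert out.region(1).voxel_count == 18

    def test_carve_reduces_by_exact_overlap(self):
        carve = np.zeros((6, 3, 3), bool)
        carve[0, :, :] = True  # 9 voxels of label 1
        out = pm.edit_labels(self.grid_labels(), carve_mask=pm.RegionMask(carve))
        assert out.region(1).voxel_count == 9

    def test_identity_edit(self):
        lab = self.grid_labels()
        out = pm.edit_labels(lab)
        assert np.array_equal(out.labels, lab.labels)

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            pm.edit_labels(self.grid_labels(), excluded={9})

    def test_relabelling_contiguous(self):
        out = pm.edit_labels(self.grid_labels(), excluded={1})
        assert out.n_regions == 1  # old label 2 renumbered to 1
        assert out.region(1).voxel_count == 18


class TestTotalMTV:
    def test_sum_and_tlg(self, unit_image):
        v = unit_image.values.copy()
        v[:1] = 4.0
        img = pm.SUVImage(v, spacing=(10, 10, 10))
        a = np.zeros((4, 4, 4), bool); a[:1] = True          # 16 voxels at SUV 4
        b = np.zeros((4, 4, 4), bool); b[2, :2, :2] = True   # 4 voxels at SUV 0
        rec = pm.total_mtv([pm.RegionMask(a), pm.RegionMask(b)], img, "p1")
        assert rec.total_mtv == pytest.approx(20.0)
        assert rec.lesion_volumes == (16.0, 4.0)
        assert rec.tlg == pytest.approx(16.0 * 4.0)

    def test_single_lesion_tlg_is_volume_times_mean(self):
        img = pm.SUVImage(np.full((10, 1, 1), 4.0), spacing=(10, 10, 10))
        mask = pm.RegionMask(np.ones((10, 1, 1), bool))
        rec = pm.total_mtv([mask], img)
        assert rec.total_mtv == pytest.approx(10.0)
        assert rec.tlg == pytest.approx(40.0)

    def test_empty_list(self, unit_image):
        rec = pm.total_mtv([], unit_image)
        assert rec.total_mtv == 0.0 and rec.tlg == 0.0

    def test_overlap_raises(self, unit_image):
        m = pm.RegionMask(np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError, match="disjoint"):
            pm.total_mtv([m, m], unit_image)


class TestDegenerateAgreement:
    def test_uniform_lesion_all_methods_identical(self):
        """Uniform lesion SUV u >= 2.5 on zero background: fixed, 41% and a
        sub-u PERCIST threshold all return the same mask."""
        v = np.zeros((8, 8, 8))
        v[2:6, 2:6, 2:6] = 5.0
        img = pm.SUVImage(v, spacing=(10, 10, 10))
        m_fixed = pm.segment_fixed(img, pm.SeedPoint((3, 3, 3)))
        ext = (np.asarray(img.shape) - 1) * 10.0
        m_pct = pm.segment_pct_max(img, pm.BoxVOI(tuple(ext / 2), tuple(ext + 1)))
        labels = pm.percist_tumor_finder(img, threshold=3.0)
        assert np.array_equal(m_fixed.mask, m_pct.mask)
        assert labels.n_regions == 1
        assert np.array_equal(labels.region(1).mask, m_fixed.mask)
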