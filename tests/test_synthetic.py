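"""Phantom generator: determinism, geometry encodings, cohort statistics."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.measure import regionprops

from nodugrade import patches, synthetic
from nodugrade.synthetic import (GeometryError, RangeError, SCGenParams,
                                 generate_cohort, generate_nodule_phantom)


def perimeter_sq_over_area(mask):
    props = regionprops(mask.astype(np.uint8))[0]
    return props.perimeter ** 2 / props.area


class TestPhantom:
    def test_bit_identical_under_same_seed(self):
        p = SCGenParams(spiculation_level=3, seed=11)
        a = generate_nodule_phantom(p)
        b = generate_nodule_phantom(p)
        for s in range(3):
            np.testing.assert_array_equal(a.slices[s], b.slices[s])
        np.testing.assert_array_equal(a.truth_mask, b.truth_mask)
        for r in range(len(a.reader_contours)):
            for s in range(3):
                np.testing.assert_array_equal(
                    a.reader_contours[r][s], b.reader_contours[r][s])

    def test_smooth_sphere_is_near_convex(self):
        for seed in range(5):
            p = SCGenParams(spiculation_level=1, lobulation_level=1,
                            sphericity_level=5, seed=seed)
            case = generate_nodule_phantom(p)
            props = regionprops(case.truth_mask[0].astype(np.uint8))[0]
            assert props.solidity >= 0.95

    def test_spiculation_raises_boundary_complexity(self):
        lo, hi = [], []
        for seed in range(50):
            for level, acc in ((1, lo), (5, hi)):
                p = SCGenParams(spiculation_level=level, seed=1000 + seed)
                acc.append(perimeter_sq_over_area(
                    generate_nodule_phantom(p).truth_mask[0]))
        assert np.mean(hi) > np.mean(lo)

    def test_three_slices_shrinking(self):
        case = generate_nodule_phantom(SCGenParams(seed=3))
        areas = case.truth_mask.sum(axis=(1, 2))
        assert len(case.slices) == 3
        assert areas[0] > areas[1] > areas[2]

    def test_masks_single_4connected_component(self):
        four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for seed in range(5):
            p = SCGenParams(spiculation_level=5, lobulation_level=5,
                            sphericity_level=1, seed=seed)
            case = generate_nodule_phantom(p)
            for s in range(3):
                _, n = ndimage.label(case.truth_mask[s], structure=four)
                assert n == 1

    def test_contours_inside_image(self):
        p = SCGenParams(spiculation_level=5, lobulation_level=5,
                        sphericity_level=1, margin_level=1, seed=9)
        case = generate_nodule_phantom(p)
        for reader in case.reader_contours:
            for contour in reader:
                assert contour.min() >= 0
                assert contour.max() <= p.image_size - 1

    def test_reader_intersection_in_dilated_truth(self):
        p = SCGenParams(spiculation_level=3, lobulation_level=3, seed=21)
        case = generate_nodule_phantom(p)
        for s in range(3):
            contours = [case.reader_contours[r][s] for r in range(4)]
            region = patches.intersection_region(contours, case.slices[s].shape)
            assert region.any()
            dilated = ndimage.binary_dilation(
                case.truth_mask[s], iterations=int(np.ceil(p.reader_jitter)) + 1)
            assert not (region & ~dilated).any()

    def test_ratings_echo_generating_levels(self):
        p = SCGenParams(spiculation_level=4, calcification_level=2, seed=0)
        case = generate_nodule_phantom(p)
        for rec in case.ratings:
            assert rec.ratings["spiculation"] == 4
            assert rec.ratings["calcification"] == 2

    @pytest.mark.parametrize("kwargs", [
        {"spiculation_level": 6},
        {"calcification_level": 0},
        {"internal_structure_level": 5},
        {"n_readers": 5},
    ])
    def test_level_range_errors(self, kwargs):
        with pytest.raises(RangeError):
            SCGenParams(**kwargs)

    def test_geometry_errors(self):
        with pytest.raises(GeometryError):
            SCGenParams(base_radius=3)
        with pytest.raises(GeometryError):
            SCGenParams(base_radius=20, image_size=64)


class TestMonotoneEncodings:
    """Average image properties move monotonically with the level."""

    N = 20

    def _mean_over_seeds(self, fn, **level):
        vals = []
        for seed in range(self.N):
            case = generate_nodule_phantom(SCGenParams(seed=2000 + seed, **level))
            vals.append(fn(case))
        return np.mean(vals)

    def test_spiculation_boundary_complexity(self):
        means = [self._mean_over_seeds(
            lambda c: perimeter_sq_over_area(c.truth_mask[0]),
            spiculation_level=lv) for lv in (1, 3, 5)]
        assert means[0] < means[1] < means[2]

    def test_sphericity_axis_ratio(self):
        def axis_ratio(c):
            pr = regionprops(c.truth_mask[0].astype(np.uint8))[0]
            return pr.axis_major_length / pr.axis_minor_length
        means = [self._mean_over_seeds(axis_ratio, sphericity_level=lv)
                 for lv in (1, 3, 5)]
        assert means[0] > means[1] > means[2]

    def test_subtlety_contrast(self):
        def contrast(c):
            img, mask = c.slices[0], c.truth_mask[0]
            return img[mask].mean() - img[~mask].mean()
        means = [self._mean_over_seeds(contrast, subtlety_level=lv)
                 for lv in (1, 3, 5)]
        assert means[0] < means[1] < means[2]

    def test_margin_edge_sharpness(self):
        def edge_grad(c):
            gy, gx = np.gradient(c.slices[0])
            edge = ndimage.binary_dilation(c.truth_mask[0], iterations=2) & ~c.truth_mask[0]
            return np.hypot(gy, gx)[edge].mean()
        means = [self._mean_over_seeds(edge_grad, margin_level=lv)
                 for lv in (1, 3, 5)]
        assert means[0] < means[1] < means[2]

    def test_calcification_speckle_brightness(self):
        def bright_fraction(c):
            img, mask = c.slices[0], c.truth_mask[0]
            return np.mean(img[mask] > 0.9)
        means = [self._mean_over_seeds(bright_fraction, calcification_level=lv)
                 for lv in (1, 3, 6)]
        assert means[0] > means[1] > means[2]
        assert means[2] == 0.0  # level 6 = calcification absent

    def test_lobulation_boundary_complexity(self):
        means = [self._mean_over_seeds(
            lambda c: perimeter_sq_over_area(c.truth_mask[0]),
            lobulation_level=lv) for lv in (1, 3, 5)]
        assert means[0] < means[1] < means[2]


class TestCohort:
    def test_counts(self):
        cases, table = generate_cohort(10, seed=0, render=False)
        assert len(cases) == 10
        assert len(table) == 10 * 4  # one row per reader
        assert table["case_id"].nunique() == 10

    def test_deterministic(self):
        _, t1 = generate_cohort(15, seed=4, render=False)
        _, t2 = generate_cohort(15, seed=4, render=False)
        assert t1.equals(t2)
        c1, _ = generate_cohort(12, seed=4)
        c2, _ = generate_cohort(12, seed=4)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.truth_mask, b.truth_mask)
            np.testing.assert_array_equal(a.slices[0], b.slices[0])

    def test_profile_validation(self):
        with pytest.raises(synthetic.ConfigError):
            generate_cohort(10, correlation_profile={"spiculation": 1.5}, render=False)
        with pytest.raises(synthetic.ConfigError):
            generate_cohort(10, correlation_profile={"bogus": 0.5}, render=False)
        with pytest.raises(ValueError):
            generate_cohort(5, render=False)

    def test_labels_follow_malignancy_rule(self):
        cases, _ = generate_cohort(50, seed=6, render=False)
        for case in cases:
            mal = case.ratings[0].ratings["malignancy"]
            assert case.malignancy_label == int(mal >= 3)


class TestGradingTask:
    def test_balanced_and_separated(self):
        cases, labels = synthetic.generate_grading_task(20, sc="spiculation", seed=0)
        assert labels.sum() == 10
        for case, lab in zip(cases, labels):
            lv = case.params.spiculation_level
            assert (lv >= 3) == bool(lab)

    def test_calcification_task_uses_absence(self):
        cases, labels = synthetic.generate_grading_task(20, sc="calcification", seed=0)
        for case, lab in zip(cases, labels):
            assert (case.params.calcification_level == 6) == bool(lab)

    def test_rejects_malignancy(self):
        with pytest.raises(synthetic.ConfigError):
            synthetic.generate_grading_task(10, sc="malignancy")
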