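"""Tests for SEI construction, LBP features and shape classifiers."""

import numpy as np
import pytest

from spinetrace import shape
from spinetrace.shape import (
    FEATURE_DIM,
    N_LBP_BINS,
    align_and_resize,
    align_mask,
    build_feature_vector,
    compute_sei,
    crossvalidate,
    decision_tree_baseline,
    measure_spine_profile,
    n_binary_learners,
    train_classifier,
    uniform_lbp_histogram,
)
from spinetrace.spines import SpineSegment
from oracles import brute_uniform_lbp


def segment_from_mask(mask, base_endpoints):
    r, c = np.nonzero(mask)
    return SpineSegment(
        spine_id=0,
        frame_index=0,
        mask=np.asarray(mask, bool),
        seed=(int(r[0]), int(c[0])),
        base_endpoints=base_endpoints,
        area=float(mask.sum()),
        height=5.0,
        width=5.0,
        mean_structure_intensity=0.5,
    )


class TestAlignment:
    def test_full_square_resizes_to_all_ones(self):
        mask = np.zeros((20, 20), bool)
        mask[4:16, 4:16] = True
        seg = segment_from_mask(mask, ((15.0, 4.0), (15.0, 15.0)))
        aligned = align_and_resize(seg)
        assert aligned.shape == (10, 10)
        assert aligned.all()

    def test_rotation_invariance_of_aligned_mask(self):
        # same rectangle presented axis-aligned and rotated 45 degrees
        h = 64
        mask = np.zeros((h, h), bool)
        mask[20:44, 28:36] = True  # 24 tall, 8 wide, base at bottom
        seg0 = segment_from_mask(mask, ((43.0, 28.0), (43.0, 35.0)))
        a0 = align_and_resize(seg0)
        rr, cc = np.mgrid[0:h, 0:h]
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        r0, c0 = 32.0, 32.0
        rot = np.zeros((h, h), bool)
        pts = np.column_stack(np.nonzero(mask)).astype(float) - (r0, c0)
        rot_pts = pts @ np.array([[c, -s], [s, c]]).T + (r0, c0)
        rot[np.round(rot_pts[:, 0]).astype(int), np.round(rot_pts[:, 1]).astype(int)] = True
        from scipy import ndimage as ndi

        rot = ndi.binary_closing(rot)
        be = np.array([[43.0, 28.0], [43.0, 35.0]]) - (r0, c0)
        be = be @ np.array([[c, -s], [s, c]]).T + (r0, c0)
        seg1 = segment_from_mask(rot, (tuple(be[0]), tuple(be[1])))
        a1 = align_and_resize(seg1)
        assert (a0 != a1).mean() <= 0.15  # identical up to discretization

    def test_vertical_bar_becomes_narrow_stripe(self):
        mask = np.zeros((20, 20), bool)
        mask[5:13, 10] = True
        seg = segment_from_mask(mask, ((12.0, 10.0), (12.0, 10.0)))  # degenerate base
        aligned = align_and_resize(seg)
        cols = np.nonzero(aligned.any(axis=0))[0]
        assert len(cols) <= 3

    def test_empty_mask_rejected(self):
        seg = segment_from_mask(np.ones((4, 4), bool), ((3.0, 0.0), (3.0, 3.0)))
        seg.mask = np.zeros((4, 4), bool)
        with pytest.raises(ValueError):
            align_mask(seg)


class TestSEI:
    def test_identical_masks_reproduce_the_mask(self, rng):
        m = rng.random((10, 10)) > 0.5
        sei = compute_sei(np.stack([m] * 5))
        assert np.array_equal(sei.pixels, m.astype(float))

    def test_half_occupancy_gives_half(self):
        on = np.ones((10, 10), bool)
        off = np.zeros((10, 10), bool)
        sei = compute_sei(np.stack([on, on, off, off]))
        assert np.allclose(sei.pixels, 0.5)

    def test_matches_per_pixel_mean(self, rng):
        stack = rng.random((7, 10, 10)) > 0.4
        sei = compute_sei(stack)
        expect = np.array(
            [[stack[:, r, c].mean() for c in range(10)] for r in range(10)]
        )
        assert np.allclose(sei.pixels, expect)

    def test_values_in_unit_interval_and_single_mask_identity(self, rng):
        m = rng.random((10, 10)) > 0.5
        sei = compute_sei(m[None])
        assert sei.pixels.min() >= 0 and sei.pixels.max() <= 1
        assert np.array_equal(sei.pixels, m.astype(float))


class TestLBP:
    def test_histogram_has_59_bins_summing_to_interior_count(self, rng):
        hist = uniform_lbp_histogram(rng.random((10, 10)))
        assert hist.shape == (N_LBP_BINS,)
        assert hist.sum() == 64  # 8x8 interior of a 10x10 image

    def test_constant_image_is_all_ones_pattern(self):
        hist = uniform_lbp_histogram(np.full((10, 10), 0.5))
        # neighbor >= center everywhere -> pattern 255, a uniform pattern
        assert hist.sum() == 64
        assert (hist > 0).sum() == 1
        assert hist[58] == 0  # not pooled: 255 is uniform (0 transitions)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(3):
            img = rng.random((10, 10))
            assert np.array_equal(uniform_lbp_histogram(img), brute_uniform_lbp(img))


class TestFeatures:
    def test_dimension_is_63(self, rng):
        vec = build_feature_vector(rng.random((10, 10)), (30.0, 8.0, 5.0, 0.4))
        assert vec.shape == (FEATURE_DIM,)

    def test_identical_spines_identical_vectors(self, rng):
        sei = rng.random((10, 10))
        assert np.array_equal(
            build_feature_vector(sei, (30.0, 8.0, 5.0, 0.4)),
            build_feature_vector(sei, (30.0, 8.0, 5.0, 0.4)),
        )

    def test_intensity_scaling_touches_only_last_coordinate(self, rng):
        sei = rng.random((10, 10))
        v1 = build_feature_vector(sei, (30.0, 8.0, 5.0, 0.4))
        v2 = build_feature_vector(sei, (30.0, 8.0, 5.0, 0.8))
        diff = np.nonzero(v1 != v2)[0]
        assert list(diff) == [FEATURE_DIM - 1]

    def test_missing_stats_rejected(self, rng):
        with pytest.raises(ValueError):
            build_feature_vector(rng.random((10, 10)), (1.0, 2.0))


def gaussian_clusters(rng, n=40, sep=6.0):
    X, y = [], []
    for i, cls in enumerate(("stubby", "thin", "mushroom")):
        center = np.zeros(FEATURE_DIM)
        center[i] = sep
        center[N_LBP_BINS + i % 4] = sep
        X.append(rng.normal(center, 1.0, size=(n, FEATURE_DIM)))
        y += [cls] * n
    return np.abs(np.concatenate(X)), np.array(y)


class TestClassifiers:
    def test_ecoc_builds_three_pairwise_learners(self, rng):
        X, y = gaussian_clusters(rng)
        model = train_classifier(X, y, "ECOC")
        assert n_binary_learners(model) == 3

    @pytest.mark.parametrize("kind", ["DA", "KNN", "ECOC"])
    def test_separated_clusters_classified_accurately(self, kind, rng):
        X, y = gaussian_clusters(rng)
        holdout = rng.permutation(len(y))
        train, test = holdout[:90], holdout[90:]
        model = train_classifier(X[train], y[train], kind)
        assert (model.predict(X[test]) == y[test]).mean() >= 0.95

    def test_shuffled_labels_at_chance(self, rng):
        X, y = gaussian_clusters(rng, n=30)
        y_shuffled = rng.permutation(y)
        mean, _ = crossvalidate(X, y_shuffled, "KNN", folds=5, repeats=2, seed=0)
        assert abs(mean - 1 / 3) <= 0.12

    def test_single_class_rejected(self, rng):
        X = rng.random((10, FEATURE_DIM))
        with pytest.raises(ValueError):
            train_classifier(X, ["thin"] * 10, "DA")

    def test_unknown_kind_rejected(self, rng):
        X, y = gaussian_clusters(rng, n=10)
        with pytest.raises(ValueError):
            train_classifier(X, y, "forest")


class TestCrossValidation:
    def test_perfectly_separable_data_scores_100(self, rng):
        X, y = gaussian_clusters(rng, n=20, sep=50.0)
        mean, std = crossvalidate(X, y, "KNN", folds=10, repeats=2, seed=0)
        assert mean == 1.0 and std == 0.0

    def test_fixed_seed_is_deterministic(self, rng):
        X, y = gaussian_clusters(rng, n=15, sep=2.0)
        r1 = crossvalidate(X, y, "DA", folds=5, repeats=3, seed=42)
        r2 = crossvalidate(X, y, "DA", folds=5, repeats=3, seed=42)
        assert r1 == r2

    def test_oversized_folds_reduced_with_warning(self, rng):
        X, y = gaussian_clusters(rng, n=3, sep=50.0)
        with pytest.warns(UserWarning):
            mean, _ = crossvalidate(X, y, "KNN", folds=20, repeats=1, seed=0)
        assert 0.0 <= mean <= 1.0


class TestDecisionTree:
    def test_squat_spine_is_stubby(self):
        label = decision_tree_baseline(
            dict(height=2.0, width=6.0, head_width=3.0, neck_width=3.0)
        )
        assert label == "stubby"

    def test_bulbous_head_is_mushroom(self):
        label = decision_tree_baseline(
            dict(height=10.0, width=6.0, head_width=6.0, neck_width=2.0)
        )
        assert label == "mushroom"

    def test_tall_narrow_falls_through_to_thin(self):
        label = decision_tree_baseline(
            dict(height=10.0, width=2.0, head_width=2.0, neck_width=2.0)
        )
        assert label == "thin"

    def test_missing_measurement_rejected(self):
        with pytest.raises(ValueError):
            decision_tree_baseline(dict(height=2.0))

    def test_profile_measurements_on_t_shape(self):
        mask = np.zeros((12, 12), bool)
        mask[2:5, 2:10] = True  # head: 8 wide
        mask[5:11, 5:7] = True  # neck: 2 wide, below the head
        m = measure_spine_profile(mask)
        assert m["head_width"] == 8.0
        assert m["neck_width"] == 2.0
        assert m["height"] == 9.0
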