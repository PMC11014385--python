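"""Overlap ratios, weight refinement, feature/label mixing, full pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import noisymix as nm
from noisymix.cam_localization import BinaryFoodMask, union_masks
from noisymix.cam_mixup import (RefinedWeights, afm_mix_labels,
                                build_mix_batch, mix_features, mix_labels,
                                overlap_ratio, refine_weights)


class TestOverlapRatio:
    def test_partial_cover_pixel_count(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[0, :4] = 1
        mask[1, :4] = 1  # 8 ones
        union = np.zeros((4, 4), np.uint8)
        union[0, :4] = 1
        union[1, :2] = 1  # covers 6 of them
        assert overlap_ratio(mask, union) == 0.75

    def test_background_and_full_cover_extremes(self):
        mask = np.ones((3, 3), np.uint8)
        assert overlap_ratio(mask, np.zeros((3, 3), np.uint8)) == 0.0
        assert overlap_ratio(mask, np.ones((3, 3), np.uint8)) == 1.0

    def test_empty_mask_is_conservative_one(self):
        assert overlap_ratio(np.zeros((3, 3), np.uint8),
                             np.ones((3, 3), np.uint8)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_ratio(np.zeros((2, 2)), np.zeros((3, 3)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_matches_brute_force_pixel_loop(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        u = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        got = overlap_ratio(m, u)
        inter = sum(int(m[y, x] and u[y, x]) for y in range(6) for x in range(6))
        area = int(m.sum())
        assert got == (inter / area if area else 1.0)

    def test_ground_truth_masks_match_brute_force(self, small_scenes):
        # oracle equivalence on rendered scenes' true masks
        multi = [s for s in small_scenes if len(s.masks) >= 2][:10]
        for s in multi:
            labels = list(s.masks)
            u = union_masks([BinaryFoodMask(s.masks[l].astype(np.uint8))
                             for l in labels[1:]])
            m = s.masks[labels[0]]
            got = overlap_ratio(BinaryFoodMask(m.astype(np.uint8)), u)
            expected = (m & u.mask.astype(bool)).sum() / m.sum()
            assert got == expected
            assert got == 0.0  # disjoint rendering policy


class TestRefineWeights:
    def test_hand_computed_example(self):
        w = refine_weights(0.6, np.array([0.5]), np.array([]), t2=0.8)
        assert w.a_il[0] == pytest.approx(0.76)  # 0.6 + 0.4*0.5*0.8

    def test_t2_zero_reduces_to_scalar_weights(self):
        w = refine_weights(0.37, np.array([0.1, 0.9]), np.array([0.4]), t2=0.0)
        assert np.all(w.a_il == 0.37)
        assert np.all(w.a_ir == 1.0 - 0.37)

    def test_full_background_overlap_with_t2_one_reaches_one(self):
        w = refine_weights(0.6, np.array([0.0]), np.array([0.0]), t2=1.0)
        assert w.a_il[0] == pytest.approx(1.0)
        assert w.a_ir[0] == pytest.approx(1.0)

    def test_full_food_overlap_keeps_base_weight(self):
        w = refine_weights(0.6, np.array([1.0]), np.array([1.0]), t2=1.0)
        assert w.a_il[0] == pytest.approx(0.6)
        assert w.a_ir[0] == pytest.approx(0.4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_bounds_hold_for_any_inputs(self, a, r, t2):
        w = refine_weights(a, np.array([r]), np.array([r]), t2)
        assert a - 1e-12 <= w.a_il[0] <= a + (1 - a) * t2 + 1e-12
        assert (1 - a) - 1e-12 <= w.a_ir[0] <= (1 - a) + a * t2 + 1e-12

    def test_strictly_monotone_decreasing_in_ratio(self):
        rs = np.linspace(0, 1, 11)
        w = refine_weights(0.5, rs, rs, t2=0.8)
        assert (np.diff(w.a_il) < 0).all()

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            refine_weights(1.2, np.array([0.5]), np.array([]), 0.8)
        with pytest.raises(ValueError):
            refine_weights(0.5, np.array([1.5]), np.array([]), 0.8)
        with pytest.raises(ValueError):
            refine_weights(0.5, np.array([0.5]), np.array([]), 1.8)


class TestMixing:
    def test_feature_mixing_endpoints_and_midpoint(self):
        xi = np.array([2.0, 0.0])
        xj = np.array([0.0, 2.0])
        assert np.array_equal(mix_features(xi, xj, 1.0), xi)
        assert np.array_equal(mix_features(xi, xj, 0.0), xj)
        assert np.array_equal(mix_features(xi, xj, 0.5), [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mix_features(np.zeros(3), np.zeros(4), 0.5)
        with pytest.raises(ValueError):
            mix_labels(np.zeros(3), np.zeros(4),
                       RefinedWeights(np.array([]), np.array([]), 0.5))

    def test_single_parent_class_gets_refined_weight(self):
        y_i = np.array([1, 0, 0])
        y_j = np.array([0, 1, 0])
        w = RefinedWeights(a_il=np.array([0.76]), a_ir=np.array([0.3]), t2=0.8)
        soft = mix_labels(y_i, y_j, w)
        assert soft[0] == 0.76
        assert soft[1] == 0.3
        assert soft[2] == 0.0  # absent from both parents

    def test_doubly_present_class_clamped_to_one(self):
        y = np.array([1, 0])
        w = RefinedWeights(a_il=np.array([0.9]), a_ir=np.array([0.8]), t2=0.8)
        soft = mix_labels(y, y, w)
        assert soft[0] == 1.0  # raw 1.7 clamped

    def test_soft_labels_always_valid_probabilities(self, rng):
        for _ in range(50):
            y_i = (rng.random(5) < 0.5).astype(float)
            y_j = (rng.random(5) < 0.5).astype(float)
            a = float(rng.random())
            ri = rng.random(int(y_i.sum()))
            rj = rng.random(int(y_j.sum()))
            soft = mix_labels(y_i, y_j, refine_weights(a, ri, rj, 0.8))
            assert ((soft >= 0) & (soft <= 1)).all()


class TestBuildMixBatch:
    def test_t2_zero_bit_identical_to_scalar_mixup(self, tiny_model,
                                                   small_scenes):
        imgs = np.stack([s.image for s in small_scenes[:6]])
        labels = np.stack([s.labels for s in small_scenes[:6]])
        mixed = build_mix_batch(imgs, labels, tiny_model, t2=0.0, seed=3)
        out = tiny_model.forward_backbone(
            nm.model_core.preprocess_images(imgs))
        for ms in mixed:
            a = ms.a_i
            expect_feat = mix_features(out.features[ms.index_i],
                                       out.features[ms.index_j], a)
            expect_soft = afm_mix_labels(labels[ms.index_i],
                                         labels[ms.index_j], a)
            assert np.array_equal(ms.feature, expect_feat)
            assert np.array_equal(ms.soft_labels, expect_soft)

    def test_disjoint_ground_truth_ratios_boost_to_maximum(self):
        # two half-plane scenes whose CAM-free oracle ratios are zero:
        # with ground-truth masks substituted, weights hit the Eq. 4/5 max
        from noisymix.cam_mixup import pair_soft_labels

        m_left = np.zeros((8, 8), np.uint8)
        m_left[:, :3] = 1
        m_right = np.zeros((8, 8), np.uint8)
        m_right[:, 5:] = 1
        y_i = np.array([1, 0])
        y_j = np.array([0, 1])
        a, t2 = 0.6, 0.8
        soft, weights, ratios = pair_soft_labels(
            y_i, y_j, a, {0: BinaryFoodMask(m_left)},
            {1: BinaryFoodMask(m_right)}, (8, 8), t2)
        assert ratios.r_i[0] == 0.0 and ratios.r_j[0] == 0.0
        assert weights.a_il[0] == pytest.approx(a + (1 - a) * t2)
        assert weights.a_ir[0] == pytest.approx((1 - a) + a * t2)
        assert soft[0] == pytest.approx(0.92)
        assert soft[1] == pytest.approx(0.88)

    def test_batch_of_one_rejected(self, tiny_model, small_scenes):
        with pytest.raises(ValueError):
            build_mix_batch(small_scenes[0].image[None],
                            small_scenes[0].labels[None], tiny_model)

    def test_soft_labels_zero_for_classes_absent_from_both(self, tiny_model,
                                                           small_scenes):
        imgs = np.stack([s.image for s in small_scenes[:8]])
        labels = np.stack([s.labels for s in small_scenes[:8]])
        for ms in build_mix_batch(imgs, labels, tiny_model, seed=0):
            absent = (labels[ms.index_i] == 0) & (labels[ms.index_j] == 0)
            assert np.all(ms.soft_labels[absent] == 0)
            assert ((ms.soft_labels >= 0) & (ms.soft_labels <= 1)).all()
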