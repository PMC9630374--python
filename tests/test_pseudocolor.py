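"""ROI statistics, Euclidean weights and the two pseudo-coloring renderers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polcolor as pc
from polcolor.pseudocolor import (
    SIGMA_FLOOR,
    DegenerateObservableWarning,
    apply_mask,
)


def stack_from_channel_values(values):
    """Observable stack whose IPP channels equal the given (H, W) array."""
    values = np.asarray(values, dtype=float)
    ones = np.ones_like(values)
    return pc.ObservableStack(
        m00=ones, D=values, P=values, P_S=values,
        P1=values, P2=values, P3=values, P_Delta=values,
        mask=np.ones_like(values, dtype=bool),
    )


class TestROIStatistics:
    def test_constant_roi_floors_std(self):
        stack = stack_from_channel_values(np.full((6, 6), 0.3))
        roi = pc.ROISpec("flat", [(0, 0, 4, 4)])
        model = pc.roi_statistics(stack, roi, "ipp", color=(1, 0, 0))
        assert np.allclose(model.means, 0.3)
        assert np.allclose(model.stds, SIGMA_FLOOR)

    def test_two_point_statistics(self):
        values = np.zeros((1, 2))
        values[0] = [0.2, 0.4]
        stack = stack_from_channel_values(values)
        model = pc.roi_statistics(stack, pc.ROISpec("two", [(0, 0, 2, 1)]), "ipp")
        assert np.allclose(model.means, 0.3)
        assert np.allclose(model.stds, np.std([0.2, 0.4], ddof=1))  # ~0.1414

    def test_union_of_disjoint_rectangles(self, rng):
        values = rng.uniform(0, 1, size=(10, 10))
        stack = stack_from_channel_values(values)
        roi = pc.ROISpec("union", [(0, 0, 3, 3), (6, 6, 10, 10)])
        model = pc.roi_statistics(stack, roi, "ipp")
        pooled = np.concatenate([values[0:3, 0:3].ravel(), values[6:10, 6:10].ravel()])
        assert model.means[0] == pytest.approx(pooled.mean())
        assert model.stds[0] == pytest.approx(pooled.std(ddof=1))

    def test_out_of_bounds_roi_rejected(self):
        stack = stack_from_channel_values(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="out of bounds"):
            pc.roi_statistics(stack, pc.ROISpec("bad", [(0, 0, 5, 2)]), "ipp")

    def test_all_masked_roi_rejected(self):
        stack = stack_from_channel_values(np.zeros((4, 4)))
        stack.mask[:2, :2] = False
        with pytest.raises(ValueError, match="valid pixel"):
            pc.roi_statistics(stack, pc.ROISpec("masked", [(0, 0, 2, 2)]), "ipp")


class TestEuclideanWeights:
    def setup_method(self):
        self.c1 = pc.ClassModel("a", [0.8, 0.9, 1.0], [0.1] * 3, pc.COLOR_PRESETS["yellow"])
        self.c2 = pc.ClassModel("b", [0.2, 0.3, 0.4], [0.1] * 3, pc.COLOR_PRESETS["blue"])

    def test_pixel_at_class_mean(self):
        w = pc.euclidean_weights(self.c1.means, self.c1, self.c2)
        assert np.allclose(w.weights, [1.0, 0.0], atol=1e-12)

    def test_midpoint_gets_half_each(self):
        w = pc.euclidean_weights(np.array([0.5, 0.6, 0.7]), self.c1, self.c2)
        assert np.allclose(w.d_norm, np.sqrt(3) / 2, atol=1e-12)
        assert np.allclose(w.weights, [0.5, 0.5], atol=1e-12)

    def test_weights_always_sum_to_one(self, rng):
        p = rng.uniform(-0.5, 1.5, size=(64, 64, 3))
        w = pc.euclidean_weights(p, self.c1, self.c2)
        assert np.allclose(w.weights.sum(axis=-1), 1.0, atol=1e-9)
        assert np.all((w.weights >= -1e-9) & (w.weights <= 1 + 1e-9))

    def test_degenerate_observable_dropped_with_warning(self):
        c2 = pc.ClassModel("b", [0.8, 0.3, 0.4], [0.1] * 3, (0, 0, 1))  # first equal
        with pytest.warns(DegenerateObservableWarning):
            w = pc.euclidean_weights(self.c1.means, self.c1, c2)
        assert np.allclose(w.weights, [1.0, 0.0], atol=1e-12)

    def test_fully_degenerate_classes_rejected(self):
        c2 = pc.ClassModel("b", self.c1.means, [0.1] * 3, (0, 0, 1))
        with pytest.raises(ValueError, match="identical means"):
            pc.euclidean_weights(self.c1.means, self.c1, c2)


class TestEuclideanPseudocolor:
    def make_two_class_stack(self):
        values = np.full((4, 4), 0.9)
        values[:, 2:] = 0.1
        return stack_from_channel_values(values)

    def models(self):
        c1 = pc.ClassModel("hi", [0.9] * 3, [0.05] * 3, pc.COLOR_PRESETS["yellow"])
        c2 = pc.ClassModel("lo", [0.1] * 3, [0.05] * 3, pc.COLOR_PRESETS["blue"])
        return c1, c2

    def test_class_mean_pixels_get_exact_class_color(self):
        stack = self.make_two_class_stack()
        c1, c2 = self.models()
        rgb = pc.euclidean_pseudocolor(stack, c1, c2, "ipp")
        assert np.allclose(rgb[0, 0], [1, 1, 0], atol=1e-12)
        assert np.allclose(rgb[0, 3], [0, 0, 1], atol=1e-12)

    def test_equidistant_pixel_is_mid_gray(self):
        stack = stack_from_channel_values(np.full((2, 2), 0.5))
        c1, c2 = self.models()
        rgb = pc.euclidean_pseudocolor(stack, c1, c2, "ipp")
        assert np.allclose(rgb, 0.5, atol=1e-12)  # (yellow + blue) / 2

    def test_masked_pixels_black(self):
        stack = self.make_two_class_stack()
        stack.mask[1, 1] = False
        c1, c2 = self.models()
        rgb = pc.euclidean_pseudocolor(stack, c1, c2, "ipp")
        assert np.allclose(rgb[1, 1], 0.0)

    def test_class_swap_symmetry(self, rng):
        stack = stack_from_channel_values(rng.uniform(0, 1, size=(8, 8)))
        c1, c2 = self.models()
        rgb12 = pc.euclidean_pseudocolor(stack, c1, c2, "ipp")
        rgb21 = pc.euclidean_pseudocolor(stack, c2, c1, "ipp")
        assert np.allclose(rgb12, rgb21, atol=1e-12)

    def test_output_bounded(self, rng):
        stack = stack_from_channel_values(rng.uniform(0, 1, size=(16, 16)))
        c1, c2 = self.models()
        rgb = pc.euclidean_pseudocolor(stack, c1, c2, "cp")
        assert rgb.min() >= 0.0 and rgb.max() <= 1.0


class TestNormalProbability:
    def test_unit_at_class_mean(self):
        cls = pc.ClassModel("c", [0.5, 0.5, 0.5], [0.1] * 3, (0, 1, 0.5))
        assert pc.normal_probability(cls.means, cls) == pytest.approx(1.0)

    def test_one_sigma_offset(self):
        cls = pc.ClassModel("c", [0.5, 0.5, 0.5], [0.1] * 3, (0, 1, 0.5))
        p = cls.means + cls.stds
        assert pc.normal_probability(p, cls) == pytest.approx(np.exp(-3), rel=1e-12)

    def test_far_pixel_is_effectively_black(self):
        cls = pc.ClassModel("c", [0.5] * 3, [0.05] * 3, (1, 0, 0.5))
        p = cls.means + 10 * cls.stds  # z = 10 per observable
        assert pc.normal_probability(p, cls) < 1e-100

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        z=st.floats(0.01, 5.0),
        dz=st.floats(0.01, 5.0),
        j=st.integers(0, 2),
    )
    def test_strictly_decreasing_in_each_residual(self, z, dz, j):
        cls = pc.ClassModel("c", [0.5] * 3, [0.1] * 3, (1, 1, 0))
        near, far = cls.means.copy(), cls.means.copy()
        near[j] += z * cls.stds[j]
        far[j] += (z + dz) * cls.stds[j]
        assert pc.normal_probability(far, cls) < pc.normal_probability(near, cls)

    def test_bounded_on_random_values(self, rng):
        cls = pc.ClassModel("c", [0.5] * 3, [0.1] * 3, (1, 1, 0))
        p = rng.uniform(0, 1, size=(512, 512, 3))
        probs = pc.normal_probability(p, cls)
        assert probs.min() >= 0.0 and probs.max() <= 1.0


class TestNormalPseudocolor:
    def test_single_class_at_mean(self):
        stack = stack_from_channel_values(np.full((3, 3), 0.4))
        cls = pc.ClassModel("c", [0.4] * 3, [0.1] * 3, (0, 1, 0.5))
        rgb, probs = pc.normal_pseudocolor(stack, [cls], "ipp")
        assert np.allclose(rgb, [0, 1, 0.5], atol=1e-12)
        assert np.allclose(probs, 1.0)

    def test_far_pixels_black_without_threshold(self):
        stack = stack_from_channel_values(np.full((3, 3), 0.9))
        cls = pc.ClassModel("c", [0.1] * 3, [0.01] * 3, (1, 0, 0.5))
        rgb, probs = pc.normal_pseudocolor(stack, [cls], "ipp")
        assert np.all(rgb < 1e-12)

    def test_overlapping_classes_clip_channelwise(self):
        stack = stack_from_channel_values(np.full((2, 2), 0.5))
        a = pc.ClassModel("a", [0.5] * 3, [0.1] * 3, pc.COLOR_PRESETS["pink"])
        b = pc.ClassModel("b", [0.5] * 3, [0.1] * 3, pc.COLOR_PRESETS["lime_green"])
        rgb, probs = pc.normal_pseudocolor(stack, [a, b], "ipp")
        assert np.allclose(probs, 1.0)
        assert np.allclose(rgb, [1, 1, 1], atol=1e-12)  # blue 0.5+0.5=1.0, no clip needed

    def test_empty_class_list_rejected(self, constant_stack):
        with pytest.raises(ValueError, match="at least one class"):
            pc.normal_pseudocolor(constant_stack, [], "ipp")

    def test_masked_pixels_black_and_zero_probability(self):
        stack = stack_from_channel_values(np.full((3, 3), 0.4))
        stack.mask[0, 0] = False
        cls = pc.ClassModel("c", [0.4] * 3, [0.1] * 3, (0, 1, 0.5))
        rgb, probs = pc.normal_pseudocolor(stack, [cls], "ipp")
        assert np.allclose(rgb[0, 0], 0.0) and probs[0, 0, 0] == 0.0


class TestClassify:
    def test_argmax_with_unassigned(self):
        probs = np.array([[[0.9, 0.1], [1e-5, 1e-6]]])
        labels = pc.classify(probs, threshold=1e-3)
        assert labels[0, 0] == 0 and labels[0, 1] == -1

    def test_threshold_only_affects_labels(self):
        stack = stack_from_channel_values(np.full((2, 2), 0.9))
        cls = pc.ClassModel("c", [0.1] * 3, [0.02] * 3, (1, 1, 0))
        rgb, probs = pc.normal_pseudocolor(stack, [cls], "ipp")
        assert np.all(pc.classify(probs) == -1)
        assert np.allclose(rgb, 0.0, atol=1e-12)


def test_apply_mask_preserves_valid_pixels():
    rgb = np.full((2, 2, 3), 0.7)
    mask = np.array([[True, False], [True, True]])
    out = apply_mask(rgb, mask)
    assert np.allclose(out[0, 1], 0.0) and np.allclose(out[0, 0], 0.7)
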