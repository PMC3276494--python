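"""Feature extraction: oracle equivalence, hand values, scaling contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimsseg import (FeatureConfig, MimsImage, ScalingStateError,
                     apply_scaling, build_feature_matrix, compute_ratio,
                     fit_scaling, gradient_magnitude, neighborhood_stats)
from mimsseg.features import FeatureMatrix


def brute_force_stats(plane, radius):
    """Double-loop oracle: truncated-window mean and population SD."""
    h, w = plane.shape
    mean = np.zeros((h, w))
    sd = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            window = plane[max(0, r - radius):r + radius + 1,
                           max(0, c - radius):c + radius + 1]
            mean[r, c] = window.mean()
            sd[r, c] = window.std()  # population SD
    return mean, sd


def brute_force_sobel(plane):
    """Oracle: 3x3 Sobel on a reflect-padded plane."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    padded = np.pad(plane, 1, mode="symmetric")
    h, w = plane.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            win = padded[r:r + 3, c:c + 3]
            gx[r, c] = np.sum(win * kx)
            gy[r, c] = np.sum(win * kx.T)
    return np.sqrt(gx ** 2 + gy ** 2)


class TestNeighborhoodStats:
    def test_constant_plane(self):
        mean, sd = neighborhood_stats(np.full((5, 7), 3.2), radius=2)
        np.testing.assert_allclose(mean, 3.2)
        np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_center_pixel_hand_value(self):
        plane = np.array([[0, 0, 0], [0, 9, 0], [0, 0, 0]], dtype=float)
        mean, sd = neighborhood_stats(plane, radius=1)
        assert mean[1, 1] == pytest.approx(1.0)
        assert sd[1, 1] == pytest.approx(np.sqrt(8.0))

    def test_corner_truncated_window(self):
        plane = np.array([[0, 0, 0], [0, 9, 0], [0, 0, 0]], dtype=float)
        mean, _ = neighborhood_stats(plane, radius=1)
        assert mean[0, 0] == pytest.approx(2.25)  # {0,0,0,9}

    def test_empty_plane_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_stats(np.empty((0, 0)), radius=1)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.integers(min_value=1, max_value=3))
    def test_oracle_equivalence(self, seed, radius):
        plane = np.random.default_rng(seed).uniform(0, 100, (16, 16))
        mean, sd = neighborhood_stats(plane, radius)
        bf_mean, bf_sd = brute_force_stats(plane, radius)
        np.testing.assert_allclose(mean, bf_mean, atol=1e-9)
        np.testing.assert_allclose(sd, bf_sd, atol=1e-9)


class TestGradientMagnitude:
    def test_constant_plane_zero(self):
        np.testing.assert_allclose(gradient_magnitude(np.full((6, 6), 5.0)), 0)

    def test_vertical_step_hand_value(self):
        # step 0|1 between columns 3 and 4; interior pixel next to the
        # step sees Gx = 1+2+1 = 4 from the Sobel row sums
        plane = np.zeros((7, 8))
        plane[:, 4:] = 1.0
        grad = gradient_magnitude(plane)
        assert grad[3, 3] == pytest.approx(4.0)
        assert grad[3, 4] == pytest.approx(4.0)
        assert grad[3, 1] == pytest.approx(0.0)

    def test_transpose_symmetry(self):
        plane = np.random.default_rng(0).uniform(0, 10, (9, 12))
        np.testing.assert_allclose(gradient_magnitude(plane.T),
                                   gradient_magnitude(plane).T)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            gradient_magnitude(np.ones((1, 1)))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_oracle_equivalence(self, seed):
        plane = np.random.default_rng(seed).uniform(0, 100, (16, 16))
        np.testing.assert_allclose(gradient_magnitude(plane),
                                   brute_force_sobel(plane), atol=1e-9)


def _two_channel_image(seed=0, shape=(12, 12)):
    rng = np.random.default_rng(seed)
    return MimsImage(channels={
        "m2": rng.integers(50, 200, shape),
        "m1": rng.integers(1, 50, shape),
    })


class TestBuildFeatureMatrix:
    def test_two_selectors_give_eight_columns(self):
        img = _two_channel_image()
        cfg = FeatureConfig(channels=["m2", "m1/m2"])
        fm = build_feature_matrix(img, cfg=cfg)
        assert fm.X.shape == (144, 8)
        assert fm.feature_names[:4] == ["m2:value", "m2:mean", "m2:sd",
                                        "m2:grad"]

    def test_single_ratio_selector_gives_four_columns(self):
        img = _two_channel_image()
        fm = build_feature_matrix(img, cfg=FeatureConfig(channels=["m1/m2"]))
        assert fm.X.shape == (144, 4)

    def test_constant_image_rows_identical(self):
        img = MimsImage(channels={"a": np.full((6, 6), 9)})
        fm = build_feature_matrix(img, cfg=FeatureConfig(channels=["a"]))
        np.testing.assert_allclose(fm.X - fm.X[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(fm.X[:, 2:], 0.0, atol=1e-12)  # sd, grad

    def test_missing_selector_rejected(self):
        with pytest.raises(KeyError):
            build_feature_matrix(_two_channel_image(),
                                 cfg=FeatureConfig(channels=["absent"]))

    def test_pixel_subset_matches_full_matrix(self):
        img = _two_channel_image(3)
        cfg = FeatureConfig(channels=["m2", "m1/m2"])
        full = build_feature_matrix(img, cfg=cfg)
        pixels = np.array([[0, 0], [5, 7], [11, 11], [3, 2]])
        sub = build_feature_matrix(img, cfg=cfg, pixels=pixels)
        flat = pixels[:, 0] * 12 + pixels[:, 1]
        np.testing.assert_allclose(sub.X, full.X[flat])

    def test_precomputed_ratio_used(self):
        img = _two_channel_image(4)
        ratio = compute_ratio(img, "m1", "m2")
        cfg = FeatureConfig(channels=["m1/m2"])
        via_ratio = build_feature_matrix(img, ratios=[ratio], cfg=cfg)
        derived = build_feature_matrix(img, cfg=cfg)
        np.testing.assert_allclose(via_ratio.X, derived.X)

    def test_translation_covariance(self):
        """No positional features: shifting the image shifts the features."""
        rng = np.random.default_rng(8)
        base = rng.integers(10, 200, (20, 20))
        shifted = np.roll(base, (3, 4), axis=(0, 1))
        cfg = FeatureConfig(channels=["a"])
        fm_a = build_feature_matrix(MimsImage(channels={"a": base}), cfg=cfg)
        fm_b = build_feature_matrix(MimsImage(channels={"a": shifted}), cfg=cfg)
        # compare interior pixels, away from edge effects
        interior_a, interior_b = [], []
        for r in range(5, 15):
            for c in range(5, 15):
                interior_a.append(fm_a.X[r * 20 + c])
                interior_b.append(fm_b.X[(r + 3) * 20 + (c + 4)])
        np.testing.assert_allclose(np.array(interior_b), np.array(interior_a))


class TestScaling:
    def _fm(self, cols):
        X = np.asarray(cols, dtype=float)
        return FeatureMatrix(X=X, pixel_index=np.zeros((len(X), 2), dtype=int),
                             feature_names=[f"f{i}" for i in
                                            range(X.shape[1])])

    def test_min_max_map(self):
        scaled = fit_scaling(self._fm([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(scaled.X.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        scaled = fit_scaling(self._fm([[5.0], [5.0]]))
        np.testing.assert_allclose(scaled.X.ravel(), [0.0, 0.0])

    def test_test_rows_may_extrapolate(self):
        train = fit_scaling(self._fm([[2.0], [6.0]]))
        test = apply_scaling(self._fm([[8.0]]), train.scaling)
        assert test.X[0, 0] == pytest.approx(1.5)

    def test_unfitted_scaling_rejected(self):
        with pytest.raises(ScalingStateError):
            apply_scaling(self._fm([[1.0]]), None)

    def test_training_columns_land_in_unit_interval(self):
        rng = np.random.default_rng(1)
        scaled = fit_scaling(self._fm(rng.normal(0, 50, (40, 6))))
        assert scaled.X.min() >= 0.0 and scaled.X.max() <= 1.0
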