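"""Metrics, annotation splitting, sub-sampling evaluation, comparisons."""

import numpy as np
import pytest

from mimsseg import (FeatureConfig, Roi, RoiSet, SamplingError, ShapeError,
                     compare_segmentations, recall_precision, robustness_eval,
                     split_pixels, split_rois, subsampling_eval)


class TestRecallPrecision:
    def test_hand_confusion_matrix(self):
        truth = ["C", "C", "C", "D"]
        pred = ["C", "C", "D", "D"]
        recall, precision = recall_precision(np.array(pred), np.array(truth),
                                             "C")
        assert recall == pytest.approx(2 / 3)
        assert precision == pytest.approx(1.0)

    def test_identity_prediction_perfect(self):
        y = np.array([1, 2, 2, 3, 3, 3])
        for c in (1, 2, 3):
            recall, precision = recall_precision(y, y, c)
            assert recall == 1.0 and precision == 1.0

    def test_missing_prediction_gives_nan_precision(self):
        truth = np.array([1, 1, 2])
        pred = np.array([2, 2, 2])
        recall, precision = recall_precision(pred, truth, 1)
        assert recall == 0.0
        assert np.isnan(precision)

    def test_absent_truth_gives_nan_recall(self):
        recall, _ = recall_precision(np.array([1, 1]), np.array([2, 2]), 1)
        assert np.isnan(recall)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            recall_precision(np.ones(3), np.ones(4), 1)

    def test_micro_recall_equals_accuracy(self):
        """Sum of correct per-class counts over total = overall accuracy."""
        rng = np.random.default_rng(0)
        truth = rng.integers(1, 5, 200)
        pred = rng.integers(1, 5, 200)
        num = den = 0
        for c in (1, 2, 3, 4):
            n_correct = np.sum((truth == c) & (pred == c))
            num += n_correct
            den += np.sum(truth == c)
        assert num / den == pytest.approx(np.mean(pred == truth))


def _grid_annotation(n_classes=2, rois_per_class=10, roi_size=10):
    """Disjoint 1x10 strip ROIs arranged on a grid."""
    rois = []
    rid = 1
    for c in range(1, n_classes + 1):
        for k in range(rois_per_class):
            row = (c - 1) * rois_per_class + k
            px = np.stack([np.full(roi_size, row),
                           np.arange(roi_size)], axis=1)
            rois.append(Roi(roi_id=rid, class_label=c, pixels=px))
            rid += 1
    shape = (n_classes * rois_per_class, roi_size)
    return RoiSet(rois=rois, image_shape=shape)


class TestSplits:
    def test_pixel_split_sizes(self):
        ann = _grid_annotation()  # 100 px per class
        train, test = split_pixels(ann, fraction=0.2, seed=0)
        for c in (1, 2):
            assert np.sum(train[:, 2] == c) == 20
            assert np.sum(test[:, 2] == c) == 80

    def test_pixel_split_disjoint(self):
        ann = _grid_annotation(rois_per_class=1)
        train, test = split_pixels(ann, fraction=0.5, seed=1)
        tr = {(r, c) for r, c, _ in train}
        te = {(r, c) for r, c, _ in test}
        assert not tr & te
        assert len(tr) + len(te) == 20

    def test_pixel_split_deterministic(self):
        ann = _grid_annotation()
        a = split_pixels(ann, 0.3, seed=9)
        b = split_pixels(ann, 0.3, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_tiny_class_rejected(self):
        rois = [Roi(roi_id=1, class_label=1, pixels=np.array([[0, 0]])),
                Roi(roi_id=2, class_label=2, pixels=np.array([[1, 0], [1, 1]]))]
        ann = RoiSet(rois=rois, image_shape=(2, 2))
        with pytest.raises(SamplingError):
            split_pixels(ann, 0.5, seed=0)

    def test_roi_split_counts_and_integrity(self):
        ann = _grid_annotation(rois_per_class=10)
        train, test = split_rois(ann, fraction=0.2, seed=3)
        for c in (1, 2):
            assert len(train.rois_of_class(c)) == 2
            assert len(test.rois_of_class(c)) == 8
        # every ROI lands whole on one side
        train_ids = {r.roi_id for r in train}
        test_ids = {r.roi_id for r in test}
        assert not train_ids & test_ids
        assert len(train_ids | test_ids) == 20

    def test_roi_split_deterministic(self):
        ann = _grid_annotation()
        a_train, _ = split_rois(ann, 0.2, seed=5)
        b_train, _ = split_rois(ann, 0.2, seed=5)
        assert [r.roi_id for r in a_train] == [r.roi_id for r in b_train]

    def test_single_roi_class_rejected(self):
        ann = _grid_annotation(rois_per_class=1)
        with pytest.raises(SamplingError):
            split_rois(ann, 0.5, seed=0)


class TestSubsamplingEval:
    CFG = FeatureConfig(channels=["m2", "m1/m2"])

    def test_deterministic_from_master_seed(self, small_fixture):
        _, img, ann = small_fixture
        kw = dict(fraction=0.3, n_iter=2, scheme="pixel", seed=17,
                  feature_config=self.CFG, max_evals=8)
        a = subsampling_eval(img, ann, **kw)
        b = subsampling_eval(img, ann, **kw)
        for c in a.classes:
            np.testing.assert_array_equal(a.recall[c], b.recall[c])
            np.testing.assert_array_equal(a.precision[c], b.precision[c])

    def test_separable_classes_near_perfect(self, small_fixture):
        _, img, ann = small_fixture
        res = subsampling_eval(img, ann, fraction=0.3, n_iter=3,
                               scheme="pixel", seed=2,
                               feature_config=self.CFG, max_evals=12)
        for c in res.classes:
            assert np.nanmean(res.recall[c]) >= 0.95
            assert np.nanmean(res.precision[c]) >= 0.95

    def test_indistinguishable_classes_near_chance(self):
        """Two classes with identical count distributions confuse ~50/50."""
        from mimsseg import MimsImage, SynthSpec, make_expert_annotations, \
            make_truth, simulate_counts

        spec = SynthSpec(shape=(40, 40), n_classes=2,
                         class_ratios=(0.3, 0.3),
                         class_lambdas=(200.0, 200.0),
                         geometry="bands", seed=21)
        truth = make_truth(spec)
        img = simulate_counts(truth, spec)
        ann = make_expert_annotations(truth, rois_per_class=3, roi_radius=3,
                                      margin=1, seed=4)
        res = subsampling_eval(img, ann, fraction=0.4, n_iter=4,
                               scheme="pixel", seed=5,
                               feature_config=self.CFG, max_evals=8)
        means = [np.nanmean(res.recall[c]) for c in res.classes]
        assert 0.2 <= np.mean(means) <= 0.8

    def test_roi_scheme_runs_and_respects_roi_integrity(self, small_fixture):
        _, img, ann = small_fixture
        res = subsampling_eval(img, ann, fraction=0.4, n_iter=2, scheme="roi",
                               seed=6, feature_config=self.CFG, max_evals=8)
        assert res.scheme == "roi" and res.n_iter == 2

    def test_schemes_coincide_for_single_pixel_rois(self):
        """Pixel and ROI sampling are the same split law when every ROI
        has exactly one pixel."""
        rois = [Roi(roi_id=i + 1, class_label=1 + i // 10,
                    pixels=np.array([[i // 10, i % 10]]))
                for i in range(20)]
        ann = RoiSet(rois=rois, image_shape=(2, 10))
        tr_px, te_px = split_pixels(ann, 0.3, seed=13)
        tr_roi, te_roi = split_rois(ann, 0.3, seed=13)
        roi_train_px = {tuple(p) for r in tr_roi for p in r.pixels.tolist()}
        px_train_px = {(r, c) for r, c, _ in tr_px}
        assert len(px_train_px) == len(roi_train_px)  # same split sizes
        assert all(len(r.pixels) == 1 for r in tr_roi)

    def test_frame_format(self, small_fixture):
        _, img, ann = small_fixture
        res = subsampling_eval(img, ann, fraction=0.3, n_iter=2, seed=1,
                               feature_config=self.CFG, max_evals=6)
        frame = res.to_frame()
        assert set(frame.columns) == {"iteration", "class", "metric", "value",
                                      "scheme", "fraction"}
        assert len(frame) == 2 * len(res.classes) * 2  # metrics x classes x iters


class TestRobustness:
    CFG = FeatureConfig(channels=["m2", "m1/m2"])

    def test_full_fraction_recalls_reference_exactly(self, small_fixture):
        _, img, ann = small_fixture
        res = robustness_eval(img, ann, fractions=[1.0], n_iter=2, seed=3,
                              feature_config=self.CFG, max_evals=8)
        for c in res[1.0].classes:
            np.testing.assert_array_equal(res[1.0].recall[c], 1.0)

    def test_monotone_in_training_fraction(self, small_fixture):
        _, img, ann = small_fixture
        res = robustness_eval(img, ann, fractions=[0.5, 0.05], n_iter=3,
                              seed=3, feature_config=self.CFG, max_evals=10)
        for c in res[0.5].classes:
            assert np.median(res[0.5].recall[c]) >= \
                np.median(res[0.05].recall[c]) - 0.02

    def test_deterministic(self, small_fixture):
        _, img, ann = small_fixture
        kw = dict(fractions=[0.5], n_iter=2, seed=8,
                  feature_config=self.CFG, max_evals=6)
        a = robustness_eval(img, ann, **kw)
        b = robustness_eval(img, ann, **kw)
        for c in a[0.5].classes:
            np.testing.assert_array_equal(a[0.5].recall[c], b[0.5].recall[c])


class TestCompareSegmentations:
    def test_identical_maps_perfect(self):
        lm = np.array([[1, 2], [2, 1]])
        res = compare_segmentations(lm, lm)
        assert res.per_class == {1: (1.0, 1.0), 2: (1.0, 1.0)}

    def test_half_coverage_hand_count(self):
        lm_a = np.ones((2, 4), dtype=int)
        lm_b = np.array([[1, 1, 2, 2], [1, 1, 2, 2]])
        res = compare_segmentations(lm_a, lm_b)
        recall1, precision1 = res.per_class[1]
        assert recall1 == 1.0 and precision1 == 0.5

    def test_unmapped_extra_class_reported(self):
        lm_a = np.array([[7, 1], [1, 1]])
        lm_b = np.ones((2, 2), dtype=int)
        res = compare_segmentations(lm_a, lm_b, class_map={1: 1})
        assert res.unmapped_classes == [7]
        recall1, precision1 = res.per_class[1]
        assert recall1 == pytest.approx(3 / 4)
        assert precision1 == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            compare_segmentations(np.ones((2, 2), int), np.ones((3, 3), int))
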