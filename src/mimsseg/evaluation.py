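"""Validation machinery: recall/precision, random sub-sampling, robustness.

Performance against expert annotation is measured per class by recall
(fraction of the expert's class-C pixels the model recovers,
``N*_C / T_C``) and precision (fraction of the model's class-C calls that
are correct, ``N*_C / (N*_C + N°_C)``).  Evaluating each class separately
avoids bias from the strongly unbalanced class sizes typical of expert
annotations.

Two repeated random sub-sampling schemes split annotations into train and
test sets: *pixel sampling* pools all annotated pixels of a class and
samples individuals, *ROI sampling* assigns whole expert ROIs to one side
or the other.  The *robustness* analysis instead trains on shrinking
fractions of the annotations and compares each full-image segmentation
against a reference prediction made from a model trained on all of them.

Undefined metric values (no truth pixels for recall, no predictions of a
class for precision) are recorded as NaN and excluded from summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SamplingError, ShapeError
from .features import (FeatureConfig, FeatureMatrix, apply_scaling,
                       build_feature_matrix, fit_scaling)
from .mims_io import MimsImage, RoiSet
from .segmentation import classify_image
from .svm_model import SegModel, predict, train, tune_nelder_mead


def recall_precision(pred, truth, class_label) -> tuple[float, float]:
    """Per-class recall and precision of *pred* against *truth*.

    Returns NaN for recall when the truth contains no class-C pixel, and
    NaN for precision when nothing was classified as C.
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ShapeError(f"pred length {pred.size} != truth length {truth.size}")
    truth_c = truth == class_label
    pred_c = pred == class_label
    n_correct = int(np.sum(truth_c & pred_c))
    t_c = int(np.sum(truth_c))
    n_pred = int(np.sum(pred_c))
    recall = n_correct / t_c if t_c else float("nan")
    precision = n_correct / n_pred if n_pred else float("nan")
    return recall, precision


@dataclass
class EvalResult:
    """Per-class recall/precision distributions over iterations."""

    scheme: str
    fraction: float
    n_iter: int
    classes: list[int]
    recall: dict[int, np.ndarray]
    precision: dict[int, np.ndarray] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: (iteration, class, metric, value, scheme, fraction)."""
        rows = []
        metrics = {"recall": self.recall}
        if self.precision is not None:
            metrics["precision"] = self.precision
        for metric, per_class in metrics.items():
            for c in self.classes:
                for it, v in enumerate(per_class[c]):
                    rows.append((it, c, metric, v, self.scheme, self.fraction))
        return pd.DataFrame(rows, columns=["iteration", "class", "metric",
                                           "value", "scheme", "fraction"])

    def summary(self) -> pd.DataFrame:
        """Per-class mean/median over iterations, NaNs excluded."""
        frame = self.to_frame()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = frame.groupby(["class", "metric"])["value"].agg(
                ["mean", "median", "std", "count"])
        return out.reset_index()


# ---------------------------------------------------------------------------
# Train/test splitting of expert annotations
# ---------------------------------------------------------------------------

def _annotation_pixels(ann: RoiSet) -> tuple[np.ndarray, np.ndarray]:
    """All annotated pixels and their class labels, ROI order preserved."""
    pixels, labels = [], []
    for roi in ann:
        pixels.append(roi.pixels)
        labels.append(np.full(roi.size, roi.class_label, dtype=int))
    if not pixels:
        return np.empty((0, 2), dtype=np.intp), np.empty(0, dtype=int)
    return np.concatenate(pixels), np.concatenate(labels)


def split_pixels(ann: RoiSet, fraction: float,
                 seed: int | np.random.Generator = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified random pixel split of expert annotations.

    Pools the pixels of all ROIs of each class and draws
    ``max(1, floor(fraction * n_c))`` of them for training, keeping the
    relative amounts of training data between classes constant.  Returns
    (train, test) as ``(n, 3)`` arrays of ``(row, col, class_label)``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    pixels, labels = _annotation_pixels(ann)
    train_parts, test_parts = [], []
    for c in ann.class_labels:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise SamplingError(
                f"class {c} has {len(idx)} annotated pixel(s); need >= 2")
        n_train = max(1, int(np.floor(fraction * len(idx))))
        if n_train >= len(idx):
            n_train = len(idx) - 1
        chosen = rng.permutation(len(idx))
        tr, te = idx[chosen[:n_train]], idx[chosen[n_train:]]
        train_parts.append(np.column_stack([pixels[tr], labels[tr]]))
        test_parts.append(np.column_stack([pixels[te], labels[te]]))
    return np.concatenate(train_parts), np.concatenate(test_parts)


def split_rois(ann: RoiSet, fraction: float,
               seed: int | np.random.Generator = 0) -> tuple[RoiSet, RoiSet]:
    """Whole-ROI random split: every ROI lands entirely in one side.

    Per class, ``max(1, floor(fraction * n_rois))`` ROIs train; at least
    one ROI per class remains on each side.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train_rois, test_rois = [], []
    for c in ann.class_labels:
        rois = ann.rois_of_class(c)
        if len(rois) < 2:
            raise SamplingError(
                f"class {c} has {len(rois)} ROI(s); need >= 2 to split")
        n_train = max(1, int(np.floor(fraction * len(rois))))
        if n_train >= len(rois):
            n_train = len(rois) - 1
        order = rng.permutation(len(rois))
        train_rois.extend(rois[i] for i in order[:n_train])
        test_rois.extend(rois[i] for i in order[n_train:])
    return (RoiSet(rois=train_rois, image_shape=ann.image_shape,
                   connectivity=ann.connectivity),
            RoiSet(rois=test_rois, image_shape=ann.image_shape,
                   connectivity=ann.connectivity))


# ---------------------------------------------------------------------------
# Repeated random sub-sampling evaluation
# ---------------------------------------------------------------------------

def _pixel_rows(fm: FeatureMatrix, shape: tuple[int, int]) -> dict[int, int]:
    flat = fm.pixel_index[:, 0] * shape[1] + fm.pixel_index[:, 1]
    return {int(f): i for i, f in enumerate(flat)}


def _fit_on_split(ann_fm: FeatureMatrix, row_of: dict[int, int],
                  shape: tuple[int, int], train_px: np.ndarray,
                  folds: int, tune_seed: int, max_evals: int,
                  params: tuple[float, float] | None,
                  feature_config: FeatureConfig) -> SegModel:
    """Scale on the training rows, optionally tune, and train a model."""
    rows = np.array([row_of[int(r * shape[1] + c)] for r, c, _ in train_px])
    train_fm = fit_scaling(ann_fm.rows(rows))
    y = train_px[:, 2]
    if params is None:
        tuned = tune_nelder_mead(train_fm, y, folds=folds, seed=tune_seed,
                                 max_evals=max_evals)
        C, gamma = tuned.best_C, tuned.best_gamma
    else:
        C, gamma = params
    return train(train_fm, y, C=C, gamma=gamma, feature_config=feature_config,
                 scaling=train_fm.scaling)


def subsampling_eval(img: MimsImage, ann: RoiSet, fraction: float = 0.2,
                     n_iter: int = 500, scheme: str = "pixel", folds: int = 5,
                     seed: int = 0, feature_config: FeatureConfig | None = None,
                     params: tuple[float, float] | None = None,
                     max_evals: int = 30) -> EvalResult:
    """Repeated random sub-sampling cross-validation.

    Per iteration: split the expert annotations (pixel or ROI scheme),
    fit feature scaling and tune (C, gamma) by Nelder-Mead on the
    training side (or use fixed *params*), train, predict the held-out
    pixels, and record per-class recall and precision.  Fully
    reproducible from *seed*.
    """
    if scheme not in ("pixel", "roi"):
        raise ValueError(f"scheme must be 'pixel' or 'roi', got {scheme!r}")
    if len(ann.class_labels) < 2:
        raise SamplingError("annotations must cover at least 2 classes")
    if feature_config is None:
        feature_config = FeatureConfig(channels=img.channel_names)
    master = np.random.default_rng(seed)
    pixels, _ = _annotation_pixels(ann)
    ann_fm = build_feature_matrix(img, cfg=feature_config, pixels=pixels)
    row_of = _pixel_rows(ann_fm, img.shape)
    classes = ann.class_labels
    recall = {c: np.empty(n_iter) for c in classes}
    precision = {c: np.empty(n_iter) for c in classes}
    for it in range(n_iter):
        split_seed = int(master.integers(2 ** 31))
        tune_seed = int(master.integers(2 ** 31))
        try:
            if scheme == "pixel":
                train_px, test_px = split_pixels(ann, fraction, split_seed)
            else:
                train_rs, test_rs = split_rois(ann, fraction, split_seed)
                tp, tl = _annotation_pixels(train_rs)
                ep, el = _annotation_pixels(test_rs)
                train_px = np.column_stack([tp, tl])
                test_px = np.column_stack([ep, el])
        except SamplingError as exc:
            raise SamplingError(f"iteration {it}: {exc}") from exc
        model = _fit_on_split(ann_fm, row_of, img.shape, train_px, folds,
                              tune_seed, max_evals, params, feature_config)
        test_rows = np.array([row_of[int(r * img.shape[1] + c)]
                              for r, c, _ in test_px])
        test_fm = apply_scaling(ann_fm.rows(test_rows), model.scaling)
        pred = predict(model, test_fm)
        for c in classes:
            recall[c][it], precision[c][it] = \
                recall_precision(pred, test_px[:, 2], c)
    return EvalResult(scheme=scheme, fraction=fraction, n_iter=n_iter,
                      classes=classes, recall=recall, precision=precision)


def robustness_eval(img: MimsImage, ann: RoiSet,
                    fractions: list[float] = (0.5, 0.25, 0.1, 0.05),
                    n_iter: int = 500, seed: int = 0,
                    feature_config: FeatureConfig | None = None,
                    folds: int = 5,
                    params: tuple[float, float] | None = None,
                    max_evals: int = 30) -> dict[float, EvalResult]:
    """Robustness to shrinking training data, against a reference prediction.

    A model trained on 100% of the expert pixels produces the *reference
    prediction* (a full segmentation).  For each fraction and iteration,
    a class-stratified pixel subsample trains a new model, the whole
    image is re-classified, and per-class recall is computed against the
    reference.  Returns one recall-only :class:`EvalResult` per fraction.
    """
    if feature_config is None:
        feature_config = FeatureConfig(channels=img.channel_names)
    if len(ann.class_labels) < 2:
        raise SamplingError("annotations must cover at least 2 classes")
    master = np.random.default_rng(seed)
    pixels, labels = _annotation_pixels(ann)
    ann_fm = build_feature_matrix(img, cfg=feature_config, pixels=pixels)
    row_of = _pixel_rows(ann_fm, img.shape)
    classes = ann.class_labels

    # reference model on 100% of the annotated pixels
    ref_seed = int(master.integers(2 ** 31))
    all_px = np.column_stack([pixels, labels])
    ref_model = _fit_on_split(ann_fm, row_of, img.shape, all_px, folds,
                              ref_seed, max_evals, params, feature_config)
    reference = classify_image(ref_model, img)

    full_fm = build_feature_matrix(img, cfg=feature_config)
    results: dict[float, EvalResult] = {}
    for fraction in fractions:
        recall = {c: np.empty(n_iter) for c in classes}
        for it in range(n_iter):
            split_seed = int(master.integers(2 ** 31))
            tune_seed = int(master.integers(2 ** 31))
            if fraction >= 1.0:
                # full training data: same fit as the reference model
                train_px, tune_seed = all_px, ref_seed
            else:
                try:
                    train_px, _ = split_pixels(ann, fraction, split_seed)
                except SamplingError as exc:
                    raise SamplingError(
                        f"fraction {fraction}, iteration {it}: {exc}") from exc
            # tiny subsamples cannot sustain the full fold count; shrink
            # folds to the smallest class size (2 minimum) so tuning
            # remains possible down to a few pixels per class
            _, counts = np.unique(train_px[:, 2], return_counts=True)
            it_folds = int(min(folds, counts.min()))
            if it_folds < 2:
                raise SamplingError(
                    f"fraction {fraction}: a class has {counts.min()} "
                    "training pixel(s); need >= 2")
            model = _fit_on_split(ann_fm, row_of, img.shape, train_px,
                                  it_folds, tune_seed, max_evals, params,
                                  feature_config)
            scaled = apply_scaling(full_fm, model.scaling)
            pred = predict(model, scaled)
            pred_map = np.zeros(img.shape, dtype=np.int32)
            pred_map[scaled.pixel_index[:, 0], scaled.pixel_index[:, 1]] = pred
            for c in classes:
                recall[c][it], _ = recall_precision(pred_map.ravel(),
                                                    reference.ravel(), c)
        results[float(fraction)] = EvalResult(
            scheme="pixel", fraction=float(fraction), n_iter=n_iter,
            classes=classes, recall=recall, precision=None)
    return results


# ---------------------------------------------------------------------------
# Cross-segmentation comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Pixel-wise comparison of two label maps (second one as truth)."""

    per_class: dict[int, tuple[float, float]]
    unmapped_classes: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, r, p) for c, (r, p) in sorted(self.per_class.items())]
        return pd.DataFrame(rows, columns=["class", "recall", "precision"])


def compare_segmentations(lm_a: np.ndarray, lm_b: np.ndarray,
                          class_map: dict[int, int] | None = None
                          ) -> ComparisonResult:
    """Per-class recall/precision of *lm_a* treating *lm_b* as truth.

    *class_map* translates labels of ``lm_a`` into the truth's label
    space (e.g. a cross-segmentation model trained with extra classes);
    labels of ``lm_a`` absent from the map keep hurting the precision of
    mapped classes only indirectly (they predict nothing mapped) and are
    reported in ``unmapped_classes``.
    """
    lm_a = np.asarray(lm_a)
    lm_b = np.asarray(lm_b)
    if lm_a.shape != lm_b.shape:
        raise ShapeError(f"label map shapes differ: {lm_a.shape} vs {lm_b.shape}")
    unmapped: list[int] = []
    if class_map is not None:
        mapped = np.zeros_like(lm_a)
        for src, dst in class_map.items():
            mapped[lm_a == src] = dst
        present = np.unique(lm_a)
        unmapped = sorted(int(c) for c in present
                          if c != 0 and int(c) not in class_map)
        lm_a = mapped
    classes = sorted(int(c) for c in np.unique(lm_b) if c != 0)
    per_class = {c: recall_precision(lm_a.ravel(), lm_b.ravel(), c)
                 for c in classes}
    return ComparisonResult(per_class=per_class, unmapped_classes=unmapped)


# ---------------------------------------------------------------------------
# Optional violin-plot rendering
# ---------------------------------------------------------------------------

def violin_plot(result: EvalResult, path, title: str | None = None) -> None:
    """Render per-class recall (and precision) distributions as violins."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [("recall", result.recall, "tab:blue")]
    if result.precision is not None:
        metrics.append(("precision", result.precision, "tab:red"))
    fig, ax = plt.subplots(figsize=(1.5 * len(result.classes) + 2, 4))
    width = 0.8 / len(metrics)
    for m, (name, per_class, color) in enumerate(metrics):
        positions, data = [], []
        for k, c in enumerate(result.classes):
            vals = per_class[c][~np.isnan(per_class[c])]
            if len(vals):
                positions.append(k + (m - (len(metrics) - 1) / 2) * width)
                data.append(vals)
        if data:
            parts = ax.violinplot(data, positions=positions, widths=width,
                                  showmedians=True)
            for body in parts["bodies"]:
                body.set_facecolor(color)
    ax.set_xticks(range(len(result.classes)))
    ax.set_xticklabels([f"class {c}" for c in result.classes])
    ax.set_ylabel("metric value")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
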