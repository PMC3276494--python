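"""Training, tuning, persistence and application of the multi-class SVM.

Pixel classification uses a C-support-vector machine with a radial basis
function kernel and one-vs-one multi-class decomposition (K classes ->
K(K-1)/2 pairwise machines, majority vote).  Hyperparameters (C, gamma)
are selected by maximizing stratified k-fold cross-validation accuracy,
either over an exhaustive log2 grid or — much cheaper in SVM fits — with
a Nelder-Mead simplex search over (log2 C, log2 gamma).  The simplex
search is a heuristic: it is not guaranteed to find the global optimum,
but it typically reaches the grid optimum's accuracy with an order of
magnitude fewer SVM trainings.

A trained :class:`SegModel` bundles the classifier with the feature
configuration and feature scaling it was trained under, so it can be
re-applied bit-exactly to other images (cross-segmentation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ModelFormatError, ShapeError, StratificationError
from .features import FeatureConfig, FeatureMatrix, FeatureScaling

MODEL_SCHEMA = "mimsseg-model/1"


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def _check_stratifiable(y: np.ndarray, folds: int) -> None:
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    labels, counts = np.unique(y, return_counts=True)
    small = labels[counts < folds]
    if len(small):
        raise StratificationError(
            f"classes {small.tolist()} have fewer than {folds} examples; "
            "cannot stratify")


def _cv_splits(X: np.ndarray, y: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(X, y))


def _cv_accuracy(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                 splits) -> float:
    """Overall accuracy pooled over the held-out folds."""
    correct = 0
    for train_idx, test_idx in splits:
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit(X[train_idx], y[train_idx])
        correct += int(np.sum(clf.predict(X[test_idx]) == y[test_idx]))
    return correct / len(y)


@dataclass
class TuneResult:
    """Outcome of a hyperparameter search.

    ``n_trainings`` counts individual SVM fits (folds x evaluated points);
    ``trace`` lists every distinct evaluated point as
    ``(log2 C, log2 gamma, cv_accuracy)``.
    """

    best_C: float
    best_gamma: float
    cv_accuracy: float
    n_trainings: int
    trace: list[tuple[float, float, float]]


def default_grid() -> list[tuple[float, float]]:
    """Conventional libSVM-style log2 grid: C in 2^-5..2^15, gamma in 2^-15..2^3."""
    return [(2.0 ** a, 2.0 ** b)
            for a in range(-5, 16, 2) for b in range(-15, 4, 2)]


def tune_grid(X, y, folds: int = 5,
              grid: Sequence[tuple[float, float]] | None = None,
              seed: int = 0) -> TuneResult:
    """Exhaustive cross-validated search over an explicit (C, gamma) grid.

    Ties in accuracy are broken toward smaller C, then smaller gamma.
    """
    if grid is None:
        grid = default_grid()
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = _as_array(X)
    y = np.asarray(y)
    _check_stratifiable(y, folds)
    splits = _cv_splits(X, y, folds, seed)
    trace = []
    best = None  # (acc, C, gamma)
    for C, gamma in grid:
        acc = _cv_accuracy(X, y, C, gamma, splits)
        trace.append((float(np.log2(C)), float(np.log2(gamma)), acc))
        if best is None or acc > best[0] or \
                (acc == best[0] and (C, gamma) < (best[1], best[2])):
            best = (acc, C, gamma)
    return TuneResult(best_C=float(best[1]), best_gamma=float(best[2]),
                      cv_accuracy=float(best[0]),
                      n_trainings=folds * len(trace), trace=trace)


class _BudgetExhausted(Exception):
    pass


def _nelder_mead(f, simplex: list[np.ndarray], max_iter: int = 200,
                 ftol: float = 1e-4, xtol: float = 5e-2):
    """Minimal 2-D Nelder-Mead with standard coefficients."""
    alpha, gamma_e, rho, sigma = 1.0, 2.0, 0.5, 0.5
    pts = [np.asarray(p, dtype=float) for p in simplex]
    vals = [f(p) for p in pts]
    for _ in range(max_iter):
        order = np.argsort(vals)
        pts = [pts[i] for i in order]
        vals = [vals[i] for i in order]
        if (vals[-1] - vals[0] < ftol
                and max(np.max(np.abs(p - pts[0])) for p in pts) < xtol):
            break
        centroid = np.mean(pts[:-1], axis=0)
        xr = centroid + alpha * (centroid - pts[-1])
        fr = f(xr)
        if fr < vals[0]:
            xe = centroid + gamma_e * (xr - centroid)
            fe = f(xe)
            if fe < fr:
                pts[-1], vals[-1] = xe, fe
            else:
                pts[-1], vals[-1] = xr, fr
        elif fr < vals[-2]:
            pts[-1], vals[-1] = xr, fr
        else:
            xc = centroid + rho * (pts[-1] - centroid)
            fc = f(xc)
            if fc < vals[-1]:
                pts[-1], vals[-1] = xc, fc
            else:
                pts = [pts[0]] + [pts[0] + sigma * (p - pts[0]) for p in pts[1:]]
                vals = [vals[0]] + [f(p) for p in pts[1:]]
    order = np.argsort(vals)
    return pts[order[0]], vals[order[0]]


def tune_nelder_mead(X, y, folds: int = 5, seed: int = 0,
                     max_evals: int = 60) -> TuneResult:
    """Nelder-Mead simplex search over (log2 C, log2 gamma).

    The objective is stratified k-fold CV accuracy with folds fixed by
    *seed*, so the search is fully deterministic.  Evaluated points are
    cached; ``max_evals`` bounds the number of *distinct* points (hence
    SVM fits = folds x evaluations).  The simplex starts at
    ``(log2 C, log2 gamma) = (0, -log2 d)`` (d = number of features) with
    unit edges and restarts up to twice from the best point found, with
    halved edge length, while budget remains.
    """
    X = _as_array(X)
    y = np.asarray(y)
    _check_stratifiable(y, folds)
    splits = _cv_splits(X, y, folds, seed)
    cache: dict[tuple[float, float], float] = {}
    trace: list[tuple[float, float, float]] = []

    def f(z: np.ndarray) -> float:
        key = (round(float(z[0]), 10), round(float(z[1]), 10))
        if key in cache:
            return cache[key]
        if len(trace) >= max_evals:
            raise _BudgetExhausted
        acc = _cv_accuracy(X, y, 2.0 ** z[0], 2.0 ** z[1], splits)
        cache[key] = -acc
        trace.append((key[0], key[1], acc))
        return -acc

    d = X.shape[1]
    x0 = np.array([0.0, -float(np.log2(max(d, 1)))])
    try:
        for restart in range(3):
            edge = 1.0 * (0.5 ** restart)
            simplex = [x0, x0 + np.array([edge, 0.0]), x0 + np.array([0.0, edge])]
            x0, _ = _nelder_mead(f, simplex)
    except _BudgetExhausted:
        pass
    if not trace:
        raise ValueError("max_evals must allow at least one evaluation")
    # best evaluated point; ties toward smaller C then smaller gamma
    best = min(trace, key=lambda t: (-t[2], t[0], t[1]))
    return TuneResult(best_C=2.0 ** best[0], best_gamma=2.0 ** best[1],
                      cv_accuracy=best[2], n_trainings=folds * len(trace),
                      trace=trace)


# ---------------------------------------------------------------------------
# SegModel
# ---------------------------------------------------------------------------

@dataclass
class SegModel:
    """A trained segmentation model and everything needed to re-apply it."""

    C: float
    gamma: float
    classes: list[int]
    feature_config: FeatureConfig | None = None
    scaling: FeatureScaling | None = None
    provenance: dict = field(default_factory=dict)
    kernel: str = "rbf"
    train_X: np.ndarray | None = None
    train_y: np.ndarray | None = None
    svc: SVC | None = None

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_pairwise(self) -> int:
        """Number of one-vs-one pairwise machines, K(K-1)/2."""
        k = self.n_classes
        return k * (k - 1) // 2

    @property
    def n_features(self) -> int:
        return self.train_X.shape[1]


def train(X, y, C: float, gamma: float,
          feature_config: FeatureConfig | None = None,
          scaling: FeatureScaling | None = None,
          provenance: dict | None = None) -> SegModel:
    """Fit a one-vs-one RBF SVM on (already scaled) features.

    The training matrix should come out of :func:`features.fit_scaling`
    (RBF kernels are scale-sensitive).  Raises ``ValueError`` for a
    single-class label vector.
    """
    fm = X if isinstance(X, FeatureMatrix) else None
    X = _as_array(X)
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ShapeError(f"{len(X)} feature rows vs {len(y)} labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if C <= 0 or gamma <= 0:
        raise ValueError("C and gamma must be positive")
    svc = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    svc.fit(X, y)
    if scaling is None and fm is not None:
        scaling = fm.scaling
    return SegModel(C=float(C), gamma=float(gamma), classes=classes.tolist(),
                    feature_config=feature_config, scaling=scaling,
                    provenance=provenance or {}, train_X=X.copy(),
                    train_y=y.copy(), svc=svc)


def predict(model: SegModel, X) -> np.ndarray:
    """Classify feature rows by one-vs-one majority vote.

    Each of the K(K-1)/2 pairwise machines casts one vote; overall ties
    go to the lowest class label, and a pairwise decision value of exactly
    zero also votes for the lower label of the pair.
    """
    X = _as_array(X)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ShapeError(
            f"expected {model.n_features} feature columns, got shape {X.shape}")
    if len(X) == 0:
        return np.empty(0, dtype=int)
    classes = np.asarray(model.svc.classes_)
    K = len(classes)
    dec = model.svc.decision_function(X)
    if K == 2:
        # sklearn's binary decision_function is positive for classes_[1];
        # flip to the multi-class ovo convention (positive = first class)
        dec = -dec.reshape(-1, 1)
    votes = np.zeros((len(X), K), dtype=int)
    k = 0
    for i in range(K):
        for j in range(i + 1, K):
            votes[:, i] += dec[:, k] >= 0  # libSVM: positive favors first class
            votes[:, j] += dec[:, k] < 0
            k += 1
    # argmax returns the first (lowest-label) maximum: deterministic ties
    return classes[np.argmax(votes, axis=1)]


def save_model(model: SegModel, path: str | Path) -> None:
    """Persist a model as versioned JSON.

    The file stores hyperparameters, feature configuration, scaling and
    the (scaled) training set; loading re-fits the deterministic SVM,
    which reproduces predictions exactly.
    """
    from .mims_io import atomic_write_text

    doc = {
        "schema": MODEL_SCHEMA,
        "kernel": model.kernel,
        "C": model.C,
        "gamma": model.gamma,
        "classes": model.classes,
        "feature_config": (model.feature_config.to_dict()
                           if model.feature_config else None),
        "scaling": model.scaling.to_dict() if model.scaling else None,
        "provenance": model.provenance,
        "train_X": model.train_X.tolist(),
        "train_y": model.train_y.tolist(),
    }
    atomic_write_text(path, json.dumps(doc))


def load_model(path: str | Path) -> SegModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != MODEL_SCHEMA:
        raise ModelFormatError(
            f"unknown model schema {doc.get('schema') if isinstance(doc, dict) else None!r}")
    cfg = (FeatureConfig.from_dict(doc["feature_config"])
           if doc.get("feature_config") else None)
    scaling = (FeatureScaling.from_dict(doc["scaling"])
               if doc.get("scaling") else None)
    model = train(np.asarray(doc["train_X"], dtype=float),
                  np.asarray(doc["train_y"], dtype=int),
                  C=doc["C"], gamma=doc["gamma"], feature_config=cfg,
                  scaling=scaling, provenance=doc.get("provenance", {}))
    if model.classes != list(doc["classes"]):
        raise ModelFormatError("stored class list disagrees with training data")
    return model
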