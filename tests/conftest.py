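"""Shared fixtures: small, fast synthetic images with known structure."""

import numpy as np
import pytest

from mimsseg import FeatureConfig, SynthSpec, fit_scaling, make_fixture
from mimsseg.evaluation import _annotation_pixels
from mimsseg.features import build_feature_matrix


@pytest.fixture(scope="session")
def small_fixture():
    """64x64, 3 well-separated classes in bands: (truth, image, annotations)."""
    spec = SynthSpec(shape=(64, 64), n_classes=3,
                     class_ratios=(0.01, 0.2, 0.6),
                     class_lambdas=(400.0, 300.0, 200.0),
                     geometry="bands", seed=11)
    return make_fixture(spec, rois_per_class=3, roi_radius=4, margin=2)


@pytest.fixture(scope="session")
def small_model(small_fixture):
    """A trained model on the small fixture's annotations."""
    from mimsseg import train, tune_nelder_mead

    truth, img, ann = small_fixture
    cfg = FeatureConfig(channels=["m2", "m1/m2"])
    pixels, labels = _annotation_pixels(ann)
    fm = fit_scaling(build_feature_matrix(img, cfg=cfg, pixels=pixels))
    tuned = tune_nelder_mead(fm, labels, folds=5, seed=5, max_evals=20)
    return train(fm, labels, C=tuned.best_C, gamma=tuned.best_gamma,
                 feature_config=cfg, scaling=fm.scaling)


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs in 2-D feature space (scaled)."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.2, 0.03, size=(30, 2))
    b = rng.normal(0.8, 0.03, size=(30, 2))
    X = np.vstack([a, b])
    y = np.array([1] * 30 + [2] * 30)
    return X, y
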