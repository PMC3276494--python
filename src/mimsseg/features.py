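"""Per-pixel feature space for SVM classification of MIMS images.

Each pixel is described by four features per selected image plane: the
intensity value itself, the mean and the standard deviation of the
intensities in a square neighborhood around the pixel, and the local
gradient magnitude.  Planes may be raw mass channels or ratio images;
no positional information (pixel coordinates) ever enters the feature
space, which is what makes a trained model transferable between images
(cross-segmentation).

Edge policy: neighborhood statistics use truncated windows (the window is
intersected with the image; no padding), while the gradient operator uses
reflect padding.  The standard deviation is the population SD of the
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ScalingStateError, ShapeError, ValidationError
from .mims_io import MimsImage
from .ratio_display import RatioImage

FEATURE_KINDS = ("value", "mean", "sd", "grad")


@dataclass
class FeatureConfig:
    """Which planes to use and how to summarize each pixel's neighborhood.

    Parameters
    ----------
    channels
        Ordered selectors: plain channel names (``"12C14N"``) and/or ratio
        names (``"12C15N/12C14N"``, matched against the ``name`` of the
        ratio images supplied or derived at feature-building time).
    radius
        Neighborhood half-width; the window is ``(2r+1) x (2r+1)``.
    gradient_operator
        ``"sobel"`` or ``"prewitt"``.
    radius_overrides
        Optional per-selector radius, for planes whose counting statistics
        differ by orders of magnitude from the rest.
    """

    channels: list[str]
    radius: int = 1
    gradient_operator: str = "sobel"
    radius_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = list(self.channels)
        if not self.channels:
            raise ValidationError("FeatureConfig needs at least one selector")
        if self.radius < 1:
            raise ValidationError(f"radius must be >= 1, got {self.radius}")
        if self.gradient_operator not in ("sobel", "prewitt"):
            raise ValidationError(
                f"unknown gradient operator {self.gradient_operator!r}")
        for r in self.radius_overrides.values():
            if r < 1:
                raise ValidationError("radius overrides must be >= 1")

    def radius_for(self, selector: str) -> int:
        return self.radius_overrides.get(selector, self.radius)

    @property
    def n_features(self) -> int:
        return 4 * len(self.channels)

    @property
    def feature_names(self) -> list[str]:
        return [f"{ch}:{kind}" for ch in self.channels for kind in FEATURE_KINDS]

    def ratio_selectors(self) -> list[tuple[str, str, str]]:
        """Selectors of the form num/den as (selector, num, den) triples."""
        out = []
        for sel in self.channels:
            if "/" in sel:
                num, den = sel.split("/", 1)
                out.append((sel, num, den))
        return out

    def to_dict(self) -> dict:
        return {
            "channels": self.channels,
            "radius": self.radius,
            "gradient_operator": self.gradient_operator,
            "radius_overrides": self.radius_overrides,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(channels=d["channels"], radius=d["radius"],
                   gradient_operator=d["gradient_operator"],
                   radius_overrides={k: int(v)
                                     for k, v in d.get("radius_overrides", {}).items()})


@dataclass
class FeatureScaling:
    """Per-feature affine map to [0, 1] fitted on training data.

    Columns are mapped as ``(x - min) / (max - min)``; constant columns
    map to 0.  Applying the map to unseen data may produce values outside
    [0, 1]; nothing is clipped.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != self.maxs.shape or self.mins.ndim != 1:
            raise ShapeError("scaling mins/maxs must be equal-length vectors")

    @property
    def n_features(self) -> int:
        return len(self.mins)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ShapeError(
                f"expected {self.n_features} feature columns, got {X.shape}")
        span = self.maxs - self.mins
        span = np.where(span > 0, span, 1.0)
        return (X - self.mins) / span

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaling":
        return cls(mins=np.asarray(d["mins"]), maxs=np.asarray(d["maxs"]))


@dataclass
class FeatureMatrix:
    """Per-pixel feature vectors plus bookkeeping.

    ``X`` is ``n_pixels x (4 * n_selected_planes)``; ``pixel_index`` maps
    each row to its ``(row, col)`` pixel; ``scaling`` is set once the
    matrix has been min-max scaled (training) or carries the training
    scaling it was transformed with (test).
    """

    X: np.ndarray
    pixel_index: np.ndarray
    feature_names: list[str]
    scaling: FeatureScaling | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.intp)
        if self.X.ndim != 2:
            raise ShapeError("X must be 2-D")
        if len(self.pixel_index) != len(self.X):
            raise ShapeError("pixel_index length differs from X rows")
        if len(self.feature_names) != self.X.shape[1]:
            raise ShapeError("feature_names length differs from X columns")

    @property
    def n_pixels(self) -> int:
        return len(self.X)

    def rows(self, indices: np.ndarray) -> "FeatureMatrix":
        """Sub-matrix of the given row indices (scaling carried over)."""
        return FeatureMatrix(X=self.X[indices], pixel_index=self.pixel_index[indices],
                             feature_names=list(self.feature_names),
                             scaling=self.scaling)


def neighborhood_stats(plane: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean and population SD over each pixel's square neighborhood.

    The ``(2r+1) x (2r+1)`` window is intersected with the image: edge and
    corner pixels use smaller windows (no padding).  A window of a single
    pixel has SD 0.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.size == 0:
        raise ValueError("empty plane")
    if plane.ndim != 2:
        raise ShapeError("plane must be 2-D")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")

    def window_sums(a: np.ndarray) -> np.ndarray:
        # summed-area table with zero padding; truncation = plain zeros
        pad = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=float)
        np.cumsum(a, axis=0, out=pad[1:, 1:])
        np.cumsum(pad[1:, 1:], axis=1, out=pad[1:, 1:])
        r = radius
        h, w = a.shape
        r0 = np.clip(np.arange(h) - r, 0, h)
        r1 = np.clip(np.arange(h) + r + 1, 0, h)
        c0 = np.clip(np.arange(w) - r, 0, w)
        c1 = np.clip(np.arange(w) + r + 1, 0, w)
        return (pad[np.ix_(r1, c1)] - pad[np.ix_(r0, c1)]
                - pad[np.ix_(r1, c0)] + pad[np.ix_(r0, c0)])

    counts = window_sums(np.ones_like(plane))
    # center on the global mean before forming sums of squares: the
    # E[x^2] - E[x]^2 identity loses ~sqrt(eps) digits in the SD for
    # near-constant windows otherwise
    mu0 = float(plane.mean())
    centered = plane - mu0
    s1 = window_sums(centered)
    s2 = window_sums(centered * centered)
    mean = s1 / counts
    var = np.maximum(s2 / counts - mean * mean, 0.0)
    return mean + mu0, np.sqrt(var)


def gradient_magnitude(plane: np.ndarray, operator: str = "sobel") -> np.ndarray:
    """Gradient magnitude sqrt(Gx^2 + Gy^2) with 3x3 derivative kernels.

    Image borders are handled by reflect padding.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2 or min(plane.shape) < 2:
        raise ValueError(f"plane must be at least 2x2, got shape {plane.shape}")
    op = {"sobel": ndimage.sobel, "prewitt": ndimage.prewitt}[operator]
    gx = op(plane, axis=1, mode="reflect")
    gy = op(plane, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def _resolve_planes(img: MimsImage, ratios: Sequence[RatioImage],
                    cfg: FeatureConfig) -> dict[str, np.ndarray]:
    from .ratio_display import compute_ratio

    ratio_by_name = {r.name: r for r in ratios}
    planes: dict[str, np.ndarray] = {}
    shape = img.shape
    for sel in cfg.channels:
        if sel in img:
            planes[sel] = np.asarray(img.channel(sel), dtype=float)
        elif sel in ratio_by_name:
            r = ratio_by_name[sel]
            if r.shape != shape:
                raise ShapeError(f"ratio {sel!r} shape {r.shape} != image {shape}")
            planes[sel] = r.values
        elif "/" in sel:
            num, den = sel.split("/", 1)
            planes[sel] = compute_ratio(img, num, den).values
        else:
            raise KeyError(f"selector {sel!r} matches no channel or ratio; "
                           f"channels: {img.channel_names}, "
                           f"ratios: {sorted(ratio_by_name)}")
    return planes


def build_feature_matrix(img: MimsImage, ratios: Sequence[RatioImage] = (),
                         cfg: FeatureConfig | None = None,
                         pixels: np.ndarray | None = None) -> FeatureMatrix:
    """Assemble the per-pixel feature matrix for the selected planes.

    Columns are grouped plane-major as ``[value, mean, sd, grad]`` per
    selector, in selector order.  If *pixels* (an ``(n, 2)`` coordinate
    array) is given, only those rows are returned, in the given order;
    otherwise all pixels in row-major order.
    """
    if cfg is None:
        cfg = FeatureConfig(channels=img.channel_names)
    planes = _resolve_planes(img, ratios, cfg)
    h, w = img.shape
    if pixels is None:
        pixel_index = np.stack(np.unravel_index(np.arange(h * w), (h, w)), axis=1)
    else:
        pixel_index = np.asarray(pixels, dtype=np.intp)
        if pixel_index.ndim != 2 or pixel_index.shape[1] != 2:
            raise ShapeError("pixels must be an (n, 2) coordinate array")
    rr, cc = pixel_index[:, 0], pixel_index[:, 1]
    cols = []
    for sel in cfg.channels:
        plane = planes[sel]
        mean, sd = neighborhood_stats(plane, cfg.radius_for(sel))
        grad = gradient_magnitude(plane, cfg.gradient_operator)
        for feat in (plane, mean, sd, grad):
            cols.append(feat[rr, cc])
    X = np.stack(cols, axis=1) if cols else np.empty((len(pixel_index), 0))
    return FeatureMatrix(X=X, pixel_index=pixel_index,
                         feature_names=cfg.feature_names)


def fit_scaling(fm: FeatureMatrix) -> FeatureMatrix:
    """Fit per-column min-max scaling on *fm* and return the scaled matrix.

    Call on the training rows only; scale test rows with
    :func:`apply_scaling` and the returned matrix's ``scaling``.
    """
    if fm.n_pixels == 0:
        raise ValidationError("cannot fit scaling on an empty matrix")
    scaling = FeatureScaling(mins=fm.X.min(axis=0), maxs=fm.X.max(axis=0))
    return FeatureMatrix(X=scaling.transform(fm.X), pixel_index=fm.pixel_index,
                         feature_names=list(fm.feature_names), scaling=scaling)


def apply_scaling(fm: FeatureMatrix, scaling: FeatureScaling | None) -> FeatureMatrix:
    """Transform *fm* with a previously fitted scaling (no clipping)."""
    if scaling is None:
        raise ScalingStateError("scaling has not been fitted")
    return FeatureMatrix(X=scaling.transform(fm.X), pixel_index=fm.pixel_index,
                         feature_names=list(fm.feature_names), scaling=scaling)
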