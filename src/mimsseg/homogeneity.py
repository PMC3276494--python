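"""Homogeneity statistic h_C and its random-translation permutation test.

A well-defined class should collect pixels whose isotope ratios come from
a single population.  The statistic compares two estimates of the class
ratio over a pixel set: the unweighted mean of per-pixel ratios,
``Mean = (1/N) sum(m1_i / m2_i)``, and the ratio of summed counts,
``Sum = sum(m1_i) / sum(m2_i)`` (the set "collapsed" into one
measurement).  ``h = |Mean - Sum|`` is zero for a perfectly homogeneous
ratio population; a gross discrepancy indicates at least two underlying
populations.  Algebraically ``Sum`` is the m2-count-weighted mean of the
pixel ratios, so ``h`` measures how much the ratio co-varies with the
denominator counts across the set.

Significance comes from a translation null: every ROI of the class is
independently translated to a uniformly random position (fully inside
the image, outside an optional exclusion mask), preserving ROI number,
shape and size, and ``h`` is recomputed over the union of the translated
pixels.  The p-value is the left-tail fraction of null statistics at or
below the observed one; *low* p means the class is *more* homogeneous
than randomly placed regions.  A nominal p of 0 occurs when no random
placement achieved a statistic as small as the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import PlacementError, ShapeError, ValidationError
from .mims_io import Roi, RoiSet


def h_statistic(m1, m2) -> float:
    """``|Mean - Sum|`` over a pixel set of numerator/denominator counts.

    Both arguments are 1-D count arrays over the same pixels; every
    denominator count must be positive (exclude zero-count pixels
    upstream).  Ratios are unscaled (no x10000 display factor).
    """
    m1 = np.asarray(m1, dtype=float).ravel()
    m2 = np.asarray(m2, dtype=float).ravel()
    if m1.shape != m2.shape:
        raise ShapeError(f"m1 and m2 differ in length: {m1.size} vs {m2.size}")
    if m1.size == 0:
        raise ValueError("empty pixel set")
    if np.any(m2 <= 0):
        raise ValueError("all denominator counts must be positive")
    mean = float(np.mean(m1 / m2))
    total = float(np.sum(m1) / np.sum(m2))
    return abs(mean - total)


def translate_roi(roi: Roi, image_shape: tuple[int, int],
                  exclusion_mask: np.ndarray | None = None,
                  rng: np.random.Generator | int | None = None) -> Roi:
    """Translate an ROI to a uniformly random feasible position.

    The integer offset is drawn uniformly over all positions that keep
    the ROI fully inside the image; draws landing on the exclusion mask
    are rejected and redrawn (up to ``10 x`` the number of candidate
    offsets) so the result is uniform over the feasible placements.
    Shape and pixel count are always preserved.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h, w = image_shape
    px = roi.pixels
    r0, c0 = px.min(axis=0)
    r1, c1 = px.max(axis=0)
    if r0 < 0 or c0 < 0 or r1 >= h or c1 >= w:
        raise ValueError(f"ROI {roi.roi_id} does not fit inside {image_shape}")
    dr_lo, dr_hi = -int(r0), h - 1 - int(r1)   # inclusive offset bounds
    dc_lo, dc_hi = -int(c0), w - 1 - int(c1)
    n_candidates = (dr_hi - dr_lo + 1) * (dc_hi - dc_lo + 1)
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != (h, w):
            raise ShapeError("exclusion mask shape differs from image")
    max_tries = max(10 * n_candidates, 10)
    for _ in range(max_tries):
        dr = int(rng.integers(dr_lo, dr_hi + 1))
        dc = int(rng.integers(dc_lo, dc_hi + 1))
        moved = px + np.array([dr, dc])
        if exclusion_mask is not None and \
                np.any(exclusion_mask[moved[:, 0], moved[:, 1]]):
            continue
        return Roi(roi_id=roi.roi_id, class_label=roi.class_label, pixels=moved)
    raise PlacementError(
        f"no feasible placement for ROI {roi.roi_id} after {max_tries} tries")


@dataclass
class HomogeneityResult:
    """Observed statistic, permutation null and left-tail p-value."""

    class_label: int
    h_obs: float
    null_h: np.ndarray
    p_value: float
    n_perm: int
    n_pixels: int
    n_excluded_pixels: int = 0

    def to_dict(self) -> dict:
        return {
            "class_label": self.class_label,
            "h_obs": self.h_obs,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "n_pixels": self.n_pixels,
            "n_excluded_pixels": self.n_excluded_pixels,
            "null_h": self.null_h.tolist(),
        }


def _h_over_flat(flat_idx: np.ndarray, m1_flat: np.ndarray,
                 m2_flat: np.ndarray) -> float | None:
    """h over a flat-index pixel union, skipping zero-denominator pixels."""
    idx = np.unique(flat_idx)
    m2 = m2_flat[idx]
    keep = m2 > 0
    if not np.any(keep):
        return None
    m1 = m1_flat[idx][keep]
    m2 = m2[keep]
    return abs(float(np.mean(m1 / m2)) - float(np.sum(m1) / np.sum(m2)))


def homogeneity_test(class_rois: RoiSet | list[Roi], m1_plane: np.ndarray,
                     m2_plane: np.ndarray, n_perm: int = 10000,
                     seed: int | np.random.Generator = 0,
                     exclusion_mask: np.ndarray | None = None,
                     class_label: int | None = None,
                     plus_one: bool = False) -> HomogeneityResult:
    """Permutation test of class homogeneity under random ROI translation.

    Parameters
    ----------
    class_rois
        The ROIs of one class (a RoiSet restricted to the class, or a
        plain list of :class:`Roi`).
    m1_plane, m2_plane
        Numerator and denominator mass-count planes.
    n_perm
        Number of random translations of the full ROI set.
    exclusion_mask
        Optional boolean plane of pixels excluded from the analysis
        (e.g. a low-count instrument shadow); observed pixels falling on
        it are dropped with a warning and random placements never
        overlap it.
    plus_one
        If True, report the bias-corrected ``(1 + #{null <= obs}) /
        (n_perm + 1)`` instead of the nominal left-tail fraction (which
        can be exactly 0).

    Overlapping translated ROIs contribute each pixel once (union).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rois = list(class_rois.rois if isinstance(class_rois, RoiSet) else class_rois)
    if not rois:
        raise ValueError("class has no ROIs")
    if class_label is None:
        class_label = rois[0].class_label
    m1_plane = np.asarray(m1_plane, dtype=float)
    m2_plane = np.asarray(m2_plane, dtype=float)
    if m1_plane.shape != m2_plane.shape:
        raise ShapeError("mass planes differ in shape")
    shape = m1_plane.shape
    m1_flat, m2_flat = m1_plane.ravel(), m2_plane.ravel()

    obs_idx = np.unique(np.concatenate([r.flat_indices(shape) for r in rois]))
    n_total = len(obs_idx)
    usable = m2_flat[obs_idx] > 0
    if exclusion_mask is not None:
        excl_flat = np.asarray(exclusion_mask, dtype=bool).ravel()
        usable &= ~excl_flat[obs_idx]
    n_dropped = int(n_total - usable.sum())
    if n_dropped:
        warnings.warn(f"class {class_label}: {n_dropped} observed pixel(s) "
                      "excluded (zero denominator count or exclusion mask)")
    obs_idx = obs_idx[usable]
    if len(obs_idx) == 0:
        raise ValueError(f"class {class_label}: no usable observed pixels")
    h_obs = _h_over_flat(obs_idx, m1_flat, m2_flat)

    null_h = np.empty(n_perm)
    for p in range(n_perm):
        try:
            moved = [translate_roi(r, shape, exclusion_mask, rng) for r in rois]
        except PlacementError as exc:
            raise PlacementError(f"permutation {p}: {exc}") from exc
        flat = np.concatenate([m.flat_indices(shape) for m in moved])
        h = _h_over_flat(flat, m1_flat, m2_flat)
        while h is None:  # every translated pixel had zero denominator
            moved = [translate_roi(r, shape, exclusion_mask, rng) for r in rois]
            flat = np.concatenate([m.flat_indices(shape) for m in moved])
            h = _h_over_flat(flat, m1_flat, m2_flat)
        null_h[p] = h

    n_le = int(np.sum(null_h <= h_obs))
    p_value = (n_le + 1) / (n_perm + 1) if plus_one else n_le / n_perm
    return HomogeneityResult(class_label=int(class_label), h_obs=float(h_obs),
                             null_h=null_h, p_value=float(p_value),
                             n_perm=n_perm, n_pixels=len(obs_idx),
                             n_excluded_pixels=n_dropped)


def null_histogram(result: HomogeneityResult, path, bins: int = 60) -> None:
    """Plot the null distribution (KDE-smoothed) with the observed value."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.null_h, bins=bins, density=True, alpha=0.4,
            color="tab:gray", label="null")
    if np.ptp(result.null_h) > 0:
        kde = stats.gaussian_kde(result.null_h)
        xs = np.linspace(result.null_h.min(), result.null_h.max(), 400)
        ax.plot(xs, kde(xs), color="tab:blue")
    ax.axvline(result.h_obs, color="tab:red",
               label=f"observed (p={result.p_value:.4g})")
    ax.set_xlabel("h")
    ax.set_ylabel("density")
    ax.set_title(f"class {result.class_label}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
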