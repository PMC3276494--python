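"""Full-image classification and derivation of ROIs from label maps.

Classifying every pixel of a MIMS image with a trained model yields a
full segmentation (a label map).  A *segment* is a maximal set of
connected pixels sharing a class; segments become ROIs after two
clean-up steps: segments smaller than a user-chosen pixel threshold are
absorbed into the neighboring segment they share the longest boundary
with (iterated smallest-first until none remain), and a segment fully
enclosed by another simply keeps its pixels — the surrounding ROI
excludes the hole, so no pixel ever belongs to more than one ROI.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ShapeError
from .features import apply_scaling, build_feature_matrix
from .mims_io import MimsImage, Roi, RoiSet, validate_labelmap
from .svm_model import SegModel, predict

DEFAULT_MIN_SIZE = 20
DEFAULT_CONNECTIVITY = 8


def _structure(connectivity: int):
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def classify_image(model: SegModel, img: MimsImage,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Assign every (unmasked) pixel of *img* a class from the model.

    Features are built with the model's embedded feature configuration
    (ratio selectors are recomputed from the image's mass channels) and
    scaled with the model's training scaling, so the same model applies
    unchanged to other images of the same channel set
    (cross-segmentation).  Masked-out pixels get label 0.
    """
    if model.feature_config is None:
        raise ValueError("model carries no feature configuration")
    h, w = img.shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (h, w):
            raise ShapeError(f"mask shape {mask.shape} != image shape {(h, w)}")
        pixels = np.argwhere(mask)
    else:
        pixels = None
    fm = build_feature_matrix(img, cfg=model.feature_config, pixels=pixels)
    fm = apply_scaling(fm, model.scaling)
    labels = predict(model, fm)
    out = np.zeros((h, w), dtype=np.int32)
    out[fm.pixel_index[:, 0], fm.pixel_index[:, 1]] = labels
    return out


def segment_volume(model: SegModel, slices: Sequence[MimsImage],
                   mask: np.ndarray | None = None) -> list[np.ndarray]:
    """Classify a stack of slices independently (features stay 2-D)."""
    slices = list(slices)
    if not slices:
        return []
    channel_set = set(slices[0].channel_names)
    for i, s in enumerate(slices[1:], start=1):
        if set(s.channel_names) != channel_set:
            raise KeyError(
                f"slice {i} channels {sorted(s.channel_names)} differ from "
                f"slice 0 {sorted(channel_set)}")
    return [classify_image(model, s, mask=mask) for s in slices]


def _segments(labels: np.ndarray, connectivity: int):
    """Connected components per class.

    Returns (seg_map, seg_class, seg_size): seg_map assigns each labeled
    pixel a 1-based segment id (0 where labels == 0); seg_class[i] and
    seg_size[i] describe segment id i+1.
    """
    struct = _structure(connectivity)
    seg_map = np.zeros(labels.shape, dtype=np.int32)
    seg_class: list[int] = []
    next_id = 1
    for c in np.unique(labels):
        if c == 0:
            continue
        comp, n = ndimage.label(labels == c, structure=struct)
        seg_map[comp > 0] = comp[comp > 0] + (next_id - 1)
        seg_class.extend([int(c)] * n)
        next_id += n
    seg_size = np.bincount(seg_map.ravel(), minlength=next_id)[1:]
    return seg_map, np.asarray(seg_class), seg_size


def _boundary_lengths(seg_map: np.ndarray, seg_id: int,
                      diagonal: bool) -> dict[int, int]:
    """Shared boundary length (adjacent pixel pairs) with each neighbor."""
    mask = seg_map == seg_id
    lengths: dict[int, int] = {}
    shifts = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    if diagonal:
        shifts += [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    for dr, dc in shifts:
        shifted = np.roll(mask, (dr, dc), axis=(0, 1))
        # roll wraps around; cut the wrapped border
        if dr == 1:
            shifted[0, :] = False
        elif dr == -1:
            shifted[-1, :] = False
        if dc == 1:
            shifted[:, 0] = False
        elif dc == -1:
            shifted[:, -1] = False
        neighbors = seg_map[shifted & ~mask]
        for nid in np.unique(neighbors):
            if nid != 0 and nid != seg_id:
                lengths[int(nid)] = lengths.get(int(nid), 0) + \
                    int(np.sum(neighbors == nid))
    return lengths


def merge_small_segments(labels: np.ndarray, min_size: int,
                         connectivity: int = DEFAULT_CONNECTIVITY) -> np.ndarray:
    """Absorb every segment smaller than *min_size* into a neighbor.

    Segments are processed smallest-first; each is relabeled to the
    neighboring segment it shares the longest boundary with (boundary
    length counted as 4-adjacent pixel pairs, falling back to diagonal
    adjacency for segments touching only diagonally; ties go to the lower
    class label).  Components are recomputed after each merge, so the
    procedure reaches a fixed point regardless of processing order.
    Pixels labeled 0 never absorb or get absorbed.
    """
    labels = validate_labelmap(labels).copy()
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    while True:
        seg_map, seg_class, seg_size = _segments(labels, connectivity)
        if len(seg_size) <= 1:
            break
        # smallest first; deterministic tie-break by class then id
        small = sorted(np.flatnonzero(seg_size < min_size),
                       key=lambda i: (seg_size[i], seg_class[i], i))
        merged = False
        for i in small:
            sid = int(i) + 1
            lengths = _boundary_lengths(seg_map, sid, diagonal=False)
            if not lengths:
                lengths = _boundary_lengths(seg_map, sid, diagonal=True)
            if not lengths:
                continue  # surrounded by label 0 only; nothing to absorb into
            # longest boundary wins; ties -> lower class label, then lower id
            target = min(lengths.items(),
                         key=lambda kv: (-kv[1], seg_class[kv[0] - 1], kv[0]))[0]
            labels[seg_map == sid] = seg_class[target - 1]
            merged = True
            break
        if not merged:
            break
    return labels


def derive_rois(labels: np.ndarray, min_size: int = DEFAULT_MIN_SIZE,
                connectivity: int = DEFAULT_CONNECTIVITY) -> RoiSet:
    """Turn a label map into a set of disjoint, connected ROIs.

    Components below *min_size* pixels are first absorbed into their
    surrounding segment (see :func:`merge_small_segments`); each
    surviving component becomes one ROI.  A component enclosed by another
    keeps its own pixels, so the surrounding ROI's pixel set excludes the
    hole — the output ROIs partition exactly the labeled pixels.
    """
    labels = validate_labelmap(labels)
    merged = merge_small_segments(labels, min_size, connectivity)
    seg_map, seg_class, seg_size = _segments(merged, connectivity)
    rois = []
    for sid in range(1, len(seg_class) + 1):
        pixels = np.argwhere(seg_map == sid)
        rois.append(Roi(roi_id=sid, class_label=int(seg_class[sid - 1]),
                        pixels=pixels))
    return RoiSet(rois=rois, image_shape=merged.shape, connectivity=connectivity)
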