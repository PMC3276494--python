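"""Domain containers and file I/O for MIMS image stacks, label maps and ROIs.

A MIMS acquisition produces one 2-D image of ion counts per measured
atomic mass.  :class:`MimsImage` holds that stack as an ordered mapping
channel-name -> count plane.  Segmentations are integer label maps
(0 = unclassified, 1..K = classes) stored as plain ``numpy`` arrays, and
regions of interest are connected, mutually disjoint pixel sets held in a
:class:`RoiSet`.

On-disk formats are deliberately plain: multi-page grayscale TIFF plus a
JSON channel manifest for stacks, single-page integer TIFF for label maps,
and a versioned JSON schema (``mims-rois/1``) with row-major run-length
encoded pixel sets for ROIs.

Coordinate convention throughout the package: row-major, 0-based, origin
at the top-left, pixels addressed as ``(row, col)``.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .errors import OverlapError, ShapeError, ValidationError

ROI_SCHEMA = "mims-rois/1"


def _atomic_write_bytes(path: str | Path, data: bytes) -> None:
    """Write *data* to *path* atomically (temp file + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: str | Path, text: str) -> None:
    _atomic_write_bytes(path, text.encode())


# ---------------------------------------------------------------------------
# MimsImage
# ---------------------------------------------------------------------------

@dataclass
class MimsImage:
    """An ordered stack of same-shape, non-negative ion-count planes.

    Parameters
    ----------
    channels
        Ordered mapping channel-name -> 2-D array of ion counts.  Channel
        names are the measured masses (e.g. ``"12C14N"``); counts must be
        finite and non-negative.
    pixel_size_um
        Optional physical pixel size in micrometres.
    meta
        Free-form acquisition metadata.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("MimsImage needs at least one channel")
        clean: dict[str, np.ndarray] = {}
        shape = None
        for name, plane in self.channels.items():
            if not isinstance(name, str) or not name:
                raise ValidationError("channel names must be non-empty strings")
            arr = np.asarray(plane)
            if arr.ndim != 2:
                raise ShapeError(f"channel {name!r} is not 2-D (ndim={arr.ndim})")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ShapeError(
                    f"channel {name!r} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"channel {name!r} contains non-finite counts")
            if np.any(arr < 0):
                raise ValidationError(f"channel {name!r} contains negative counts")
            clean[name] = arr
        self.channels = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels


def load_stack(path: str | Path, manifest: str | Path | None = None) -> MimsImage:
    """Read a multi-page TIFF stack into a :class:`MimsImage`.

    The optional JSON *manifest* maps page index (as a string or int key)
    to channel name; without one, pages are named ``ch0 .. chN`` in page
    order.  Page order is preserved.
    """
    with tifffile.TiffFile(str(path)) as tf:
        planes = [page.asarray() for page in tf.pages]
    if not planes:
        raise ValidationError(f"{path}: TIFF contains no pages")
    shape = planes[0].shape
    for i, plane in enumerate(planes):
        if plane.ndim != 2:
            raise ShapeError(f"page {i} is not 2-D (ndim={plane.ndim})")
        if plane.shape != shape:
            raise ShapeError(
                f"page {i} has shape {plane.shape}, expected {shape}")
    pages = np.stack(planes)
    n = pages.shape[0]
    names = [f"ch{i}" for i in range(n)]
    if manifest is not None:
        with open(manifest) as fh:
            mapping = json.load(fh)
        for key, name in mapping.items():
            idx = int(key)
            if not 0 <= idx < n:
                raise ValidationError(f"manifest page index {idx} out of range 0..{n - 1}")
            names[idx] = str(name)
    if len(set(names)) != n:
        raise ValidationError(f"duplicate channel names in manifest: {names}")
    return MimsImage(channels={name: pages[i] for i, name in enumerate(names)})


def save_stack(img: MimsImage, path: str | Path,
               manifest: str | Path | None = None) -> None:
    """Write a stack as multi-page TIFF (+ optional JSON manifest)."""
    planes = []
    for plane in img.channels.values():
        arr = np.asarray(plane)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValidationError("ion counts must be integer-valued")
            arr = arr.astype(np.int64)
        dtype = np.uint16 if arr.max(initial=0) < 2 ** 16 else np.uint32
        planes.append(arr.astype(dtype))
    with tifffile.TiffWriter(str(path)) as tw:
        for plane in planes:
            tw.write(plane, photometric="minisblack")
    if manifest is not None:
        mapping = {str(i): name for i, name in enumerate(img.channel_names)}
        atomic_write_text(manifest, json.dumps(mapping, indent=1))


# ---------------------------------------------------------------------------
# LabelMap
# ---------------------------------------------------------------------------
# A label map is a plain 2-D integer ndarray: 0 = unclassified/background,
# 1..K = classes.  Helpers below validate and (de)serialize it.

def validate_labelmap(labels: np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ShapeError(f"label map must be 2-D, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
            raise ValidationError("label map has float dtype; cast to int explicitly")
        raise ValidationError(f"label map must be integer-valued (dtype={arr.dtype})")
    if arr.min(initial=0) < 0:
        raise ValidationError("label map contains negative labels")
    return arr


def save_labelmap(labels: np.ndarray, path: str | Path) -> None:
    arr = validate_labelmap(labels)
    tifffile.imwrite(str(path), arr.astype(np.int32))


def load_labelmap(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return validate_labelmap(arr)


# ---------------------------------------------------------------------------
# RoiSet
# ---------------------------------------------------------------------------

@dataclass
class Roi:
    """A connected, class-labeled pixel region.

    ``pixels`` is an ``(n, 2)`` integer array of ``(row, col)`` coordinates.
    """

    roi_id: int
    class_label: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.intp)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise ValidationError(
                f"ROI {self.roi_id}: pixels must be a non-empty (n, 2) array")
        self.pixels = px

    @property
    def size(self) -> int:
        return len(self.pixels)

    def flat_indices(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Row-major flat pixel indices within an image of *image_shape*."""
        return self.pixels[:, 0] * image_shape[1] + self.pixels[:, 1]

    def is_connected(self, connectivity: int = 8) -> bool:
        r0, c0 = self.pixels.min(axis=0)
        r1, c1 = self.pixels.max(axis=0)
        mask = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
        mask[self.pixels[:, 0] - r0, self.pixels[:, 1] - c0] = True
        structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
        _, n = ndimage.label(mask, structure=structure)
        return n == 1


@dataclass
class RoiSet:
    """A collection of mutually disjoint ROIs on one image."""

    rois: list[Roi]
    image_shape: tuple[int, int]
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.image_shape = tuple(int(v) for v in self.image_shape)
        self.validate()

    def validate(self) -> None:
        h, w = self.image_shape
        all_idx, all_ids = [], []
        for roi in self.rois:
            px = roi.pixels
            if px.min(initial=0) < 0 or px[:, 0].max(initial=0) >= h \
                    or px[:, 1].max(initial=0) >= w:
                raise ValidationError(
                    f"ROI {roi.roi_id} has pixels outside image {self.image_shape}")
            if not roi.is_connected(self.connectivity):
                raise ValidationError(
                    f"ROI {roi.roi_id} is not {self.connectivity}-connected")
            all_idx.append(roi.flat_indices(self.image_shape))
            all_ids.append(np.full(roi.size, roi.roi_id, dtype=np.int64))
        if not all_idx:
            return
        idx = np.concatenate(all_idx)
        ids = np.concatenate(all_ids)
        order = np.argsort(idx, kind="stable")
        idx, ids = idx[order], ids[order]
        dup = np.flatnonzero(np.diff(idx) == 0)
        for d in dup:
            if ids[d] != ids[d + 1]:
                raise OverlapError(int(ids[d]), int(ids[d + 1]))
            raise ValidationError(
                f"ROI {int(ids[d])} lists pixel index {int(idx[d])} twice")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self) -> Iterator[Roi]:
        return iter(self.rois)

    @property
    def class_labels(self) -> list[int]:
        return sorted({roi.class_label for roi in self.rois})

    def rois_of_class(self, class_label: int) -> list[Roi]:
        return [r for r in self.rois if r.class_label == class_label]

    def pixels_of_class(self, class_label: int) -> np.ndarray:
        """Union of pixel coordinates of all ROIs of one class, (n, 2)."""
        parts = [r.pixels for r in self.rois_of_class(class_label)]
        if not parts:
            return np.empty((0, 2), dtype=np.intp)
        return np.concatenate(parts)

    def to_labelmap(self) -> np.ndarray:
        """Paint ROIs onto a fresh label map (non-ROI pixels = 0)."""
        out = np.zeros(self.image_shape, dtype=np.int32)
        for roi in self.rois:
            out[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.class_label
        return out


def _rle_encode(flat_idx: np.ndarray) -> list[list[int]]:
    """Row-major run-length encoding of a sorted flat pixel-index set."""
    idx = np.sort(np.asarray(flat_idx, dtype=np.int64))
    runs: list[list[int]] = []
    if len(idx) == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    for s, e in zip(starts, ends):
        runs.append([int(idx[s]), int(e - s + 1)])
    return runs


def _rle_decode(runs: Sequence[Sequence[int]]) -> np.ndarray:
    parts = [np.arange(start, start + length, dtype=np.int64)
             for start, length in runs]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)


def save_rois(rs: RoiSet, path: str | Path) -> None:
    """Write a RoiSet as versioned JSON with RLE pixel runs."""
    doc = {
        "schema": ROI_SCHEMA,
        "image_shape": list(rs.image_shape),
        "connectivity": rs.connectivity,
        "rois": [
            {
                "roi_id": int(roi.roi_id),
                "class_label": int(roi.class_label),
                "runs": _rle_encode(roi.flat_indices(rs.image_shape)),
            }
            for roi in rs.rois
        ],
    }
    atomic_write_text(path, json.dumps(doc, indent=1))


def load_rois(path: str | Path) -> RoiSet:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != ROI_SCHEMA:
        raise ValidationError(
            f"unknown ROI schema {doc.get('schema')!r}; expected {ROI_SCHEMA!r}")
    shape = tuple(doc["image_shape"])
    w = shape[1]
    rois = []
    for entry in doc["rois"]:
        flat = _rle_decode(entry["runs"])
        pixels = np.stack([flat // w, flat % w], axis=1)
        rois.append(Roi(roi_id=entry["roi_id"],
                        class_label=entry["class_label"], pixels=pixels))
    return RoiSet(rois=rois, image_shape=shape,
                  connectivity=doc.get("connectivity", 8))
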