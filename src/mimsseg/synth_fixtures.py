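"""Synthetic MIMS images with known class structure and counting noise.

SIMS detectors count individual secondary ions, so shot noise is the
canonical noise model: per pixel of class c the denominator mass (e.g.
12C14N) draws ``Poisson(lambda_c)`` counts and the numerator mass (e.g.
12C15N) draws ``Poisson(r_c * lambda_c)``, where ``r_c`` is the class's
true isotope ratio and ``lambda_c`` its mean ion count.  Class geometry
comes from simple generators (bands, Voronoi cells, blobs); no attempt is
made to mimic histology, instrument drift, or detector dead time.

The default parameters emulate a 15N tracer experiment: class ratios run
from the natural 15N/14N abundance (~0.0037) up to strong enrichment,
with mean counts in the hundreds, giving classes that are well separated
relative to single-pixel ratio noise after 3x3 smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import SamplingError, ValidationError
from .mims_io import MimsImage, Roi, RoiSet

#: Natural abundance ratio of 15N/14N (the unenriched baseline).
NATURAL_15N_RATIO = 0.0037

#: Default class isotope ratios: natural abundance up to strong enrichment.
DEFAULT_CLASS_RATIOS = (0.004, 0.05, 0.12, 0.25, 0.45, 0.8)

#: Default mean denominator-mass counts per pixel, one per class.
DEFAULT_CLASS_LAMBDAS = (500.0, 420.0, 340.0, 270.0, 210.0, 160.0)


@dataclass
class SynthSpec:
    """Recipe for one synthetic MIMS image."""

    shape: tuple[int, int] = (128, 128)
    n_classes: int = 6
    class_ratios: tuple[float, ...] = DEFAULT_CLASS_RATIOS
    class_lambdas: tuple[float, ...] = DEFAULT_CLASS_LAMBDAS
    geometry: str = "voronoi"
    geometry_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(v) for v in self.shape)
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.n_classes > self.shape[0] * self.shape[1]:
            raise ValueError("more classes than pixels")
        self.class_ratios = tuple(float(r) for r in self.class_ratios)[:self.n_classes]
        self.class_lambdas = tuple(float(l) for l in self.class_lambdas)[:self.n_classes]
        if len(self.class_ratios) != self.n_classes or \
                len(self.class_lambdas) != self.n_classes:
            raise ValidationError(
                f"need {self.n_classes} ratios and lambdas, got "
                f"{len(self.class_ratios)} and {len(self.class_lambdas)}")
        if min(self.class_ratios) <= 0 or min(self.class_lambdas) <= 0:
            raise ValidationError("ratios and lambdas must be positive")
        if self.geometry not in ("bands", "voronoi", "blobs"):
            raise ValidationError(f"unknown geometry {self.geometry!r}")


def make_truth(spec: SynthSpec) -> np.ndarray:
    """Generate the ground-truth label map (every pixel in 1..K)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    K = spec.n_classes
    if spec.geometry == "bands":
        # K horizontal bands of (near-)equal height, top to bottom
        edges = np.linspace(0, h, K + 1).round().astype(int)
        labels = np.zeros((h, w), dtype=np.int32)
        for c in range(K):
            labels[edges[c]:edges[c + 1], :] = c + 1
        return labels
    if spec.geometry == "voronoi":
        # nearest-seed labeling: K convex, connected cells.  Seed points
        # are rejection-sampled to a minimum pairwise distance so every
        # cell is large enough to host annotation ROIs; the requirement
        # relaxes gradually if a seed set cannot be found.
        min_dist = float(spec.geometry_params.get(
            "min_seed_distance", min(h, w) / 4))
        seeds = None
        while seeds is None:
            for _ in range(200):
                flat = rng.choice(h * w, size=K, replace=False)
                cand = np.stack([flat // w, flat % w], axis=1)
                margin_ok = np.all((cand >= min_dist / 2) &
                                   (cand < np.array([h, w]) - min_dist / 2))
                diff = cand[:, None, :] - cand[None, :, :]
                d = np.sqrt((diff ** 2).sum(-1)) + np.eye(K) * 1e9
                if margin_ok and d.min() >= min_dist:
                    seeds = cand
                    break
            else:
                min_dist *= 0.8
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        d2 = ((rr[..., None] - seeds[:, 0]) ** 2
              + (cc[..., None] - seeds[:, 1]) ** 2)
        return (np.argmin(d2, axis=-1) + 1).astype(np.int32)
    # blobs: class 1 background, classes 2..K as random non-overlapping disks
    radius = int(spec.geometry_params.get("radius", max(3, min(h, w) // 8)))
    labels = np.ones((h, w), dtype=np.int32)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for c in range(2, K + 1):
        for _ in range(1000):
            r = int(rng.integers(radius, h - radius))
            col = int(rng.integers(radius, w - radius))
            disk = (rr - r) ** 2 + (cc - col) ** 2 <= radius ** 2
            if np.all(labels[disk] == 1):
                labels[disk] = c
                break
        else:
            raise SamplingError(
                f"could not place blob for class {c} (radius {radius})")
    return labels


def simulate_counts(truth: np.ndarray, spec: SynthSpec) -> MimsImage:
    """Draw Poisson ion counts for a truth map.

    Returns a two-channel image: denominator mass ``"m2"`` with mean
    ``lambda_c`` and numerator mass ``"m1"`` with mean ``r_c * lambda_c``
    per pixel of class c.
    """
    truth = np.asarray(truth)
    labels = np.unique(truth)
    if labels.min(initial=1) < 1 or labels.max(initial=1) > spec.n_classes:
        raise ValueError(
            f"truth labels {labels.tolist()} outside 1..{spec.n_classes}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    lam2 = np.zeros(truth.shape)
    lam1 = np.zeros(truth.shape)
    for c in range(1, spec.n_classes + 1):
        mask = truth == c
        lam2[mask] = spec.class_lambdas[c - 1]
        lam1[mask] = spec.class_ratios[c - 1] * spec.class_lambdas[c - 1]
    m2 = rng.poisson(lam2).astype(np.int64)
    m1 = rng.poisson(lam1).astype(np.int64)
    return MimsImage(channels={"m2": m2, "m1": m1},
                     meta={"synthetic": True, "seed": spec.seed,
                           "geometry": spec.geometry})


def make_expert_annotations(truth: np.ndarray, rois_per_class: int = 2,
                            roi_radius: int = 4, margin: int = 2,
                            seed: int | np.random.Generator = 0) -> RoiSet:
    """Sample disk-shaped stand-ins for expert freehand training ROIs.

    Per class, *rois_per_class* disjoint disks of *roi_radius* are placed
    fully interior to the class's regions, at least *margin* pixels from
    any class border, and labeled with the true class.
    """
    truth = np.asarray(truth)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = truth.shape
    rr, cc = np.meshgrid(np.arange(-roi_radius, roi_radius + 1),
                         np.arange(-roi_radius, roi_radius + 1), indexing="ij")
    disk = rr ** 2 + cc ** 2 <= roi_radius ** 2
    disk_off = np.argwhere(disk) - roi_radius
    erosion = ndimage.generate_binary_structure(2, 2)
    occupied = np.zeros((h, w), dtype=bool)
    rois = []
    roi_id = 1
    for c in sorted(int(v) for v in np.unique(truth) if v > 0):
        interior = ndimage.binary_erosion(
            truth == c, structure=erosion, iterations=roi_radius + margin,
            border_value=0)
        placed = 0
        candidates = np.argwhere(interior)
        if len(candidates) == 0:
            raise SamplingError(
                f"class {c}: no interior pixels at radius {roi_radius} "
                f"+ margin {margin}")
        for _ in range(200 * rois_per_class):
            if placed == rois_per_class:
                break
            center = candidates[int(rng.integers(len(candidates)))]
            px = center + disk_off
            if np.any(occupied[px[:, 0], px[:, 1]]):
                continue
            occupied[px[:, 0], px[:, 1]] = True
            rois.append(Roi(roi_id=roi_id, class_label=c, pixels=px))
            roi_id += 1
            placed += 1
        if placed < rois_per_class:
            raise SamplingError(
                f"class {c}: placed only {placed}/{rois_per_class} ROIs")
    return RoiSet(rois=rois, image_shape=(h, w))


def make_fixture(spec: SynthSpec, rois_per_class: int = 2, roi_radius: int = 4,
                 margin: int = 2) -> tuple[np.ndarray, MimsImage, RoiSet]:
    """Convenience: truth map, simulated counts and annotations in one call."""
    truth = make_truth(spec)
    img = simulate_counts(truth, spec)
    ann = make_expert_annotations(
        truth, rois_per_class=rois_per_class, roi_radius=roi_radius,
        margin=margin, seed=np.random.default_rng(np.random.SeedSequence([spec.seed, 2])))
    return truth, img, ann
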