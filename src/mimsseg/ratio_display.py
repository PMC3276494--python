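"""Scaled isotope-ratio images and hue-saturation-intensity (HSI) rendering.

In a stable-isotope tracer experiment the quantity of interest at each
pixel is the ratio of two mass channels (e.g. 12C15N / 12C14N), scaled by
convention by 10000.  Ratio values span a high dynamic range and the
per-pixel precision depends on the ion counts behind them, so the field's
standard display encodes the ratio as hue (blue = low, red = high) and the
ion counts as brightness, de-emphasizing noisy low-count pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .errors import ShapeError
from .mims_io import MimsImage

DEFAULT_RATIO_SCALE = 10000.0


@dataclass
class RatioImage:
    """Pixel-wise scaled quotient of two mass channels.

    ``values[i] = scale * numerator[i] / denominator[i]`` where the
    denominator count is positive; pixels with zero denominator carry
    ``values = 0`` and ``valid = False``.
    """

    values: np.ndarray
    numerator: str
    denominator: str
    scale: float = DEFAULT_RATIO_SCALE
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ShapeError("valid mask shape differs from values")

    @property
    def name(self) -> str:
        """Selector name used in feature configurations, ``"num/den"``."""
        return f"{self.numerator}/{self.denominator}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def compute_ratio(img: MimsImage, numerator: str, denominator: str,
                  scale: float = DEFAULT_RATIO_SCALE) -> RatioImage:
    """Compute the scaled ratio image of two mass channels.

    Pixels where the denominator count is zero are marked invalid and set
    to 0 (the ratio is undefined there, not infinite).
    """
    m1 = np.asarray(img.channel(numerator), dtype=float)
    m2 = np.asarray(img.channel(denominator), dtype=float)
    valid = m2 > 0
    values = np.zeros(m1.shape, dtype=float)
    np.divide(m1, m2, out=values, where=valid)
    values *= scale
    return RatioImage(values=values, numerator=numerator,
                      denominator=denominator, scale=scale, valid=valid)


@dataclass
class HsiRendering:
    """RGB composite where hue encodes the ratio and brightness the counts."""

    rgb: np.ndarray  # (rows, cols, 3) uint8
    rmin: float
    rmax: float
    intensity_source: str
    intensity_ceiling: float


# Hue sweep in degrees: 240 (blue, lowest ratio) down to 0 (red, highest).
_HUE_LOW_DEG = 240.0


def render_hsi(ratio: RatioImage, counts: np.ndarray, rmin: float, rmax: float,
               intensity_ceiling: float | None = None,
               intensity_source: str = "") -> HsiRendering:
    """Render a ratio image as an HSI composite.

    Parameters
    ----------
    ratio
        The scaled ratio image; hue is a linear map of
        ``clip(values, rmin, rmax)`` onto the blue-to-red rainbow.
    counts
        Ion-count plane controlling per-pixel brightness,
        ``min(counts / intensity_ceiling, 1)``; conventionally the
        denominator mass channel.
    intensity_ceiling
        Counts at (or above) which a pixel reaches full brightness.
        Defaults to the 99th percentile of *counts* (0-count images get 1).

    Invalid ratio pixels render black regardless of counts.
    """
    if not rmin < rmax:
        raise ValueError(f"rmin must be < rmax, got {rmin} >= {rmax}")
    counts = np.asarray(counts, dtype=float)
    if counts.shape != ratio.shape:
        raise ShapeError("counts plane shape differs from ratio image")
    if intensity_ceiling is None:
        intensity_ceiling = float(np.percentile(counts, 99)) or 1.0
    if intensity_ceiling <= 0:
        raise ValueError("intensity_ceiling must be positive")

    t = (np.clip(ratio.values, rmin, rmax) - rmin) / (rmax - rmin)
    hue = (_HUE_LOW_DEG / 360.0) * (1.0 - t)
    value = np.clip(counts / intensity_ceiling, 0.0, 1.0)
    value[~ratio.valid] = 0.0
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    rgb = np.floor(hsv_to_rgb(hsv) * 255.0 + 0.5).astype(np.uint8)
    return HsiRendering(rgb=rgb, rmin=float(rmin), rmax=float(rmax),
                        intensity_source=intensity_source,
                        intensity_ceiling=float(intensity_ceiling))


def save_rendering(rendering: HsiRendering, path) -> None:
    """Write the composite to a PNG file."""
    import imageio.v3 as iio

    iio.imwrite(str(path), rendering.rgb, extension=".png")
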