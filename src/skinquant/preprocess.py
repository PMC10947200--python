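"""Per-tile preprocessing: colour normalization, specimen filtering,
grayscale conversion and adaptive stain thresholding.

Colour normalization is Reinhard-style mean/std transfer in CIELAB:
each channel of the source tile is centred, rescaled by the ratio of
reference to source standard deviation, shifted to the reference mean
and converted back to RGB.  The normalization method is pluggable —
pass any callable with the same signature to the pipeline config to
substitute e.g. a stain-vector (Macenko-style) method.

DAB-positive stain is *dark* on a light background, so the adaptive
threshold flags the dark phase: a pixel is stain iff its luminance
falls below the local window mean minus an offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color

from .types import BinaryMask, InvalidArgumentError, RgbTile

#: Luminance above which a pixel counts as glass/background by default.
DEFAULT_BACKGROUND_LUMINANCE = 240
#: Skip a tile when more than this fraction of pixels is background.
DEFAULT_MAX_BACKGROUND_FRACTION = 0.95
#: Default offset (levels below the local mean) for generic dark-object
#: thresholding.
DEFAULT_THRESHOLD_OFFSET = 10

_MIN_STD = 1e-6


@dataclass(frozen=True)
class ColorStats:
    """Per-channel mean/std of a reference tile in CIELAB."""

    mean: tuple[float, float, float]
    std: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.mean) != 3 or len(self.std) != 3:
            raise InvalidArgumentError("ColorStats needs exactly 3 channels")
        if any(s < 0 for s in self.std):
            raise InvalidArgumentError("standard deviations must be >= 0")


def _to_lab(tile: RgbTile) -> np.ndarray:
    return color.rgb2lab(tile.pixels.astype(np.float64) / 255.0)


def compute_color_stats(tile: RgbTile) -> ColorStats:
    """Mean and standard deviation of each CIELAB channel of a tile."""
    lab = _to_lab(tile)
    mean = lab.reshape(-1, 3).mean(axis=0)
    std = lab.reshape(-1, 3).std(axis=0)
    return ColorStats(mean=tuple(float(m) for m in mean),
                      std=tuple(float(s) for s in std))


def normalize_color(tile: RgbTile, reference: ColorStats) -> RgbTile:
    """Reinhard mean/std colour transfer towards a reference tile.

    Channels with degenerate source spread (std < 1e-6) are set flat to
    the reference mean, which keeps constant-colour tiles well-defined.
    Output is clipped back to valid 8-bit RGB.
    """
    lab = _to_lab(tile)
    out = np.empty_like(lab)
    for c in range(3):
        src = lab[:, :, c]
        src_mean = src.mean()
        src_std = src.std()
        if src_std < _MIN_STD:
            out[:, :, c] = reference.mean[c]
        else:
            out[:, :, c] = ((src - src_mean) * (reference.std[c] / src_std)
                            + reference.mean[c])
    rgb = color.lab2rgb(out)
    rgb8 = np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
    return RgbTile(pixels=rgb8, origin_x=tile.origin_x, origin_y=tile.origin_y,
                   level_magnification=tile.level_magnification)


def to_grayscale(tile: RgbTile) -> np.ndarray:
    """ITU-R BT.601 luminance: round(0.299 R + 0.587 G + 0.114 B)."""
    p = tile.pixels.astype(np.float64)
    lum = 0.299 * p[:, :, 0] + 0.587 * p[:, :, 1] + 0.114 * p[:, :, 2]
    return np.clip(np.rint(lum), 0, 255).astype(np.uint8)


def specimen_present(tile: RgbTile,
                     background_luminance: float = DEFAULT_BACKGROUND_LUMINANCE,
                     max_background_fraction: float = DEFAULT_MAX_BACKGROUND_FRACTION,
                     ) -> bool:
    """Whether a tile contains specimen rather than bare glass.

    True iff the fraction of pixels brighter than ``background_luminance``
    is at most ``max_background_fraction``.
    """
    if not 0 <= background_luminance <= 255:
        raise InvalidArgumentError("background_luminance must be in [0, 255]")
    if not 0 <= max_background_fraction <= 1:
        raise InvalidArgumentError("max_background_fraction must be in [0, 1]")
    lum = to_grayscale(tile)
    frac = float((lum > background_luminance).mean())
    return frac <= max_background_fraction


def default_window(tile_size: int) -> int:
    """Default adaptive-threshold window: nearest odd integer to tile/8."""
    w = max(3, tile_size // 8)
    if w % 2 == 0:
        w += 1
    return w


def adaptive_threshold(gray: np.ndarray, window: int,
                       offset: float = DEFAULT_THRESHOLD_OFFSET) -> BinaryMask:
    """Bradley-style local-mean threshold of the dark (stained) phase.

    A pixel is foreground iff its intensity is strictly below the mean
    of the ``window`` x ``window`` neighbourhood (replicate-padded at the
    borders) minus ``offset`` levels.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidArgumentError(
            f"window must be odd and >= 3, got {window}"
        )
    if offset < 0:
        raise InvalidArgumentError("offset must be >= 0")
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise InvalidArgumentError("adaptive_threshold expects a 2-D raster")
    local_mean = ndimage.uniform_filter(gray, size=window, mode="nearest")
    mask = (gray < local_mean - offset).astype(np.uint8)
    return BinaryMask(values=mask, role="stain")
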