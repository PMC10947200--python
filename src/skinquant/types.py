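"""Core domain types for the skin IHC quantification pipeline.

All rasters are numpy arrays in row-major (y, x) order with 0-based,
half-open pixel coordinates.  Class-code conventions follow the two
segmentation tasks:

tissue masks
    1 = epidermis, 2 = dermal papilla / dermis, 3 = hair follicle,
    sweat gland or other artefact, 4 = background.

cell masks
    1 = positive cell membrane/cytoplasm, 2 = negative cell
    membrane/cytoplasm, 3 = positive cell nucleus, 4 = negative cell
    nucleus, 5 = other non-cell structure.

combined cell masks
    1 = positive cell, 2 = negative cell, 0 = any other structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TISSUE_CODES = frozenset({1, 2, 3, 4})
CELL_CODES = frozenset({1, 2, 3, 4, 5})
COMBINED_CODES = frozenset({0, 1, 2})

TISSUE_EPIDERMIS = 1
TISSUE_DERMIS = 2
TISSUE_ARTEFACT = 3
TISSUE_BACKGROUND = 4

CELL_POS_MEMBRANE = 1
CELL_NEG_MEMBRANE = 2
CELL_POS_NUCLEUS = 3
CELL_NEG_NUCLEUS = 4
CELL_OTHER = 5


class SkinQuantError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(SkinQuantError, ValueError):
    """An argument violates an operation's precondition."""


class FormatError(SkinQuantError, ValueError):
    """An input file does not meet the expected image format."""


class ValidationError(SkinQuantError, ValueError):
    """Data content violates a declared invariant."""


class ConfigurationError(SkinQuantError, ValueError):
    """Pipeline or model configuration is inconsistent."""


def _as_uint8_rgb(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidArgumentError(
            f"RGB tile must be H x W x 3, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidArgumentError("RGB tile must have H >= 1 and W >= 1")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating):
            if arr.min() < 0 or arr.max() > 255:
                raise InvalidArgumentError("intensities must lie in [0, 255]")
            arr = np.rint(arr)
        elif arr.min() < 0 or arr.max() > 255:
            raise InvalidArgumentError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


@dataclass
class RgbTile:
    """An RGB image block with its slide-coordinate origin.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
        8-bit intensities.
    origin_x, origin_y : int
        0-based pixel offset of the tile's top-left corner in slide
        coordinates.
    level_magnification : float
        Nominal scan magnification tag (e.g. 20 or 40).
    """

    pixels: np.ndarray
    origin_x: int = 0
    origin_y: int = 0
    level_magnification: float = 20.0

    def __post_init__(self) -> None:
        self.pixels = _as_uint8_rgb(self.pixels)
        if self.origin_x < 0 or self.origin_y < 0:
            raise InvalidArgumentError("tile origin must be non-negative")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.height, self.width


def validate_class_mask(codes: np.ndarray, allowed_codes) -> np.ndarray:
    """Check every pixel of ``codes`` against an allowed vocabulary.

    Returns the mask as a contiguous integer array.  Raises
    :class:`ValidationError` naming the first offending value and its
    (y, x) coordinate in row-major order.
    """
    arr = np.ascontiguousarray(np.asarray(codes))
    if arr.ndim != 2:
        raise InvalidArgumentError(f"class mask must be 2-D, got shape {arr.shape}")
    allowed = np.array(sorted(allowed_codes))
    bad = ~np.isin(arr, allowed)
    if bad.any():
        ys, xs = np.nonzero(bad)
        y, x = int(ys[0]), int(xs[0])
        raise ValidationError(
            f"mask value {int(arr[y, x])} at (y={y}, x={x}) is outside the "
            f"allowed codes {sorted(int(c) for c in allowed_codes)}"
        )
    return arr.astype(np.int64, copy=False)


@dataclass
class TissueMask:
    """Per-pixel tissue class codes (1=epidermis .. 4=background)."""

    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = validate_class_mask(self.codes, TISSUE_CODES)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.codes.shape)  # type: ignore[return-value]


@dataclass
class CellMask:
    """Per-pixel cell class codes (1..4 cell structures, 5=other)."""

    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = validate_class_mask(self.codes, CELL_CODES)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.codes.shape)  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A {0,1} raster with a semantic role tag.

    Roles used in the pipeline: ``"epidermis"`` (tissue foreground),
    ``"stain"`` (adaptive-threshold DAB mask), ``"cell-foreground"``.
    """

    values: np.ndarray
    role: str = "cell-foreground"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise InvalidArgumentError("binary mask must be 2-D")
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("binary mask must contain only 0 and 1")
        self.values = arr.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]


@dataclass
class CombinedCellMask:
    """Fused cell raster: 1=positive cell, 2=negative cell, 0=other."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = validate_class_mask(self.values, COMBINED_CODES)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]


@dataclass
class InstanceLabels:
    """Watershed-split cell instances.

    ``labels`` is a non-negative integer raster; 0 is background and the
    positive labels are contiguous 1..N.  ``polarity`` records whether
    these are positive (1) or negative (2) cells.
    """

    labels: np.ndarray
    polarity: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise InvalidArgumentError("instance labels must be 2-D")
        if arr.min() < 0:
            raise ValidationError("instance labels must be non-negative")
        if self.polarity not in (1, 2):
            raise InvalidArgumentError("polarity must be 1 (positive) or 2 (negative)")
        self.labels = arr.astype(np.int64, copy=False)

    @property
    def n_instances(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class Window:
    """A half-open raster window [x, x+w) x [y, y+h)."""

    x: int
    y: int
    width: int
    height: int


@dataclass
class TileGrid:
    """Row-major tile windows covering a slide, top-left first."""

    windows: list[Window]
    tile_size: int
    slide_width: int
    slide_height: int

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class SectionQuant:
    """Per-section quantification endpoints.

    Counts are positive/negative cell instances inside the epidermis
    (``_epi``) and outside it (``_derm``).  Percentages are
    100 * pos / (pos + neg), ``None`` when a compartment holds no cells.
    ``avg_signal`` is the mean stain darkness (255 - grayscale) over all
    pixels of positive-cell instances, ``None`` when there are none.
    """

    n_pos_epi: int = 0
    n_neg_epi: int = 0
    n_pos_derm: int = 0
    n_neg_derm: int = 0
    pct_positive_epi: Optional[float] = None
    pct_positive_derm: Optional[float] = None
    avg_signal: Optional[float] = None
    n_excluded: int = 0

    @property
    def n_pos(self) -> int:
        return self.n_pos_epi + self.n_pos_derm

    @property
    def n_neg(self) -> int:
        return self.n_neg_epi + self.n_neg_derm


@dataclass
class SegMetrics:
    """One validation run's five segmentation metrics, on the 0-100 scale."""

    global_accuracy: float
    mean_accuracy: float
    mean_iou: float
    weighted_iou: float
    mean_bf: float

    def as_dict(self) -> dict[str, float]:
        return {
            "GlobalAccuracy": self.global_accuracy,
            "MeanAccuracy": self.mean_accuracy,
            "MeanIoU": self.mean_iou,
            "WeightedIoU": self.weighted_iou,
            "MeanBFScore": self.mean_bf,
        }


@dataclass
class SplitSpec:
    """Random train/test/left-out split fractions plus the base seed."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0


@dataclass
class FoldReport:
    """k rows of :class:`SegMetrics` plus their arithmetic-mean row."""

    folds: list[SegMetrics] = field(default_factory=list)
    average: Optional[SegMetrics] = None

    def as_table(self) -> list[dict[str, float]]:
        rows = [m.as_dict() for m in self.folds]
        if self.average is not None:
            rows.append(self.average.as_dict())
        return rows
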