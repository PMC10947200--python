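"""Mask fusion, noise removal and watershed instance splitting.

The raw outputs of the two segmentation models are turned into clean
binary compartment masks and individual cell instances:

1. the tissue mask is binarized to an epidermis mask;
2. the cell mask is fused with the adaptive-threshold stain mask into a
   {0,1,2} raster (1 = positive cell, 2 = negative cell) — the stain
   mask can *promote* a model-detected cell from negative to positive
   (rescuing stained cells an under-trained cell model missed) but
   never creates cells on its own;
3. connected objects of at most 100 pixels are removed as noise
   (inclusive cutoff);
4. touching cells are split by marker-controlled watershed on the
   negated Euclidean distance transform.

Connectivity is 8-connected throughout.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import relabel_sequential, watershed

from .types import (
    BinaryMask,
    CellMask,
    CombinedCellMask,
    InstanceLabels,
    InvalidArgumentError,
    TissueMask,
)

DEFAULT_MAX_NOISE_AREA = 100
DEFAULT_MIN_SEED_DISTANCE = 5

_STRUCT8 = np.ones((3, 3), dtype=bool)


def binarize_tissue(mask: TissueMask, foreground_codes=frozenset({1})) -> BinaryMask:
    """Binarize a tissue mask: 1 where the code is in ``foreground_codes``.

    The default foreground is the epidermis (code 1); pass e.g. {1, 2}
    to include dermal papillae.
    """
    if not foreground_codes:
        raise InvalidArgumentError("foreground_codes must not be empty")
    fg = np.isin(mask.codes, sorted(foreground_codes)).astype(np.uint8)
    return BinaryMask(values=fg, role="epidermis")


def fuse_cell_masks(cells: CellMask, stain: BinaryMask) -> CombinedCellMask:
    """Combine the cell-model mask with the stain mask into {0,1,2}.

    Pixel rules (cell codes: 1/3 positive membrane/nucleus, 2/4
    negative membrane/nucleus, 5 other):

    * cells in {1,3}                      -> 1 (positive)
    * cells in {2,4} and stain == 1       -> 1 (promoted to positive)
    * cells in {2,4} and stain == 0       -> 2 (negative)
    * cells == 5                          -> 0 (stain alone never
      creates a cell)
    """
    if cells.shape != stain.shape:
        raise InvalidArgumentError(
            f"cell mask shape {cells.shape} does not match stain mask "
            f"shape {stain.shape}"
        )
    c = cells.codes
    positive = np.isin(c, (1, 3))
    negative = np.isin(c, (2, 4))
    out = np.zeros(c.shape, dtype=np.int64)
    out[negative] = 2
    out[negative & (stain.values == 1)] = 1
    out[positive] = 1
    return CombinedCellMask(values=out)


def remove_small_objects(
    mask: Union[BinaryMask, CombinedCellMask],
    max_noise_area: int = DEFAULT_MAX_NOISE_AREA,
) -> Union[BinaryMask, CombinedCellMask]:
    """Remove 8-connected components with area <= ``max_noise_area``.

    For a :class:`CombinedCellMask` the rule is applied per nonzero
    value class (positive and negative components independently).
    """
    if max_noise_area < 0:
        raise InvalidArgumentError("max_noise_area must be >= 0")
    values = mask.values.copy()
    nonzero_classes = [v for v in np.unique(values) if v != 0]
    for v in nonzero_classes:
        binary = values == v
        lbl, n = ndimage.label(binary, structure=_STRUCT8)
        if n == 0:
            continue
        areas = np.bincount(lbl.ravel())[1:]
        small = np.nonzero(areas <= max_noise_area)[0] + 1
        if small.size:
            values[np.isin(lbl, small)] = 0
    if isinstance(mask, BinaryMask):
        return BinaryMask(values=values, role=mask.role)
    return CombinedCellMask(values=values)


def extract_polarity(mask: CombinedCellMask, polarity: int) -> BinaryMask:
    """Binary mask of one polarity (1 = positive cells, 2 = negative)."""
    if polarity not in (1, 2):
        raise InvalidArgumentError("polarity must be 1 or 2")
    return BinaryMask(values=(mask.values == polarity).astype(np.uint8),
                      role="cell-foreground")


def split_instances(mask: BinaryMask,
                    min_seed_distance: int = DEFAULT_MIN_SEED_DISTANCE,
                    polarity: int = 1) -> InstanceLabels:
    """Split clustered cells by marker-controlled watershed.

    Markers are local maxima of the Euclidean distance transform, at
    least ``min_seed_distance`` px apart within each connected
    component; flooding the negated distance transform from those
    markers assigns every foreground pixel to exactly one instance.
    Components in which peak detection yields no marker (tiny or
    degenerate shapes) are kept as single instances.  Labels are
    relabelled contiguously 1..N.
    """
    binary = mask.values.astype(bool)
    if not binary.any():
        return InstanceLabels(labels=np.zeros(mask.shape, dtype=np.int64),
                              polarity=polarity)
    components, _ = ndimage.label(binary, structure=_STRUCT8)
    distance = ndimage.distance_transform_edt(binary)
    coords = peak_local_max(distance, min_distance=min_seed_distance,
                            labels=components, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int64)
    for i, (y, x) in enumerate(coords, start=1):
        markers[y, x] = i
    labels = watershed(-distance, markers=markers, mask=binary,
                       connectivity=2)
    # components without any marker stay 0: keep them as whole instances
    orphan = binary & (labels == 0)
    if orphan.any():
        extra, n_extra = ndimage.label(orphan, structure=_STRUCT8)
        labels = labels + np.where(orphan, extra + labels.max(), 0)
    labels, _, _ = relabel_sequential(labels)
    return InstanceLabels(labels=labels.astype(np.int64), polarity=polarity)


def apply_exclusion(mask: Union[BinaryMask, CombinedCellMask],
                    exclusion: Optional[BinaryMask]):
    """Zero out pixels under a user-supplied exclusion mask.

    Stands in for the manual removal of residual artefacts: users
    export a nonzero-is-excluded mask and pass it before
    quantification.
    """
    if exclusion is None:
        return mask
    if exclusion.shape != mask.shape:
        raise InvalidArgumentError("exclusion mask shape mismatch")
    values = np.where(exclusion.values > 0, 0, mask.values)
    if isinstance(mask, BinaryMask):
        return BinaryMask(values=values, role=mask.role)
    return CombinedCellMask(values=values)
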