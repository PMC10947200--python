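"""Bit-exact readers and writers for tiles, class masks and result files.

Tiles and masks travel as plain 8-bit PNG or (uncompressed) TIFF;
proprietary scanner formats are rejected with a clear message — convert
whole-slide files to TIFF/PNG before running the pipeline.  Mask files
are single-channel images whose pixel values are the literal class
codes (not palette indices).

File naming pairs a tile with its masks:
``{slide}_x{origin_x}_y{origin_y}.png`` with siblings
``..._tissue.png`` and ``..._cells.png``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Union

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError

from .types import (
    CELL_CODES,
    TISSUE_CODES,
    CellMask,
    FormatError,
    InvalidArgumentError,
    RgbTile,
    TissueMask,
    validate_class_mask,
)

_PROPRIETARY = {".svs", ".ndpi", ".scn", ".mrxs", ".vms", ".vmu", ".dcm"}


def _check_extension(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in _PROPRIETARY:
        raise FormatError(
            f"{path.name}: proprietary scanner format '{ext}' is not "
            "supported; convert the slide to plain TIFF or PNG first"
        )
    if ext not in {".png", ".tif", ".tiff"}:
        raise FormatError(
            f"{path.name}: unsupported extension '{ext}' (use PNG or TIFF)"
        )
    return ext


def _load_array(path: Path) -> np.ndarray:
    ext = _check_extension(path)
    try:
        if ext in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except (UnidentifiedImageError, OSError, ValueError) as exc:
        raise FormatError(f"{path.name}: unreadable image file ({exc})") from exc
    return arr


def read_rgb_tile(path, origin_x: int = 0, origin_y: int = 0,
                  level_magnification: float = 20.0) -> RgbTile:
    """Read an 8-bit PNG/TIFF tile; grayscale is promoted to 3 channels."""
    path = Path(path)
    arr = _load_array(path)
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path.name}: expected 8-bit pixels, got dtype {arr.dtype}"
        )
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]  # drop alpha
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path.name}: expected 1, 3 or 4 channels, got shape {arr.shape}"
        )
    origin = _parse_tile_name(path.name)
    if origin is not None:
        origin_x, origin_y = origin
    return RgbTile(pixels=arr.copy(), origin_x=origin_x, origin_y=origin_y,
                   level_magnification=level_magnification)


def write_rgb_tile(tile: RgbTile, path) -> None:
    """Write a tile as 8-bit PNG or uncompressed TIFF (by extension)."""
    path = Path(path)
    ext = _check_extension(path)
    if ext in {".tif", ".tiff"}:
        tifffile.imwrite(path, tile.pixels, compression=None)
    else:
        Image.fromarray(tile.pixels, mode="RGB").save(path, format="PNG")


def read_class_mask(path, allowed_codes) -> np.ndarray:
    """Read an 8-bit single-channel class mask, validating its vocabulary.

    Returns the raw integer raster; wrap in :class:`TissueMask` /
    :class:`CellMask` as needed.
    """
    path = Path(path)
    arr = _load_array(path)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: class masks must be single-channel, got shape {arr.shape}"
        )
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path.name}: expected 8-bit mask pixels, got dtype {arr.dtype}"
        )
    return validate_class_mask(arr, allowed_codes)


def read_tissue_mask(path) -> TissueMask:
    return TissueMask(read_class_mask(path, TISSUE_CODES))


def read_cell_mask(path) -> CellMask:
    return CellMask(read_class_mask(path, CELL_CODES))


def write_class_mask(mask: Union[TissueMask, CellMask, np.ndarray], path) -> None:
    """Write class codes as an 8-bit single-channel PNG/TIFF."""
    codes = getattr(mask, "codes", mask)
    codes = np.asarray(codes)
    if codes.min() < 0 or codes.max() > 255:
        raise InvalidArgumentError("class codes must fit 8-bit")
    arr = codes.astype(np.uint8)
    path = Path(path)
    ext = _check_extension(path)
    if ext in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr, compression=None)
    else:
        Image.fromarray(arr, mode="L").save(path, format="PNG")


# ---------------------------------------------------------------------------
# File naming: {slide}_x{ox}_y{oy}.png, masks {...}_tissue.png / {...}_cells.png

_TILE_RE = re.compile(r"_x(\d+)_y(\d+)(?:_(?:tissue|cells))?\.(?:png|tiff?)$",
                      re.IGNORECASE)


def tile_filename(slide: str, origin_x: int, origin_y: int,
                  kind: str = "tile", ext: str = "png") -> str:
    """Canonical tile/mask file name for a slide window."""
    stem = f"{slide}_x{origin_x}_y{origin_y}"
    if kind == "tile":
        return f"{stem}.{ext}"
    if kind in {"tissue", "cells"}:
        return f"{stem}_{kind}.{ext}"
    raise InvalidArgumentError(f"unknown tile file kind '{kind}'")


def _parse_tile_name(name: str):
    m = _TILE_RE.search(name)
    if m is None:
        return None
    return int(m.group(1)), int(m.group(2))


def write_metrics_json(report, path) -> None:
    """Write a fold report (or any metric mapping) as JSON."""
    path = Path(path)
    if hasattr(report, "as_table"):
        payload = {"folds": [m.as_dict() for m in report.folds]}
        if report.average is not None:
            payload["average"] = report.average.as_dict()
    else:
        payload = report
    path.write_text(json.dumps(payload, indent=2))
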