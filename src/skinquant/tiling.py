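"""Raster tile grids and slide-mask assembly.

A whole-slide image is traversed region by region in row-major order,
top-left first.  Windows that would overhang the slide edge are clamped
so they fit (the last column/row overlaps its neighbour); a slide
smaller than the tile size yields a single window equal to the slide.
"""

from __future__ import annotations

import numpy as np

from .types import InvalidArgumentError, TileGrid, Window


def tile_grid(slide_width: int, slide_height: int, tile_size: int) -> TileGrid:
    """Build the row-major grid of tile windows covering a slide.

    Parameters
    ----------
    slide_width, slide_height : int
        Slide dimensions in pixels, >= 1.
    tile_size : int
        Square window edge in pixels, >= 1.

    Returns
    -------
    TileGrid
        Windows ordered strictly row-major by (origin_y, origin_x);
        their union covers every slide pixel at least once.
    """
    if slide_width < 1 or slide_height < 1 or tile_size < 1:
        raise InvalidArgumentError(
            "slide_width, slide_height and tile_size must all be >= 1 "
            f"(got {slide_width}, {slide_height}, {tile_size})"
        )

    def origins(extent: int) -> list[int]:
        if extent <= tile_size:
            return [0]
        xs = list(range(0, extent - tile_size, tile_size))
        last = extent - tile_size  # clamped so the window fits
        if xs[-1] != last:
            xs.append(last)
        else:  # exact fit: range() stopped one short of the last origin
            xs.append(last)
        return sorted(set(xs))

    w = min(tile_size, slide_width)
    h = min(tile_size, slide_height)
    windows = [
        Window(x, y, w, h)
        for y in origins(slide_height)
        for x in origins(slide_width)
    ]
    return TileGrid(windows=windows, tile_size=tile_size,
                    slide_width=slide_width, slide_height=slide_height)


def split_by_grid(raster: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Cut a slide-sized raster into per-window views (copies)."""
    raster = np.asarray(raster)
    if raster.shape[0] != grid.slide_height or raster.shape[1] != grid.slide_width:
        raise InvalidArgumentError(
            f"raster shape {raster.shape[:2]} does not match grid slide size "
            f"({grid.slide_height}, {grid.slide_width})"
        )
    return [
        raster[w.y:w.y + w.height, w.x:w.x + w.width].copy()
        for w in grid.windows
    ]


def assemble_slide_mask(grid: TileGrid, tile_masks: list[np.ndarray]) -> np.ndarray:
    """Stitch per-tile masks back into a slide-sized raster.

    In overlap zones created by edge clamping the later tile in
    row-major order wins, so every slide pixel receives exactly one
    code.
    """
    if len(tile_masks) != len(grid.windows):
        raise InvalidArgumentError(
            f"expected {len(grid.windows)} tile masks, got {len(tile_masks)}"
        )
    first = np.asarray(tile_masks[0])
    out = np.zeros((grid.slide_height, grid.slide_width), dtype=first.dtype)
    for win, mask in zip(grid.windows, tile_masks):
        mask = np.asarray(mask)
        if mask.shape[:2] != (win.height, win.width):
            raise InvalidArgumentError(
                f"tile mask shape {mask.shape[:2]} does not match window "
                f"({win.height}, {win.width}) at (x={win.x}, y={win.y})"
            )
        out[win.y:win.y + win.height, win.x:win.x + win.width] = mask
    return out
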