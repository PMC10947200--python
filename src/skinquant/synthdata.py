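"""Synthetic DAB-stained skin-section generator with exact ground truth.

Each generated section emulates a brightfield IHC image block: a light
glass background above an epidermal band whose lower boundary undulates
sinusoidally (dermal papillae), dermis below, optional follicle-like
artefact blobs, and elliptical cells coloured brown (DAB-positive) or
blue-gray (haematoxylin-counterstained, negative).  The staining
pattern is configurable: nuclear (stained nucleus only), cytoplasmic
(nucleus plus stained halo) or membrane (stained ring).

The generator returns the image together with pixel-exact tissue and
cell class masks and the per-compartment ground-truth cell counts, so
pipeline output can be checked against a known answer.  Randomness
comes from one ``numpy`` Generator seeded from ``params.seed`` and is
consumed in a fixed order (artefacts, then cell geometry, then cell
polarity, then pixel noise), so identical parameters give bit-identical
sections.

Cells are placed wholly inside one compartment with a clear margin from
every compartment boundary and from each other, so compartment ground
truth is unambiguous and each cell is one connected component.  Nucleus
radii default to 6.5-9 px so that genuine nuclei always exceed the
pipeline's 100-px noise-removal cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .types import (
    CellMask,
    InvalidArgumentError,
    RgbTile,
    SectionQuant,
    TissueMask,
)
from . import io as sqio

STAINING_PATTERNS = ("nuclear", "cytoplasmic", "membrane")


@dataclass(frozen=True)
class SynthPalette:
    """Base colours of the synthetic section, one per semantic class.

    Defaults approximate a haematoxylin/DAB section; every pair of
    colours differs by at least 30 intensity levels in some channel so
    that colour-rule segmentation is well defined.  Values are
    configuration, not contract.
    """

    background: tuple[int, int, int] = (245, 242, 240)
    epidermis: tuple[int, int, int] = (225, 175, 190)
    dermis: tuple[int, int, int] = (240, 210, 218)
    artefact: tuple[int, int, int] = (205, 185, 150)
    positive_nucleus: tuple[int, int, int] = (94, 60, 48)
    negative_nucleus: tuple[int, int, int] = (168, 178, 216)
    positive_cyto: tuple[int, int, int] = (140, 95, 60)
    negative_cyto: tuple[int, int, int] = (200, 205, 230)

    def as_dict(self) -> dict[str, tuple[int, int, int]]:
        return {
            "background": self.background,
            "epidermis": self.epidermis,
            "dermis": self.dermis,
            "artefact": self.artefact,
            "positive_nucleus": self.positive_nucleus,
            "negative_nucleus": self.negative_nucleus,
            "positive_cyto": self.positive_cyto,
            "negative_cyto": self.negative_cyto,
        }

    def __post_init__(self) -> None:
        entries = list(self.as_dict().items())
        for i, (ni, ci) in enumerate(entries):
            for nj, cj in entries[i + 1:]:
                if max(abs(a - b) for a, b in zip(ci, cj)) < 30:
                    raise InvalidArgumentError(
                        f"palette colours '{ni}' and '{nj}' differ by < 30 "
                        "levels in every channel"
                    )


@dataclass
class SynthParams:
    """Parameters of one synthetic section."""

    seed: int = 0
    width: int = 300
    height: int = 300
    #: Fraction of the image height occupied by the glass background strip
    #: above the tissue surface.
    background_depth_frac: float = 0.08
    #: Mean epidermal band depth as a fraction of image height.
    epidermis_depth_frac: float = 0.26
    #: Papillae undulation: amplitude (fraction of height) and number of
    #: full sine cycles across the image width.
    papilla_amplitude_frac: float = 0.07
    papilla_frequency: float = 2.5
    n_cells: int = 40
    positive_fraction: float = 0.3
    staining_pattern: str = "nuclear"
    artefact_count: int = 2
    #: Std of additive Gaussian pixel noise applied after mask generation.
    noise_std: float = 4.0
    #: Nucleus semi-major axis range in pixels.
    nucleus_radius: tuple[float, float] = (6.5, 9.0)
    palette: SynthPalette = field(default_factory=SynthPalette)

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise InvalidArgumentError("positive_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise InvalidArgumentError("n_cells must be >= 0")
        if self.staining_pattern not in STAINING_PATTERNS:
            raise InvalidArgumentError(
                f"staining_pattern must be one of {STAINING_PATTERNS}"
            )
        if self.width < 32 or self.height < 32:
            raise InvalidArgumentError("section must be at least 32 x 32 px")
        if self.noise_std < 0:
            raise InvalidArgumentError("noise_std must be >= 0")


@dataclass
class SynthSection:
    """A generated section: image, exact masks and ground-truth counts."""

    tile: RgbTile
    tissue: TissueMask
    cells: CellMask
    ground_truth: SectionQuant
    params: SynthParams


class PackingError(InvalidArgumentError):
    """Raised when the requested cells do not fit; reports achieved count."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} cells without overlap; "
            f"achieved {achieved} after bounded retries"
        )


# margin (px) kept between a cell footprint and any compartment boundary,
# artefact, or other cell; guarantees unambiguous compartments and
# separate 8-connected components
_CELL_MARGIN = 3
# minimum painted area (px) of a cell footprint, safely above the 100-px
# noise-removal cutoff
_MIN_CELL_AREA = 110


def _tissue_layout(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Tissue class raster (no cells yet): 1 epi, 2 dermis, 3 artefact, 4 bg."""
    h, w = params.height, params.width
    codes = np.full((h, w), 2, dtype=np.int64)
    x = np.arange(w)
    surface = int(round(params.background_depth_frac * h))
    depth = params.epidermis_depth_frac * h
    amp = params.papilla_amplitude_frac * h
    phase = rng.uniform(0, 2 * np.pi)
    lower = surface + depth + amp * np.sin(
        2 * np.pi * params.papilla_frequency * x / w + phase)
    lower = np.clip(np.round(lower).astype(int), surface + 4, h - 8)
    rows = np.broadcast_to(np.arange(h)[:, None], (h, w))
    codes[rows < surface] = 4
    codes[(rows >= surface) & (rows < lower[None, :])] = 1

    # follicle-like artefact blobs, fully inside the dermis
    for _ in range(params.artefact_count):
        for _attempt in range(50):
            cy = rng.uniform(lower.max() + 12, h - 10)
            cx = rng.uniform(10, w - 10)
            ra = rng.uniform(6, min(14, h / 8))
            rb = rng.uniform(0.6, 1.0) * ra
            theta = rng.uniform(0, np.pi)
            rr, cc = draw_ellipse(cy, cx, ra, rb, shape=(h, w), rotation=theta)
            if rr.size and (codes[rr, cc] == 2).all():
                codes[rr, cc] = 3
                break
    return codes


def _cell_footprint(cy: float, cx: float, a: float, b: float, theta: float,
                    pattern: str, shape: tuple[int, int]):
    """Pixel sets for one cell: (nucleus, periphery) index tuples.

    The periphery is empty for nuclear staining, a touching halo for
    cytoplasmic staining, and a detached ring for membrane staining (in
    which case the nucleus set is empty — only membranes are visible).
    """
    nuc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=theta)
    if pattern == "nuclear":
        return nuc, (np.array([], dtype=int), np.array([], dtype=int))
    if pattern == "cytoplasmic":
        outer = draw_ellipse(cy, cx, 1.5 * a, 1.5 * b, shape=shape, rotation=theta)
        nuc_set = set(zip(nuc[0].tolist(), nuc[1].tolist()))
        halo = [(y, x) for y, x in zip(outer[0].tolist(), outer[1].tolist())
                if (y, x) not in nuc_set]
        hy = np.array([p[0] for p in halo], dtype=int)
        hx = np.array([p[1] for p in halo], dtype=int)
        return nuc, (hy, hx)
    # membrane: ring between 1.3 and 1.6 of the nuclear radii
    outer = draw_ellipse(cy, cx, 1.6 * a, 1.6 * b, shape=shape, rotation=theta)
    inner = draw_ellipse(cy, cx, 1.3 * a, 1.3 * b, shape=shape, rotation=theta)
    inner_set = set(zip(inner[0].tolist(), inner[1].tolist()))
    ring = [(y, x) for y, x in zip(outer[0].tolist(), outer[1].tolist())
            if (y, x) not in inner_set]
    ry = np.array([p[0] for p in ring], dtype=int)
    rx = np.array([p[1] for p in ring], dtype=int)
    return (np.array([], dtype=int), np.array([], dtype=int)), (ry, rx)


def generate_section(params: SynthParams) -> SynthSection:
    """Generate one synthetic section with pixel-exact ground truth.

    Raises
    ------
    PackingError
        If ``params.n_cells`` cells cannot be placed without overlap
        after bounded retries; the error reports the achieved count.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    pal = params.palette
    tissue = _tissue_layout(params, rng)
    cells = np.full((h, w), 5, dtype=np.int64)

    image = np.empty((h, w, 3), dtype=np.float64)
    for code, colour in ((1, pal.epidermis), (2, pal.dermis),
                         (3, pal.artefact), (4, pal.background)):
        image[tissue == code] = colour

    blocked = np.zeros((h, w), dtype=bool)  # cells + separation margin
    pattern = params.staining_pattern
    outer_factor = {"nuclear": 1.0, "cytoplasmic": 1.5, "membrane": 1.6}[pattern]

    n_pos = {1: 0, 2: 0}
    n_neg = {1: 0, 2: 0}
    placed = 0
    max_attempts = max(200, 120 * params.n_cells)
    attempts = 0
    while placed < params.n_cells and attempts < max_attempts:
        attempts += 1
        a = rng.uniform(*params.nucleus_radius)
        b = rng.uniform(0.92, 1.0) * a
        theta = rng.uniform(0, np.pi)
        r_out = outer_factor * a
        cy = rng.uniform(r_out + 1, h - r_out - 2)
        cx = rng.uniform(r_out + 1, w - r_out - 2)

        # the whole footprint plus a margin must sit in one compartment
        gy, gx = draw_ellipse(cy, cx, r_out + _CELL_MARGIN, r_out + _CELL_MARGIN,
                              shape=(h, w))
        comp = tissue[gy, gx]
        if not ((comp == 1).all() or (comp == 2).all()):
            continue
        compartment = int(comp[0])
        nuc, peri = _cell_footprint(cy, cx, a, b, theta, pattern, (h, w))
        fy = np.concatenate([nuc[0], peri[0]])
        fx = np.concatenate([nuc[1], peri[1]])
        if fy.size < _MIN_CELL_AREA:
            continue
        if blocked[fy, fx].any():
            continue

        positive = bool(rng.random() < params.positive_fraction)
        if positive:
            if nuc[0].size:
                image[nuc] = pal.positive_nucleus
                cells[nuc] = 3
            if peri[0].size:
                image[peri] = pal.positive_cyto
                cells[peri] = 1
            n_pos[compartment] += 1
        else:
            if nuc[0].size:
                image[nuc] = pal.negative_nucleus
                cells[nuc] = 4
            if peri[0].size:
                image[peri] = pal.negative_cyto
                cells[peri] = 2
            n_neg[compartment] += 1
        my, mx = draw_ellipse(cy, cx, r_out + _CELL_MARGIN, r_out + _CELL_MARGIN,
                              shape=(h, w))
        blocked[my, mx] = True
        placed += 1

    if placed < params.n_cells:
        raise PackingError(params.n_cells, placed)

    gt = _ground_truth_quant(n_pos, n_neg, image, cells)

    if params.noise_std > 0:
        image = image + rng.normal(0.0, params.noise_std, size=image.shape)
    pixels = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return SynthSection(
        tile=RgbTile(pixels=pixels),
        tissue=TissueMask(tissue),
        cells=CellMask(cells),
        ground_truth=gt,
        params=params,
    )


def _ground_truth_quant(n_pos, n_neg, image, cells) -> SectionQuant:
    def pct(p, n):
        return 100.0 * p / (p + n) if (p + n) > 0 else None

    pos_pixels = np.isin(cells, (1, 3))
    if pos_pixels.any():
        rgb = image[pos_pixels]
        lum = np.rint(0.299 * rgb[:, 0] + 0.587 * rgb[:, 1] + 0.114 * rgb[:, 2])
        avg_signal = float(np.mean(255.0 - lum))
    else:
        avg_signal = None
    return SectionQuant(
        n_pos_epi=n_pos[1], n_neg_epi=n_neg[1],
        n_pos_derm=n_pos[2], n_neg_derm=n_neg[2],
        pct_positive_epi=pct(n_pos[1], n_neg[1]),
        pct_positive_derm=pct(n_pos[2], n_neg[2]),
        avg_signal=avg_signal,
    )


def generate_dataset(out_dir, n_tiles: int, params: Optional[SynthParams] = None,
                     slide_name: str = "synth") -> pd.DataFrame:
    """Write ``n_tiles`` paired tile/mask files plus a manifest CSV.

    Tile *i* uses seed ``params.seed + i``; regenerating from the
    manifest reproduces every file byte-identically.
    """
    params = params or SynthParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_tiles):
        p = replace(params, seed=params.seed + i)
        section = generate_section(p)
        ox, oy = 0, i * params.height  # nominal stacked layout
        tile_name = sqio.tile_filename(slide_name, ox, oy)
        tissue_name = sqio.tile_filename(slide_name, ox, oy, kind="tissue")
        cells_name = sqio.tile_filename(slide_name, ox, oy, kind="cells")
        sqio.write_rgb_tile(section.tile, out / tile_name)
        sqio.write_class_mask(section.tissue, out / tissue_name)
        sqio.write_class_mask(section.cells, out / cells_name)
        gt = section.ground_truth
        rows.append({
            "tile": tile_name, "tissue_mask": tissue_name,
            "cell_mask": cells_name, "seed": p.seed,
            "width": p.width, "height": p.height,
            "n_cells": p.n_cells, "positive_fraction": p.positive_fraction,
            "staining_pattern": p.staining_pattern,
            "artefact_count": p.artefact_count, "noise_std": p.noise_std,
            "n_pos_epi": gt.n_pos_epi, "n_neg_epi": gt.n_neg_epi,
            "n_pos_derm": gt.n_pos_derm, "n_neg_derm": gt.n_neg_derm,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
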