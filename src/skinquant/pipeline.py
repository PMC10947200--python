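"""End-to-end pipeline: preprocess -> segment tissue -> segment cells
-> post-process -> quantify.

The pipeline runs per section image: the tissue model labels
epidermis/dermis/artefact/background, the cell model labels
positive/negative cell structures, an adaptive threshold on the
grayscale image recovers strongly stained (DAB-dark) pixels, the cell
and stain masks are fused, noise objects are removed, clustered cells
are watershed-split, and instances are counted per compartment.

The stain threshold uses a larger offset (default 60 levels below the
local mean) than generic dark-object detection: DAB chromogen is far
darker than the haematoxylin counterstain, and the offset is chosen to
sit between the two so the stain mask marks DAB without promoting
counterstained (negative) nuclei.

Every run writes into a fresh run directory: quantification CSV, the
per-section class masks, a Figure-style colour overlay (epidermis red,
positive cells inside the epidermis purple, negative inside blue,
positive outside cyan, negative outside yellow), the effective config
and a log.  Inputs are never modified.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import io as sqio
from .postprocess import (
    apply_exclusion,
    binarize_tissue,
    extract_polarity,
    fuse_cell_masks,
    remove_small_objects,
    split_instances,
)
from .preprocess import adaptive_threshold, default_window, to_grayscale
from .quantify import assign_compartment, quantify_section
from .segmentation import (
    ColorRuleOracle,
    PixelClassifierBackend,
    SegmentationBackend,
    segment_slide,
)
from .tiling import tile_grid
from .types import (
    BinaryMask,
    CellMask,
    ConfigurationError,
    RgbTile,
    SectionQuant,
    TissueMask,
)

logger = logging.getLogger("skinquant")

OVERLAY_COLORS = {
    "epidermis": (255, 0, 0),        # red
    "pos_in_epi": (128, 0, 128),     # purple
    "neg_in_epi": (0, 0, 255),       # blue
    "pos_outside": (0, 255, 255),    # cyan
    "neg_outside": (255, 255, 0),    # yellow
    "other": (255, 255, 255),
}

#: Default stain-mask offset (levels below local mean); sits between
#: DAB darkness and haematoxylin counterstain darkness.
DEFAULT_STAIN_OFFSET = 60


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run."""

    input_dir: str = "."
    out_dir: str = "runs"
    tissue_model: str = "oracle"   # "oracle" or a checkpoint directory
    cell_model: str = "oracle"
    tissue_tile_size: int = 700
    cell_tile_size: int = 300
    background_luminance: float = 240.0
    max_background_fraction: float = 0.95
    stain_window: Optional[int] = None   # default: odd ~ cell_tile_size/8
    stain_offset: float = DEFAULT_STAIN_OFFSET
    max_noise_area: int = 100
    min_seed_distance: int = 5
    epidermis_codes: tuple[int, ...] = (1,)
    upper_dermis_band: Optional[int] = None
    exclusion_suffix: str = "_exclude.png"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)}"
            )
        if "epidermis_codes" in data:
            data["epidermis_codes"] = tuple(data["epidermis_codes"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["epidermis_codes"] = list(d["epidermis_codes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_model(spec: str, task: str) -> SegmentationBackend:
    """Resolve a model spec: ``"oracle"`` or a checkpoint directory."""
    if spec == "oracle":
        return ColorRuleOracle(task)
    path = Path(spec)
    if not path.exists():
        raise ConfigurationError(
            f"{task} model stage: checkpoint path '{spec}' does not exist"
        )
    model = PixelClassifierBackend.load(path)
    if model.task != task:
        raise ConfigurationError(
            f"{task} model stage: checkpoint at '{spec}' was trained for "
            f"task '{model.task}'"
        )
    return model


@dataclass
class SectionResult:
    """All per-section artifacts produced by :func:`process_section`."""

    quant: SectionQuant
    tissue: TissueMask
    cells: CellMask
    epidermis: BinaryMask
    combined: np.ndarray
    pos_instances: np.ndarray
    neg_instances: np.ndarray
    overlay: np.ndarray = field(repr=False, default=None)


def process_section(image: np.ndarray,
                    tissue_model: SegmentationBackend,
                    cell_model: SegmentationBackend,
                    config: Optional[PipelineConfig] = None,
                    exclusion: Optional[BinaryMask] = None) -> SectionResult:
    """Run the full analysis chain on one section image (H x W x 3)."""
    cfg = config or PipelineConfig()
    image = np.asarray(image)
    h, w = image.shape[:2]

    tgrid = tile_grid(w, h, cfg.tissue_tile_size)
    cgrid = tile_grid(w, h, cfg.cell_tile_size)
    t0 = time.perf_counter()
    tissue_codes = segment_slide(tissue_model, image, tgrid,
                                 background_luminance=cfg.background_luminance,
                                 max_background_fraction=cfg.max_background_fraction)
    cell_codes = segment_slide(cell_model, image, cgrid,
                               background_luminance=cfg.background_luminance,
                               max_background_fraction=cfg.max_background_fraction)
    logger.info("segmentation done in %.2f s", time.perf_counter() - t0)

    tissue = TissueMask(tissue_codes)
    cells = CellMask(cell_codes)
    epidermis = binarize_tissue(tissue, frozenset(cfg.epidermis_codes))

    gray = to_grayscale(RgbTile(pixels=image))
    window = cfg.stain_window or default_window(cfg.cell_tile_size)
    stain = adaptive_threshold(gray, window=window, offset=cfg.stain_offset)

    combined = fuse_cell_masks(cells, stain)
    combined = remove_small_objects(combined, cfg.max_noise_area)
    combined = apply_exclusion(combined, exclusion)

    pos = split_instances(extract_polarity(combined, 1),
                          cfg.min_seed_distance, polarity=1)
    neg = split_instances(extract_polarity(combined, 2),
                          cfg.min_seed_distance, polarity=2)

    quant = quantify_section(pos, neg, epidermis, gray,
                             upper_dermis_band=cfg.upper_dermis_band)
    overlay = make_overlay(epidermis, pos, neg)
    return SectionResult(quant=quant, tissue=tissue, cells=cells,
                         epidermis=epidermis, combined=combined.values,
                         pos_instances=pos.labels, neg_instances=neg.labels,
                         overlay=overlay)


def make_overlay(epidermis: BinaryMask, pos, neg) -> np.ndarray:
    """Colour overlay using the standard output colour map."""
    h, w = epidermis.shape
    out = np.full((h, w, 3), OVERLAY_COLORS["other"], dtype=np.uint8)
    out[epidermis.values == 1] = OVERLAY_COLORS["epidermis"]
    for inst, key_in, key_out in ((pos, "pos_in_epi", "pos_outside"),
                                  (neg, "neg_in_epi", "neg_outside")):
        flags = assign_compartment(inst, epidermis)
        for label in range(1, inst.n_instances + 1):
            key = key_in if flags[label - 1] else key_out
            out[inst.labels == label] = OVERLAY_COLORS[key]
    return out


def _find_section_images(input_dir: Path) -> list[Path]:
    skip_suffixes = ("_tissue", "_cells", "_exclude")
    files = []
    for p in sorted(input_dir.iterdir()):
        if p.suffix.lower() not in {".png", ".tif", ".tiff"}:
            continue
        if any(p.stem.endswith(s) for s in skip_suffixes):
            continue
        files.append(p)
    return files


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run the pipeline over every section image in ``config.input_dir``.

    Creates a fresh, timestamp-free run directory (``run-0001`` etc.)
    under ``config.out_dir`` and writes: ``quantification.csv``,
    per-section tissue/cell/combined masks, colour overlays,
    ``effective_config.yaml`` and ``run.log``.  Returns the
    quantification table.
    """
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise ConfigurationError(
            f"input stage: '{input_dir}' is not a directory"
        )
    sections = _find_section_images(input_dir)
    if not sections:
        raise ConfigurationError(
            f"input stage: no PNG/TIFF section images found in '{input_dir}'"
        )

    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    n = 1
    while (out_root / f"run-{n:04d}").exists():
        n += 1
    run_dir = out_root / f"run-{n:04d}"
    run_dir.mkdir()

    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config.to_yaml(run_dir / "effective_config.yaml")
        tissue_model = load_model(config.tissue_model, "tissue")
        cell_model = load_model(config.cell_model, "cells")
        logger.info("models loaded: tissue=%s cells=%s",
                    config.tissue_model, config.cell_model)

        rows = []
        for path in sections:
            tile = sqio.read_rgb_tile(path)
            exclusion = None
            excl_path = path.with_name(path.stem + config.exclusion_suffix)
            if excl_path.exists():
                raw = sqio._load_array(excl_path)
                exclusion = BinaryMask(values=(np.asarray(raw) > 0).astype(np.uint8),
                                       role="exclusion")
            logger.info("processing %s (%dx%d)", path.name,
                        tile.width, tile.height)
            res = process_section(tile.pixels, tissue_model, cell_model,
                                  config, exclusion=exclusion)
            stem = path.stem
            sqio.write_class_mask(res.tissue, run_dir / f"{stem}_tissue.png")
            sqio.write_class_mask(res.cells, run_dir / f"{stem}_cells.png")
            sqio.write_class_mask(res.combined,
                                  run_dir / f"{stem}_combined.png")
            sqio.write_rgb_tile(RgbTile(pixels=res.overlay),
                                run_dir / f"{stem}_overlay.png")
            q = res.quant
            rows.append({
                "section": stem,
                "n_pos_epi": q.n_pos_epi, "n_neg_epi": q.n_neg_epi,
                "n_pos_derm": q.n_pos_derm, "n_neg_derm": q.n_neg_derm,
                "pct_positive_epi": q.pct_positive_epi,
                "pct_positive_derm": q.pct_positive_derm,
                "avg_signal": q.avg_signal,
                "n_excluded": q.n_excluded,
            })
        table = pd.DataFrame(rows)
        table.to_csv(run_dir / "quantification.csv", index=False)
        logger.info("wrote %d section rows to %s", len(rows),
                    run_dir / "quantification.csv")
        return table
    finally:
        logger.removeHandler(handler)
        handler.close()
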