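"""Per-tile semantic segmentation with pluggable backends.

Two backends implement a common interface:

``ColorRuleOracle``
    Deterministic nearest-palette-colour classifier that inverts the
    synthetic generator's colour rules.  On noise-free synthetic tiles
    it reproduces the ground-truth masks exactly, which makes it the
    reference predictor for pipeline and validation-harness tests.

``PixelClassifierBackend``
    A trainable multi-scale pixel classifier: each pixel is described
    by its RGB values, Gaussian-smoothed colour at several scales
    (context analogous to dilated-convolution receptive fields) and
    local gradient magnitude, and classified by a small multi-layer
    perceptron.  Training subsamples pixels with balanced classes
    (countering the large background/epidermis imbalance), runs a fixed
    number of epochs, and is bit-reproducible given the seed.

Both backends predict a full class raster for a tile; predictions are
deterministic given fixed weights and input.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .preprocess import (
    ColorStats,
    normalize_color,
    specimen_present,
)
from .synthdata import SynthPalette
from .tiling import TileGrid, assemble_slide_mask
from .types import (
    CELL_CODES,
    TISSUE_CODES,
    CellMask,
    ConfigurationError,
    InvalidArgumentError,
    RgbTile,
    TissueMask,
)

TASK_CODES = {"tissue": TISSUE_CODES, "cells": CELL_CODES}
TASK_BACKGROUND = {"tissue": 4, "cells": 5}

# palette entry -> (tissue code or None for "fill from surroundings",
#                   cell code)
_PALETTE_SEMANTICS = {
    "background": (4, 5),
    "epidermis": (1, 5),
    "dermis": (2, 5),
    "artefact": (3, 5),
    "positive_nucleus": (None, 3),
    "negative_nucleus": (None, 4),
    "positive_cyto": (None, 1),
    "negative_cyto": (None, 2),
}


@dataclass
class TrainingPair:
    """A tile with its ground-truth mask for one segmentation task."""

    tile: RgbTile
    truth: Union[TissueMask, CellMask]

    def __post_init__(self) -> None:
        if self.tile.shape != self.truth.shape:
            raise InvalidArgumentError(
                f"tile shape {self.tile.shape} does not match truth shape "
                f"{self.truth.shape}"
            )


def _wrap_mask(codes: np.ndarray, task: str):
    return TissueMask(codes) if task == "tissue" else CellMask(codes)


class SegmentationBackend:
    """Interface: deterministic per-tile class prediction."""

    task: str

    def predict_codes(self, tile: RgbTile) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict_tile(self, tile: RgbTile):
        """Predict the class mask for one tile.

        Returns a :class:`TissueMask` or :class:`CellMask` matching the
        backend's task; output codes are restricted to the task
        vocabulary.
        """
        if self.task not in TASK_CODES:
            raise ConfigurationError(f"unknown task '{self.task}'")
        codes = self.predict_codes(tile)
        self.n_predict_calls = getattr(self, "n_predict_calls", 0) + 1
        return _wrap_mask(codes, self.task)


class ColorRuleOracle(SegmentationBackend):
    """Nearest-palette-colour segmentation of synthetic sections.

    Pixels matching a cell colour have no intrinsic tissue class; for
    the tissue task they inherit the class of the nearest non-cell
    pixel (cells are always embedded wholly inside one compartment).
    """

    def __init__(self, task: str, palette: Optional[SynthPalette] = None):
        if task not in TASK_CODES:
            raise ConfigurationError(f"unknown task '{task}'")
        self.task = task
        self.palette = palette or SynthPalette()
        self.n_predict_calls = 0
        entries = self.palette.as_dict()
        self._names = list(entries)
        self._colors = np.array([entries[n] for n in self._names], dtype=np.float64)

    def predict_codes(self, tile: RgbTile) -> np.ndarray:
        px = tile.pixels.astype(np.float64)
        d2 = ((px[:, :, None, :] - self._colors[None, None, :, :]) ** 2).sum(axis=3)
        nearest = d2.argmin(axis=2)
        if self.task == "cells":
            lut = np.array([_PALETTE_SEMANTICS[n][1] for n in self._names])
            return lut[nearest]
        tissue_lut = np.array([
            -1 if _PALETTE_SEMANTICS[n][0] is None else _PALETTE_SEMANTICS[n][0]
            for n in self._names
        ])
        codes = tissue_lut[nearest]
        cellpix = codes == -1
        if cellpix.any():
            if cellpix.all():
                return np.full_like(codes, TASK_BACKGROUND["tissue"])
            # inherit the tissue class of the nearest non-cell pixel
            _, (iy, ix) = ndimage.distance_transform_edt(
                cellpix, return_indices=True)
            codes = np.where(cellpix, codes[iy, ix], codes)
        return codes


@dataclass
class TrainConfig:
    """Training configuration for the pixel-classifier backend."""

    epochs: int = 15
    hidden_layers: tuple[int, ...] = (48, 24)
    learning_rate: float = 1e-3
    batch_size: int = 512
    #: Gaussian context scales (px); analogous to increasing dilation rates.
    feature_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    #: Per-class cap on training pixels (balanced subsampling).
    pixels_per_class: int = 12000
    seed: int = 0


def _pixel_features(pixels: np.ndarray, sigmas: Sequence[float]) -> np.ndarray:
    """Multi-scale per-pixel feature stack, shape (H, W, F)."""
    img = pixels.astype(np.float64) / 255.0
    feats = [img[:, :, c] for c in range(3)]
    for s in sigmas:
        for c in range(3):
            feats.append(ndimage.gaussian_filter(img[:, :, c], sigma=s,
                                                 mode="nearest"))
    gray = img.mean(axis=2)
    for s in (1.0, 2.0):
        feats.append(ndimage.gaussian_gradient_magnitude(gray, sigma=s,
                                                         mode="nearest"))
    return np.stack(feats, axis=2)


class PixelClassifierBackend(SegmentationBackend):
    """Trainable multi-scale pixel classifier (MLP head).

    Construct via :func:`train_model` or :meth:`load`.
    """

    def __init__(self, task: str, config: TrainConfig, mlp: MLPClassifier,
                 feature_mean: np.ndarray, feature_std: np.ndarray,
                 loss_curve: list[float]):
        if task not in TASK_CODES:
            raise ConfigurationError(f"unknown task '{task}'")
        self.task = task
        self.config = config
        self._mlp = mlp
        self._mean = feature_mean
        self._std = feature_std
        self.loss_curve = loss_curve
        self.n_predict_calls = 0

    def predict_codes(self, tile: RgbTile) -> np.ndarray:
        f = _pixel_features(tile.pixels, self.config.feature_sigmas)
        h, w, nf = f.shape
        x = (f.reshape(-1, nf) - self._mean) / self._std
        pred = self._mlp.predict(x)
        return pred.reshape(h, w).astype(np.int64)

    # -- checkpointing: JSON config + npz weights blob ------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = {
            "task": self.task,
            "epochs": self.config.epochs,
            "hidden_layers": list(self.config.hidden_layers),
            "learning_rate": self.config.learning_rate,
            "batch_size": self.config.batch_size,
            "feature_sigmas": list(self.config.feature_sigmas),
            "pixels_per_class": self.config.pixels_per_class,
            "seed": self.config.seed,
            "loss_curve": self.loss_curve,
        }
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        with open(d / "weights.pkl", "wb") as fh:
            pickle.dump({"mlp": self._mlp, "feature_mean": self._mean,
                         "feature_std": self._std}, fh)

    @classmethod
    def load(cls, directory) -> "PixelClassifierBackend":
        d = Path(directory)
        if not (d / "config.json").exists():
            raise ConfigurationError(
                f"model checkpoint '{d}' is missing config.json"
            )
        cfg = json.loads((d / "config.json").read_text())
        with open(d / "weights.pkl", "rb") as fh:
            blob = pickle.load(fh)
        config = TrainConfig(
            epochs=cfg["epochs"],
            hidden_layers=tuple(cfg["hidden_layers"]),
            learning_rate=cfg["learning_rate"],
            batch_size=cfg["batch_size"],
            feature_sigmas=tuple(cfg["feature_sigmas"]),
            pixels_per_class=cfg["pixels_per_class"],
            seed=cfg["seed"],
        )
        return cls(cfg["task"], config, blob["mlp"], blob["feature_mean"],
                   blob["feature_std"], cfg.get("loss_curve", []))


def train_model(pairs: Sequence[TrainingPair],
                config: Optional[TrainConfig] = None,
                task: Optional[str] = None) -> PixelClassifierBackend:
    """Train the pixel-classifier backend on tile/mask pairs.

    The task (tissue vs cells) is inferred from the truth mask types
    unless given explicitly.  Training pixels are subsampled with equal
    per-class caps, which implements inverse-frequency balancing of the
    heavily skewed class areas.  The per-epoch training loss is kept on
    the returned model (``loss_curve``) and decreases over training.
    """
    if len(pairs) == 0:
        raise InvalidArgumentError("training requires at least one tile/mask pair")
    config = config or TrainConfig()

    kinds = {type(p.truth) for p in pairs}
    if len(kinds) != 1:
        raise InvalidArgumentError("all training pairs must share one task")
    inferred = "tissue" if kinds == {TissueMask} else "cells"
    task = task or inferred
    if task != inferred:
        raise ConfigurationError(
            f"requested task '{task}' does not match mask type for "
            f"'{inferred}'"
        )

    rng = np.random.default_rng(config.seed)
    xs, ys = [], []
    for p in pairs:
        f = _pixel_features(p.tile.pixels, config.feature_sigmas)
        xs.append(f.reshape(-1, f.shape[2]))
        ys.append(p.truth.codes.reshape(-1))
    X = np.concatenate(xs, axis=0)
    y = np.concatenate(ys, axis=0)

    keep = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if idx.size > config.pixels_per_class:
            idx = rng.choice(idx, size=config.pixels_per_class, replace=False)
        keep.append(idx)
    sel = np.concatenate(keep)
    rng.shuffle(sel)
    X, y = X[sel], y[sel]

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-9] = 1.0
    Xn = (X - mean) / std

    mlp = MLPClassifier(
        hidden_layer_sizes=config.hidden_layers,
        learning_rate_init=config.learning_rate,
        batch_size=config.batch_size,
        max_iter=config.epochs,
        random_state=int(config.seed) % (2 ** 31),
        early_stopping=False,
        n_iter_no_change=config.epochs + 1,
        tol=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(Xn, y)
    return PixelClassifierBackend(task, config, mlp, mean, std,
                                  [float(v) for v in mlp.loss_curve_])


def segment_slide(model: SegmentationBackend, slide: np.ndarray,
                  grid: TileGrid,
                  reference_stats: Optional[ColorStats] = None,
                  background_luminance: float = 240,
                  max_background_fraction: float = 0.95) -> np.ndarray:
    """Segment a whole slide tile by tile and stitch the results.

    Tiles that fail the specimen-presence filter are emitted as
    all-background without invoking the model (the model's
    ``n_predict_calls`` counter is not incremented for them).  Remaining
    tiles are colour-normalized towards ``reference_stats`` when given,
    predicted, and stitched with last-writer-wins overlap handling.
    """
    slide = np.asarray(slide)
    if slide.shape[0] != grid.slide_height or slide.shape[1] != grid.slide_width:
        raise InvalidArgumentError(
            f"slide shape {slide.shape[:2]} does not match grid "
            f"({grid.slide_height}, {grid.slide_width})"
        )
    bg_code = TASK_BACKGROUND[model.task]
    tile_masks = []
    for win in grid.windows:
        crop = slide[win.y:win.y + win.height, win.x:win.x + win.width]
        tile = RgbTile(pixels=crop, origin_x=win.x, origin_y=win.y)
        if not specimen_present(tile, background_luminance,
                                max_background_fraction):
            tile_masks.append(np.full((win.height, win.width), bg_code,
                                      dtype=np.int64))
            continue
        if reference_stats is not None:
            tile = normalize_color(tile, reference_stats)
        tile_masks.append(model.predict_tile(tile).codes)
    return assemble_slide_mask(grid, tile_masks)
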