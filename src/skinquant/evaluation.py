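"""Segmentation validation harness.

Implements the five standard semantic-segmentation metrics on the
0-100 (%) scale — GlobalAccuracy, MeanAccuracy, MeanIoU, WeightedIoU
and the mean Boundary-F1 (contour-matching) score — plus repeated
random-split validation: the dataset is randomly partitioned into
train / test / left-out sets, a model is trained and evaluated per
run, and the per-run metric rows are tabulated together with their
arithmetic mean, flagging problems such as overfitting or selection
bias.

Accuracy/IoU metrics are pooled over the test set (one confusion
matrix across all test tiles); the BF score is computed per image and
averaged, matching its per-image normalization.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import (
    FoldReport,
    InvalidArgumentError,
    SegMetrics,
    SplitSpec,
    ValidationError,
)


def confusion_matrix(truth: np.ndarray, pred: np.ndarray,
                     classes: Sequence[int]) -> np.ndarray:
    """C x C pixel counts; entry (i, j) = truth class i predicted as j."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise InvalidArgumentError(
            f"truth shape {truth.shape} does not match pred shape {pred.shape}"
        )
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    for name, arr in (("truth", truth), ("pred", pred)):
        bad = ~np.isin(arr, classes)
        if bad.any():
            val = int(arr[np.nonzero(bad)][0])
            raise ValidationError(
                f"{name} contains value {val} outside classes {classes}"
            )
    t = np.vectorize(index.get, otypes=[np.int64])(truth.ravel())
    p = np.vectorize(index.get, otypes=[np.int64])(pred.ravel())
    c = len(classes)
    cm = np.bincount(t * c + p, minlength=c * c).reshape(c, c)
    return cm.astype(np.int64)


def class_boundaries(mask: np.ndarray, classes: Sequence[int]
                     ) -> dict[int, np.ndarray]:
    """Boundary pixel coordinates per class.

    A boundary pixel of class c has a 4-neighbour (inside the image) of
    a different class; the image border itself is not a boundary.
    Returns {class: (K, 2) array of (y, x)}.
    """
    mask = np.asarray(mask)
    out: dict[int, np.ndarray] = {}
    cross = ndimage.generate_binary_structure(2, 1)
    for c in classes:
        binary = mask == c
        if not binary.any():
            out[c] = np.zeros((0, 2), dtype=np.int64)
            continue
        eroded = ndimage.binary_erosion(binary, structure=cross,
                                        border_value=1)
        ys, xs = np.nonzero(binary & ~eroded)
        out[c] = np.stack([ys, xs], axis=1).astype(np.int64)
    return out


def bf_score(truth_boundary: np.ndarray, pred_boundary: np.ndarray,
             tolerance: float) -> float:
    """Boundary F1: harmonic mean of boundary precision and recall.

    Precision is the fraction of predicted boundary pixels within
    Euclidean ``tolerance`` of some true boundary pixel; recall is
    symmetric.  Two empty boundaries match vacuously (score 1); one
    empty boundary against a non-empty one scores 0.
    """
    if tolerance < 0:
        raise InvalidArgumentError("tolerance must be >= 0")
    tb = np.asarray(truth_boundary, dtype=np.float64).reshape(-1, 2)
    pb = np.asarray(pred_boundary, dtype=np.float64).reshape(-1, 2)
    if tb.shape[0] == 0 and pb.shape[0] == 0:
        return 1.0
    if tb.shape[0] == 0 or pb.shape[0] == 0:
        return 0.0
    truth_tree = cKDTree(tb)
    pred_tree = cKDTree(pb)
    d_pred, _ = truth_tree.query(pb)
    d_truth, _ = pred_tree.query(tb)
    precision = float((d_pred <= tolerance).mean())
    recall = float((d_truth <= tolerance).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def default_bf_tolerance(shape: tuple[int, int]) -> float:
    """Conventional BF tolerance: 0.75% of the image diagonal, rounded up."""
    diag = math.hypot(shape[0], shape[1])
    return float(math.ceil(0.0075 * diag))


def seg_metrics(cm: np.ndarray,
                truth_boundary_sets: Optional[dict[int, np.ndarray]] = None,
                pred_boundary_sets: Optional[dict[int, np.ndarray]] = None,
                tolerance: float = 2.0,
                classes: Optional[Sequence[int]] = None,
                bf_values: Optional[Sequence[float]] = None) -> SegMetrics:
    """The five segmentation metrics from a confusion matrix, in percent.

    ``bf_values`` may supply pre-averaged per-class BF scores (used by
    the repeated-validation harness, which averages BF per image);
    otherwise boundary sets are compared directly.  Classes absent from
    both truth and prediction are excluded from the class-averaged
    metrics.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise InvalidArgumentError("confusion matrix has no pixels")
    c = cm.shape[0]
    if classes is None:
        classes = list(range(c))

    tp = np.diag(cm)
    truth_count = cm.sum(axis=1)
    pred_count = cm.sum(axis=0)
    present = (truth_count + pred_count) > 0

    global_accuracy = tp.sum() / total

    acc = np.zeros(c)
    has_truth = truth_count > 0
    acc[has_truth] = tp[has_truth] / truth_count[has_truth]
    mean_accuracy = acc[present].mean()

    union = truth_count + pred_count - tp
    iou = np.zeros(c)
    nz = union > 0
    iou[nz] = tp[nz] / union[nz]
    mean_iou = iou[present].mean()

    weights = truth_count / total
    weighted_iou = float((weights * iou).sum())

    if bf_values is not None:
        mean_bf = float(np.mean(bf_values)) if len(bf_values) else 0.0
    elif truth_boundary_sets is not None and pred_boundary_sets is not None:
        scores = []
        for i, cls in enumerate(classes):
            if not present[i]:
                continue
            scores.append(bf_score(truth_boundary_sets.get(cls, ()),
                                   pred_boundary_sets.get(cls, ()),
                                   tolerance))
        mean_bf = float(np.mean(scores)) if scores else 0.0
    else:
        mean_bf = float("nan")

    return SegMetrics(
        global_accuracy=100.0 * float(global_accuracy),
        mean_accuracy=100.0 * float(mean_accuracy),
        mean_iou=100.0 * float(mean_iou),
        weighted_iou=100.0 * weighted_iou,
        mean_bf=100.0 * mean_bf,
    )


def evaluate_masks(truth: np.ndarray, pred: np.ndarray,
                   classes: Sequence[int],
                   tolerance: Optional[float] = None) -> SegMetrics:
    """Convenience: all five metrics for one truth/prediction pair."""
    truth = np.asarray(truth)
    if tolerance is None:
        tolerance = default_bf_tolerance(truth.shape)
    cm = confusion_matrix(truth, pred, classes)
    tb = class_boundaries(truth, classes)
    pb = class_boundaries(pred, classes)
    return seg_metrics(cm, tb, pb, tolerance, classes=classes)


def partition_dataset(n_items: int, fractions: Sequence[float], seed: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random train / test / left-out index sets.

    Sizes follow floor arithmetic with the left-out set absorbing the
    remainder: n_train = floor(n * f_train), n_test = floor(n * f_test),
    n_leftout = n - n_train - n_test.  Membership is uniformly random
    given the seed; the three sets are disjoint and exhaustive.
    """
    if n_items < 1:
        raise InvalidArgumentError("n_items must be >= 1")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise InvalidArgumentError(
            "fractions must be three positive values (train, test, left-out)"
        )
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidArgumentError(
            f"fractions must sum to 1, got {sum(fractions)!r}"
        )
    # epsilon guards against float noise, e.g. 560 * 0.7 == 391.99999999999994
    n_train = int(math.floor(n_items * fractions[0] + 1e-6))
    n_test = int(math.floor(n_items * fractions[1] + 1e-6))
    n_leftout = n_items - n_train - n_test
    if n_leftout < 0:
        raise InvalidArgumentError("fractions leave a negative remainder")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_items)
    return (np.sort(perm[:n_train]),
            np.sort(perm[n_train:n_train + n_test]),
            np.sort(perm[n_train + n_test:]))


def repeated_validation(dataset: Sequence, model_factory: Callable,
                        spec: SplitSpec, k: int = 10,
                        classes: Optional[Sequence[int]] = None,
                        tolerance: Optional[float] = None) -> FoldReport:
    """Repeated random-split validation of a segmentation model.

    Parameters
    ----------
    dataset : sequence of (tile, truth) pairs
        ``truth`` provides ``.codes`` (class masks) and ``tile`` is fed
        to the trained model's ``predict_tile``.
    model_factory : callable(train_pairs, seed) -> model
        Trains (or constructs) a model for one run.
    spec : SplitSpec
        Split fractions and the base seed; run r uses seed
        ``spec.seed + r``.
    k : int
        Number of repeated runs (>= 1).

    Returns
    -------
    FoldReport
        k metric rows plus their arithmetic-mean row.  Accuracy/IoU are
        pooled over the test tiles of each run; BF is averaged per
        image then over images.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if len(dataset) < 3:
        raise InvalidArgumentError("dataset must hold at least 3 items")
    if classes is None:
        codes = np.unique(np.concatenate(
            [np.unique(np.asarray(t.codes)) for _, t in dataset]))
        classes = [int(v) for v in codes]

    folds = []
    for r in range(k):
        run_seed = spec.seed + r
        train_idx, test_idx, _ = partition_dataset(
            len(dataset), spec.fractions, run_seed)
        train_pairs = [dataset[i] for i in train_idx]
        model = model_factory(train_pairs, run_seed)
        cm_total = None
        bf_per_image = []
        for i in test_idx:
            tile, truth = dataset[i]
            pred = model.predict_tile(tile).codes
            truth_codes = np.asarray(truth.codes)
            cm = confusion_matrix(truth_codes, pred, classes)
            cm_total = cm if cm_total is None else cm_total + cm
            tol = (default_bf_tolerance(truth_codes.shape)
                   if tolerance is None else tolerance)
            tb = class_boundaries(truth_codes, classes)
            pb = class_boundaries(pred, classes)
            present = [c for j, c in enumerate(classes)
                       if (cm.sum(axis=1)[j] + cm.sum(axis=0)[j]) > 0]
            scores = [bf_score(tb[c], pb[c], tol) for c in present]
            bf_per_image.append(float(np.mean(scores)) if scores else 1.0)
        folds.append(seg_metrics(cm_total, classes=classes,
                                 bf_values=[np.mean(bf_per_image)]))

    avg = SegMetrics(
        global_accuracy=float(np.mean([f.global_accuracy for f in folds])),
        mean_accuracy=float(np.mean([f.mean_accuracy for f in folds])),
        mean_iou=float(np.mean([f.mean_iou for f in folds])),
        weighted_iou=float(np.mean([f.weighted_iou for f in folds])),
        mean_bf=float(np.mean([f.mean_bf for f in folds])),
    )
    return FoldReport(folds=folds, average=avg)
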