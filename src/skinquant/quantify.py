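"""Compartment-aware quantification of positive/negative cells.

Endpoints mirror standard IHC reporting: per-compartment instance
counts, percent positive cells 100*pos/(pos+neg) and the average stain
signal, defined here as the mean stain darkness (255 - grayscale
luminance) over all pixels of positive-cell instances.  A compartment
with no cells yields an *undefined* percentage, reported as missing and
never as zero.

Compartment membership of an instance is decided by its centroid
pixel: inside the epidermis mask -> epidermal, otherwise dermal
(everything outside the epidermis).  An optional band-depth parameter
restricts "dermal" to a literal upper-dermis band of the given depth
below the epidermis.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    BinaryMask,
    InstanceLabels,
    InvalidArgumentError,
    SectionQuant,
    ValidationError,
)

ENDPOINTS = ("n_pos_epi", "n_neg_epi", "n_pos_derm", "n_neg_derm",
             "pct_positive_epi", "pct_positive_derm", "avg_signal")


def assign_compartment(instances: InstanceLabels,
                       epidermis: BinaryMask) -> np.ndarray:
    """Per-instance compartment flags: True = epidermal, False = dermal.

    An instance is epidermal iff its centroid pixel (rounded to the
    nearest raster position) lies inside the epidermis mask.  Returns a
    boolean array of length ``n_instances`` (index i-1 for label i).
    """
    if instances.shape != epidermis.shape:
        raise InvalidArgumentError(
            f"instance raster shape {instances.shape} does not match "
            f"epidermis mask shape {epidermis.shape}"
        )
    n = instances.n_instances
    if n == 0:
        return np.zeros(0, dtype=bool)
    centroids = ndimage.center_of_mass(
        np.ones(instances.shape), instances.labels, index=range(1, n + 1))
    flags = np.zeros(n, dtype=bool)
    h, w = epidermis.shape
    for i, (cy, cx) in enumerate(centroids):
        y = min(max(int(round(cy)), 0), h - 1)
        x = min(max(int(round(cx)), 0), w - 1)
        flags[i] = bool(epidermis.values[y, x])
    return flags


def _upper_dermis_mask(epidermis: BinaryMask, band_depth: int) -> np.ndarray:
    """Pixels within ``band_depth`` px below/around the epidermis."""
    dist = ndimage.distance_transform_edt(epidermis.values == 0)
    return (dist > 0) & (dist <= band_depth)


def quantify_section(pos: InstanceLabels, neg: InstanceLabels,
                     epidermis: BinaryMask, gray: np.ndarray,
                     exclusion: Optional[BinaryMask] = None,
                     upper_dermis_band: Optional[int] = None) -> SectionQuant:
    """Count instances per compartment and compute the section endpoints.

    Parameters
    ----------
    pos, neg : InstanceLabels
        Watershed-split positive and negative cell instances; their
        pixel supports must be disjoint.
    epidermis : BinaryMask
        Binary epidermis compartment.
    gray : ndarray
        Grayscale luminance of the (un-normalized) section, for the
        average-signal endpoint.
    exclusion : BinaryMask, optional
        Instances overlapping any nonzero exclusion pixel are dropped
        and counted in ``n_excluded``.
    upper_dermis_band : int, optional
        When given, dermal instances whose centroid is farther than
        this many pixels from the epidermis are dropped (literal
        upper-dermis reading) and counted in ``n_excluded``.
    """
    gray = np.asarray(gray)
    for name, arr in (("pos", pos), ("neg", neg)):
        if arr.shape != epidermis.shape:
            raise InvalidArgumentError(f"{name} instance shape mismatch")
    if gray.shape != epidermis.shape:
        raise InvalidArgumentError("gray raster shape mismatch")
    overlap = (pos.labels > 0) & (neg.labels > 0)
    if overlap.any():
        ys, xs = np.nonzero(overlap)
        raise ValidationError(
            f"positive and negative instances overlap at "
            f"(y={int(ys[0])}, x={int(xs[0])})"
        )

    band = None
    if upper_dermis_band is not None:
        band = _upper_dermis_mask(epidermis, upper_dermis_band)

    def survey(instances: InstanceLabels):
        n = instances.n_instances
        keep = np.ones(n, dtype=bool)
        if exclusion is not None and n > 0:
            excluded_labels = np.unique(
                instances.labels[(instances.labels > 0)
                                 & (exclusion.values > 0)])
            keep[excluded_labels - 1] = False
        epi_flags = assign_compartment(instances, epidermis)
        if band is not None and n > 0:
            centroids = ndimage.center_of_mass(
                np.ones(instances.shape), instances.labels,
                index=range(1, n + 1))
            h, w = epidermis.shape
            for i, (cy, cx) in enumerate(centroids):
                if epi_flags[i]:
                    continue
                y = min(max(int(round(cy)), 0), h - 1)
                x = min(max(int(round(cx)), 0), w - 1)
                if not band[y, x]:
                    keep[i] = False
        n_epi = int((keep & epi_flags).sum())
        n_derm = int((keep & ~epi_flags).sum())
        n_dropped = int((~keep).sum())
        kept_labels = np.nonzero(keep)[0] + 1
        return n_epi, n_derm, n_dropped, kept_labels

    pos_epi, pos_derm, pos_dropped, pos_kept = survey(pos)
    neg_epi, neg_derm, neg_dropped, neg_kept = survey(neg)

    def pct(p, n):
        return 100.0 * p / (p + n) if (p + n) > 0 else None

    pos_pixels = np.isin(pos.labels, pos_kept) & (pos.labels > 0)
    if pos_pixels.any():
        avg_signal = float(np.mean(255.0 - gray[pos_pixels].astype(np.float64)))
    else:
        avg_signal = None

    return SectionQuant(
        n_pos_epi=pos_epi, n_neg_epi=neg_epi,
        n_pos_derm=pos_derm, n_neg_derm=neg_derm,
        pct_positive_epi=pct(pos_epi, neg_epi),
        pct_positive_derm=pct(pos_derm, neg_derm),
        avg_signal=avg_signal,
        n_excluded=pos_dropped + neg_dropped,
    )


def aggregate_sections(quants: Sequence[SectionQuant],
                       group_labels: Optional[Sequence[str]] = None
                       ) -> pd.DataFrame:
    """Median and interquartile range of each endpoint per group.

    Percentiles use linear interpolation.  Undefined endpoints are
    excluded from the order statistics; their count is reported in
    ``n_excluded``.  Returns a tidy frame with one row per
    (group, endpoint).
    """
    if len(quants) == 0:
        raise InvalidArgumentError("aggregate_sections requires >= 1 section")
    if group_labels is None:
        group_labels = ["all"] * len(quants)
    if len(group_labels) != len(quants):
        raise InvalidArgumentError("one group label per section required")

    rows = []
    frame = pd.DataFrame([
        {"group": g, **{e: getattr(q, e) for e in ENDPOINTS}}
        for g, q in zip(group_labels, quants)
    ])
    for group, sub in frame.groupby("group", sort=False):
        for endpoint in ENDPOINTS:
            vals = sub[endpoint].dropna().astype(float).to_numpy()
            n_excl = int(sub[endpoint].isna().sum())
            if vals.size:
                med = float(np.percentile(vals, 50))
                q25 = float(np.percentile(vals, 25))
                q75 = float(np.percentile(vals, 75))
            else:
                med = q25 = q75 = float("nan")
            rows.append({
                "group": group, "endpoint": endpoint, "n": int(vals.size),
                "median": med, "q25": q25, "q75": q75,
                "n_excluded": n_excl,
                "all_undefined": vals.size == 0,
            })
    return pd.DataFrame(rows)
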