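"""Image quantification for scratch-wound and colocalization assays.

Mirrors a standard ImageJ workflow on three-channel fluorescence fields
(nuclear stain, transduction reporter, EdU): auto-threshold each channel,
colocalize by pixel-wise AND, count nuclei as connected components, and
report transduction efficiency and proliferation percentages. Wound closure
is computed from cell-free areas of a confluent-monolayer mask series as
((Area_t0 - Area_t) / Area_t0) * 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

#: default minimum particle area in px for nucleus counting
MIN_PARTICLE_PX = 20


@dataclass
class ChannelField:
    """Registered multi-channel field: channel name -> 2-D intensity array."""

    channels: Dict[str, np.ndarray]
    timepoint: float | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, img in self.channels.items():
            if not np.isfinite(np.asarray(img, dtype=float)).all():
                raise ValueError(f"non-finite intensities in channel {name!r}")


@dataclass
class ParticleSet:
    """Connected components of a binary mask surviving the size gate."""

    labels: np.ndarray
    areas: np.ndarray
    centroids: np.ndarray

    @property
    def count(self) -> int:
        return len(self.areas)


def wound_closure_pct(series: Mapping[float, float], t: float) -> float:
    """Percent wound closure at time ``t``: ((A0 - At) / A0) * 100.

    ``series`` maps timepoint (h) to wound area; time 0 must be present with
    positive area. Negative closure (wound growth) is allowed but flagged
    with a warning.
    """
    if 0 not in series and 0.0 not in series:
        raise KeyError("wound series has no t0 (time 0) entry")
    a0 = float(series[0 if 0 in series else 0.0])
    if a0 <= 0:
        raise ValueError("t0 wound area must be positive")
    if t not in series:
        raise KeyError(f"timepoint {t!r} not in wound series")
    pct = (a0 - float(series[t])) / a0 * 100.0
    if pct < 0:
        warnings.warn(f"negative wound closure at t={t}: wound grew")
    return pct


def threshold_channel(
    img: np.ndarray,
    method: str = "otsu",
    fixed: float | None = None,
    invert: bool = False,
    allow_constant: bool = False,
) -> np.ndarray:
    """Binary foreground mask of an intensity image.

    ``method="otsu"`` uses Otsu's threshold; ``method="fixed"`` uses the
    ``fixed`` value. Foreground is strictly above the threshold (below it
    with ``invert=True``, for inverted-polarity images). A constant image has
    no threshold and raises, unless ``allow_constant`` is set, in which case
    an all-False mask is returned (no signal).
    """
    img = np.asarray(img)
    if img.min() == img.max():
        if allow_constant:
            return np.zeros(img.shape, dtype=bool)
        raise ValueError("constant image: no threshold exists")
    if method == "otsu":
        thr = threshold_otsu(img)
    elif method == "fixed":
        if fixed is None:
            raise ValueError("fixed threshold requested but no value given")
        thr = fixed
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (img < thr) if invert else (img > thr)


def colocalize(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise AND of binary masks (the Image Calculator AND operation)."""
    if not masks:
        raise ValueError("need at least one mask")
    out = np.asarray(masks[0], dtype=bool)
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError("mask shapes differ")
        out = out & m
    return out


def count_particles(mask: np.ndarray, min_size_px: int = MIN_PARTICLE_PX) -> ParticleSet:
    """8-connected components of a binary mask with area >= min_size_px."""
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    keep = [p for p in props if p.area >= min_size_px]
    out_labels = np.zeros_like(labels)
    for new, p in enumerate(keep, start=1):
        out_labels[labels == p.label] = new
    areas = np.array([p.area for p in keep], dtype=int)
    cents = np.array([p.centroid for p in keep]) if keep else np.empty((0, 2))
    return ParticleSet(labels=out_labels, areas=areas, centroids=cents)


def _channel_masks(field: ChannelField, names: Sequence[str]) -> Dict[str, np.ndarray]:
    masks = {}
    for name in names:
        if name not in field.channels:
            raise KeyError(f"channel {name!r} missing from field")
        masks[name] = threshold_channel(field.channels[name], allow_constant=True)
    return masks


def transduction_efficiency(
    field: ChannelField, min_size_px: int = MIN_PARTICLE_PX
) -> float:
    """Percent of nuclear-stain particles also positive for the reporter.

    100 * (particles in nuclear AND reporter mask) / (particles in nuclear
    mask), following the threshold -> colocalize -> count-particles recipe.
    """
    masks = _channel_masks(field, ["nuclear", "reporter"])
    n_all = count_particles(masks["nuclear"], min_size_px).count
    if n_all == 0:
        raise ValueError("no nuclei detected")
    n_co = count_particles(
        colocalize([masks["nuclear"], masks["reporter"]]), min_size_px
    ).count
    return 100.0 * n_co / n_all


def proliferation_fraction(
    field: ChannelField,
    population: str = "transduced",
    min_size_px: int = MIN_PARTICLE_PX,
) -> float:
    """Percent of EdU-positive nuclei within a population.

    ``population="transduced"``: triple-colocalized (nuclear AND reporter AND
    edu) particles over nuclear-AND-reporter particles. ``"untransduced"``:
    nuclear AND edu AND NOT-reporter particles over all nuclear particles
    (i.e. reported as a percentage of all cells).
    """
    masks = _channel_masks(field, ["nuclear", "reporter", "edu"])
    if population == "transduced":
        denom = count_particles(
            colocalize([masks["nuclear"], masks["reporter"]]), min_size_px
        ).count
        if denom == 0:
            raise ValueError("no transduced nuclei: denominator empty")
        num = count_particles(
            colocalize([masks["nuclear"], masks["reporter"], masks["edu"]]),
            min_size_px,
        ).count
        return 100.0 * num / denom
    elif population == "untransduced":
        denom = count_particles(masks["nuclear"], min_size_px).count
        if denom == 0:
            raise ValueError("no nuclei detected")
        n_untrans = count_particles(
            colocalize([masks["nuclear"], ~masks["reporter"]]), min_size_px
        ).count
        if n_untrans == 0:
            warnings.warn("no untransduced nuclei present; returning 0")
        num = count_particles(
            colocalize([masks["nuclear"], masks["edu"], ~masks["reporter"]]),
            min_size_px,
        ).count
        return 100.0 * num / denom
    raise ValueError("population must be 'transduced' or 'untransduced'")


def wound_area_from_mask(
    cell_mask: np.ndarray,
    roi: tuple[float, float, float] | np.ndarray,
) -> float:
    """Cell-free wound area (px) inside/overlapping the t0 ROI.

    ``roi`` is either a boolean mask or a circle ``(cy, cx, r)``. The wound is
    the largest connected background (cell-free) component overlapping the
    ROI; its full pixel area is returned. A fully confluent mask returns 0.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if isinstance(roi, np.ndarray):
        roi_mask = np.asarray(roi, dtype=bool)
        if roi_mask.shape != cell_mask.shape:
            raise ValueError("ROI mask shape differs from cell mask")
    else:
        cy, cx, r = roi
        h, w = cell_mask.shape
        if not (0 <= cy < h and 0 <= cx < w):
            raise ValueError("ROI center outside image")
        yy, xx = np.ogrid[:h, :w]
        roi_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if not roi_mask.any():
        raise ValueError("empty ROI")
    bg = measure.label(~cell_mask, connectivity=2)
    overlap_labels = np.unique(bg[roi_mask])
    overlap_labels = overlap_labels[overlap_labels > 0]
    if overlap_labels.size == 0:
        return 0.0
    sizes = [(bg == lab).sum() for lab in overlap_labels]
    return float(max(sizes))


def wound_series_from_images(
    images: Mapping[float, np.ndarray],
    roi: tuple[float, float, float] | np.ndarray,
) -> pd.Series:
    """Wound areas per timepoint from confluent-monolayer intensity images.

    Each image is Otsu-thresholded to a cell mask; the cell-free area within
    the t0 ROI is measured by :func:`wound_area_from_mask`.
    """
    areas = {}
    for t, img in images.items():
        mask = threshold_channel(img)
        areas[float(t)] = wound_area_from_mask(mask, roi)
    return pd.Series(areas).sort_index()
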