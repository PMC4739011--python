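"""Lesion segmentation by seeded region growing of the background.

Dermoscopic framing guarantees two things after preprocessing: the healthy
skin is roughly homogeneous and it completely surrounds the lesion. The
segmenter therefore grows the *background* from a corner seed — merging
4-connected neighbors whose intensity stays within a tolerance of the
running region mean — and takes the complement as the lesion.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops


class SegmentationError(RuntimeError):
    """Raised when no lesion can be extracted (e.g. background fills the image)."""


@dataclass
class LesionMask:
    """Binary lesion mask with geometry derived from image moments.

    ``major_axis``/``minor_axis`` are the lengths of the second-moment
    ellipse axes; ``orientation`` is the major-axis angle in radians
    (counter-clockwise from the positive column axis, as in
    ``skimage.measure.regionprops``).
    """

    pixels: np.ndarray
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # top, left, height, width
    area_px: int
    major_axis: float
    minor_axis: float
    orientation: float

    @classmethod
    def from_array(cls, mask: np.ndarray) -> "LesionMask":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise SegmentationError("empty lesion mask")
        props = regionprops(mask.astype(np.uint8))[0]
        top, left, bottom, right = props.bbox
        return cls(
            pixels=mask,
            centroid=tuple(props.centroid),
            bbox=(top, left, bottom - top, right - left),
            area_px=int(mask.sum()),
            major_axis=props.axis_major_length,
            minor_axis=props.axis_minor_length,
            orientation=props.orientation,
        )


def grow_background(
    img: np.ndarray, tolerance: float | None = None, seeds: list[tuple[int, int]] | None = None
) -> np.ndarray:
    """Grow the healthy-skin region from a corner seed.

    Starting at ``(0, 0)`` (or each seed in ``seeds``), 4-connected
    neighbors are merged whenever ``|pixel - region_mean| <= tolerance``;
    the region mean is updated after every merge and growth stops when the
    frontier is exhausted. Default tolerance is 10% of the image intensity
    range.

    Returns the boolean background mask.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("grow_background expects a 2-D grayscale image")
    rng = float(img.max() - img.min())
    if tolerance is None:
        tolerance = 0.1 * rng if rng > 0 else 0.0
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    if seeds is None:
        seeds = [(0, 0)]

    h, w = img.shape
    mask = np.zeros((h, w), dtype=bool)
    flat = img.ravel()
    total = 0.0
    count = 0
    queue: deque[int] = deque()
    for r, c in seeds:
        idx = r * w + c
        if not mask.flat[idx]:
            mask.flat[idx] = True
            total += flat[idx]
            count += 1
            queue.append(idx)

    mflat = mask.ravel()
    while queue:
        idx = queue.popleft()
        r, c = divmod(idx, w)
        for nidx in (
            idx - w if r > 0 else -1,
            idx + w if r < h - 1 else -1,
            idx - 1 if c > 0 else -1,
            idx + 1 if c < w - 1 else -1,
        ):
            if nidx < 0 or mflat[nidx]:
                continue
            if abs(flat[nidx] - total / count) <= tolerance:
                mflat[nidx] = True
                total += flat[nidx]
                count += 1
                queue.append(nidx)
    return mask


def mask_from_background(
    bg: np.ndarray, fill_holes: bool = True, keep_largest: bool = True
) -> LesionMask:
    """Complement the grown background into a single lesion mask.

    Holes inside the lesion (pixels neither background nor lesion-connected)
    are filled and, if several disjoint foreground components remain, only
    the largest is kept, so the result is one connected lesion.
    """
    bg = np.asarray(bg, dtype=bool)
    lesion = ~bg
    if not lesion.any():
        raise SegmentationError("background covers the whole image; no lesion found")
    if keep_largest:
        labels = cc_label(lesion, connectivity=1)
        if labels.max() > 1:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            lesion = labels == int(sizes.argmax())
    if fill_holes:
        lesion = ndimage.binary_fill_holes(lesion)
    return LesionMask.from_array(lesion)


def border_error(pred: LesionMask | np.ndarray, truth: LesionMask | np.ndarray) -> float:
    """Segmentation border error: XOR area divided by true lesion area.

    0 for identical masks; 1.0 when the prediction is empty; may exceed 1
    for gross over-segmentation.
    """
    p = pred.pixels if isinstance(pred, LesionMask) else np.asarray(pred, dtype=bool)
    t = truth.pixels if isinstance(truth, LesionMask) else np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    t_area = int(t.sum())
    if t_area == 0:
        raise ValueError("ground-truth mask is empty")
    return float(np.logical_xor(p, t).sum()) / t_area


def segment_lesion(img: np.ndarray, tolerance: float | None = None, **kwargs) -> LesionMask:
    """Convenience wrapper: grow background from the corner, complement."""
    return mask_from_background(grow_background(img, tolerance), **kwargs)
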