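"""Nucleus segmentation: IsoData thresholding, distance-transform watershed,
and size/border filtering of the resulting segments.

The threshold is the classic iterative intermeans (Ridler-Calvard / IsoData)
rule computed on the 256-bin histogram; the watershed splits touching nuclei
using seeds found as smoothed local maxima of the Euclidean distance
transform. Filtering keeps segments whose area lies in an inclusive pixel
window (default [15, 230]) and, optionally, discards any segment touching
the image border so partial nuclei are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import ParameterError

#: Inclusive nucleus/marker segment area window, in pixels.
MIN_SEGMENT_AREA = 15
MAX_SEGMENT_AREA = 230

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class BinaryMask:
    """Thresholded image: ``mask`` is True exactly where pixel > threshold."""

    mask: np.ndarray
    threshold_value: int


@dataclass
class NucleusSegment:
    """One labeled nucleus region after watershed."""

    label: int
    coords: np.ndarray  # (n, 2) array of (row, col) pixel coordinates
    area_px: int
    centroid: tuple[float, float]
    touches_border: bool


def isodata_threshold(image: np.ndarray, *, min_contrast: float = 0.0) -> BinaryMask:
    """Threshold an 8-bit image by iterative intermeans on its histogram.

    Iterates ``t <- (mean(pixels <= t) + mean(pixels > t)) / 2`` (integer
    bins) to a fixed point. A constant image yields an empty mask with the
    constant as threshold. If ``min_contrast`` > 0 and the converged class
    means differ by less than it, the image is treated as having no
    foreground (guards against thresholding pure noise).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ParameterError("empty image")
    if image.dtype != np.uint8:
        raise ParameterError(f"expected uint8 image, got {image.dtype}")

    hist = np.bincount(image.ravel(), minlength=256).astype(np.float64)
    bins = np.arange(256, dtype=np.float64)
    nonzero = np.nonzero(hist)[0]
    if len(nonzero) == 1:  # constant image: no foreground
        t = int(nonzero[0])
        return BinaryMask(mask=np.zeros(image.shape, dtype=bool), threshold_value=t)

    csum = np.cumsum(hist)
    cmoment = np.cumsum(hist * bins)
    total, total_moment = csum[-1], cmoment[-1]

    t = int(total_moment / total)  # start at the global mean
    seen = set()
    while t not in seen:
        seen.add(t)
        n0 = csum[t]
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            break
        m0 = cmoment[t] / n0
        m1 = (total_moment - cmoment[t]) / n1
        t = int((m0 + m1) / 2.0)

    n0 = csum[t]
    n1 = total - n0
    if n0 > 0 and n1 > 0 and min_contrast > 0:
        m0 = cmoment[t] / n0
        m1 = (total_moment - cmoment[t]) / n1
        if (m1 - m0) < min_contrast:
            return BinaryMask(mask=np.zeros(image.shape, dtype=bool), threshold_value=t)
    return BinaryMask(mask=image > t, threshold_value=t)


def watershed_nuclei(
    mask: BinaryMask | np.ndarray,
    *,
    min_seed_distance: int = 5,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Split touching nuclei in a binary mask into labeled regions.

    Seeds are local maxima of the Gaussian-smoothed Euclidean distance
    transform, at least ``min_seed_distance`` pixels apart; the seeded
    watershed runs on the negated distance map restricted to the foreground.
    The output labels cover exactly the foreground pixels (components left
    without a seed are labeled as single regions).
    """
    fg = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    labels = np.zeros(fg.shape, dtype=np.int32)
    if not fg.any():
        return labels

    dist = ndi.distance_transform_edt(fg)
    smoothed = ndi.gaussian_filter(dist, sigma=smooth_sigma) if smooth_sigma > 0 else dist
    peak_coords = peak_local_max(
        smoothed, min_distance=min_seed_distance, labels=fg, exclude_border=False
    )
    seeds = np.zeros(fg.shape, dtype=bool)
    seeds[tuple(peak_coords.T)] = True
    markers, n_seeds = ndi.label(seeds, structure=_STRUCT8)
    if n_seeds > 0:
        labels = watershed(-smoothed, markers=markers, mask=fg, connectivity=2)

    missed = fg & (labels == 0)
    if missed.any():
        extra, n_extra = ndi.label(missed, structure=_STRUCT8)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0).astype(labels.dtype)
    return labels


def filter_segments(
    labels: np.ndarray,
    min_area: int = MIN_SEGMENT_AREA,
    max_area: int = MAX_SEGMENT_AREA,
    exclude_border: bool = True,
) -> list[NucleusSegment]:
    """Apply the inclusive size window and border exclusion to labeled nuclei.

    Returns the retained segments; their count is the field's nucleus count.
    """
    if min_area > max_area:
        raise ParameterError(f"min_area {min_area} > max_area {max_area}")
    h, w = labels.shape
    segments: list[NucleusSegment] = []
    for prop in regionprops(labels):
        area = int(prop.area)
        r0, c0, r1, c1 = prop.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        if area < min_area or area > max_area:
            continue
        if exclude_border and touches:
            continue
        segments.append(
            NucleusSegment(
                label=int(prop.label),
                coords=prop.coords.copy(),
                area_px=area,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                touches_border=touches,
            )
        )
    return segments


def segment_nuclei(
    dapi: np.ndarray,
    *,
    min_area: int = MIN_SEGMENT_AREA,
    max_area: int = MAX_SEGMENT_AREA,
    exclude_border: bool = True,
    min_seed_distance: int = 5,
    min_contrast: float = 0.0,
) -> tuple[list[NucleusSegment], np.ndarray]:
    """Full nucleus pipeline: threshold, watershed, filter.

    Returns the retained segments and the (unfiltered) label image.
    """
    mask = isodata_threshold(dapi, min_contrast=min_contrast)
    labels = watershed_nuclei(mask, min_seed_distance=min_seed_distance)
    segments = filter_segments(
        labels, min_area=min_area, max_area=max_area, exclude_border=exclude_border
    )
    return segments, labels


def nucleus_label_image(segments: list[NucleusSegment], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize retained segments back into a label image."""
    out = np.zeros(shape, dtype=np.int32)
    for seg in segments:
        out[seg.coords[:, 0], seg.coords[:, 1]] = seg.label
    return out
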