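"""Nucleus identification from the counterstain channel.

Nuclei are segmented on the maximum-intensity projection (MIP) of the
nuclear-channel stack: a single Otsu threshold computed from the MIP
histogram separates DAPI-positive from DAPI-negative pixels, connected
components are labelled, and each component becomes a candidate nucleus.
Components smaller than ``min_nucleus_px`` pixels or touching the image
boundary are flagged as excluded.  The one 2D mask derived from the MIP is
applied to every slice of the focus channel when cropping, which removes
all signal outside the nucleus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import ImageStack, max_intensity_projection

__all__ = [
    "NucleusRegion",
    "DegenerateHistogramError",
    "otsu_threshold",
    "label_regions",
    "segment_nuclei",
    "crop_nucleus",
]

log = logging.getLogger(__name__)

#: 3x3 structuring element giving 8-connectivity for labelling
_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)

DEFAULT_MIN_NUCLEUS_PX = 1000


class DegenerateHistogramError(ValueError):
    """The histogram cannot be split into two nonempty classes."""


@dataclass
class NucleusRegion:
    """One labelled nuclear component of the MIP mask.

    ``bbox`` is (row_min, col_min, row_max_exclusive, col_max_exclusive) and
    tightly bounds ``mask``, a full-frame boolean raster.  ``centroid_xy`` is
    (x_bar, y_bar) in pixel coordinates with x = column.
    """

    label: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    area_px: int
    centroid_xy: tuple[float, float]
    excluded: bool = False
    exclusion_reason: str = "none"  # one of {"none", "too_small", "touches_boundary"}


def otsu_threshold(histogram: np.ndarray, offset: int = 0) -> int:
    """Otsu's threshold for an integer gray-level histogram.

    Returns the gray level ``t`` maximising the between-class variance
    ``w0*w1*(mu0-mu1)**2`` of the split background={levels <= t} vs
    foreground={levels > t}; pixels strictly above ``t`` are foreground.
    Ties are broken toward the lowest maximising level so the result is
    reproducible.

    Parameters
    ----------
    histogram:
        Counts per gray level; index ``i`` holds the count of level
        ``i + offset``.
    offset:
        Gray level of the first bin (0 for ordinary unsigned images).
    """
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.ndim != 1 or counts.sum() <= 0:
        raise ValueError("histogram must be a 1D array of nonnegative counts")
    nonzero = np.flatnonzero(counts)
    if nonzero.size < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied gray levels")

    levels = np.arange(counts.size, dtype=np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts)
    sum0 = np.cumsum(counts * levels)
    mu_total = sum0[-1] / total
    w1 = total - w0
    # candidate thresholds leave both classes nonempty; raising t across a
    # run of empty bins changes nothing, so candidates are restricted to
    # occupied levels — the lowest-t tie-break then falls out exactly
    valid = (w0 > 0) & (w1 > 0) & (counts > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (sum0[-1] - sum0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf
    best = int(np.argmax(sigma_b))  # argmax returns first (lowest) maximiser
    return best + offset


def label_regions(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label 8-connected components of a binary mask.

    Background is 0; components are labelled 1..count in raster-scan order of
    their first (topmost, then leftmost) pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, count = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    return labels, count


def _region_from_component(labels: np.ndarray, lab: int, frame_shape: tuple[int, int],
                            min_nucleus_px: int) -> NucleusRegion:
    mask = labels == lab
    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    area = int(rows.size)
    centroid_xy = (float(cols.mean()), float(rows.mean()))
    touches = (
        bbox[0] == 0 or bbox[1] == 0
        or bbox[2] == frame_shape[0] or bbox[3] == frame_shape[1]
    )
    if area < min_nucleus_px:
        reason = "too_small"
    elif touches:
        reason = "touches_boundary"
    else:
        reason = "none"
    return NucleusRegion(
        label=lab, mask=mask, bbox=bbox, area_px=area,
        centroid_xy=centroid_xy, excluded=reason != "none", exclusion_reason=reason,
    )


def segment_nuclei(
    nuclear_stack: ImageStack,
    min_nucleus_px: int = DEFAULT_MIN_NUCLEUS_PX,
    include_excluded: bool = True,
) -> list[NucleusRegion]:
    """Segment nuclei from the nuclear-channel stack.

    The MIP is thresholded with :func:`otsu_threshold`, components are
    labelled under 8-connectivity, and every component is materialised as a
    :class:`NucleusRegion`.  Retained (non-excluded) nuclei are labelled
    1..K in raster-scan order of their first pixel; excluded components
    follow with labels K+1 onward, flagged with their exclusion reason.

    A degenerate histogram (all pixels identical) yields an empty list with
    a logged warning rather than an error.
    """
    mip = max_intensity_projection(nuclear_stack)
    hist = np.bincount(mip.ravel(), minlength=2 ** nuclear_stack.bit_depth)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        log.warning("degenerate nuclear histogram (single gray level): no nuclei segmented")
        return []
    mask = mip > t
    labels, count = label_regions(mask)
    regions = [
        _region_from_component(labels, lab, mip.shape, min_nucleus_px)
        for lab in range(1, count + 1)
    ]
    kept = [r for r in regions if not r.excluded]
    dropped = [r for r in regions if r.excluded]
    for i, r in enumerate(kept, start=1):
        r.label = i
    for i, r in enumerate(dropped, start=len(kept) + 1):
        r.label = i
    if not include_excluded:
        return kept
    return kept + dropped


def crop_nucleus(
    focus_stack: ImageStack,
    nucleus: NucleusRegion,
    pad_px: int = 0,
) -> tuple[ImageStack, np.ndarray]:
    """Crop the focus-channel stack to one nucleus and zero non-nuclear pixels.

    Every slice is cropped to the nucleus bounding box (grown by ``pad_px``,
    clamped to the frame), and pixels outside the 2D nuclear mask are set to
    zero in every slice.  Returns the cropped stack and the matching mask
    crop.
    """
    if nucleus.excluded:
        raise ValueError(
            f"nucleus {nucleus.label} is excluded ({nucleus.exclusion_reason}); refuse to crop"
        )
    n_rows, n_cols = focus_stack.data.shape[1:]
    r0, c0, r1, c1 = nucleus.bbox
    r0 = max(0, r0 - pad_px)
    c0 = max(0, c0 - pad_px)
    r1 = min(n_rows, r1 + pad_px)
    c1 = min(n_cols, c1 + pad_px)
    mask_crop = nucleus.mask[r0:r1, c0:c1]
    data = focus_stack.data[:, r0:r1, c0:c1].copy()
    data[:, ~mask_crop] = 0
    return focus_stack.with_data(data), mask_crop
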