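"""Moment-based descriptors of 2D focus regions.

Each connected binary focus region R is summarised by its image moments:
the raw moment m_pq = sum over (u, v) in R of u^p v^q, with u the column
(x) and v the row (y) coordinate.  The area is m00, the centroid is
(m10/m00, m01/m00), and the second-order central moments (mu20, mu02,
mu11) — computed about the centroid, hence translation-invariant — define
the best-fit ellipse: its orientation theta, the eigenvalues lambda1 >=
lambda2 of the moment matrix [[mu20, mu11], [mu11, mu02]], the eccentricity
ratio lambda1/lambda2 and the radii r_a = 2*sqrt(lambda1/m00),
r_b = 2*sqrt(lambda2/m00).

The eccentricity reported here is the eigenvalue ratio (>= 1, equal to the
squared axis ratio), not the conic eccentricity in [0, 1); it is exposed
as ``ecc_ratio`` alongside the plain axis ratio ``r_a / r_b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import ImageStack

__all__ = [
    "SliceFocus",
    "region_from_mask",
    "raw_moment",
    "centroid",
    "central_moments",
    "ellipse_params",
    "measure_slice_foci",
]

_EIGHT = np.ones((3, 3), dtype=bool)

#: eigenvalue ratio reported when the minor eigenvalue vanishes (line/point region)
ECC_DEGENERATE = math.inf


@dataclass
class SliceFocus:
    """One connected focus region in one z-slice with its moment descriptors.

    ``pixels`` is an (N, 2) integer array of (u, v) = (col, row)
    coordinates; intensities are measured on the raw (unfiltered) focus
    channel within the region.
    """

    nucleus_label: int
    z_index: int
    pixels: np.ndarray
    area_px: int
    centroid_px: tuple[float, float]  # (x_bar, y_bar)
    central_moments: tuple[float, float, float]  # (mu20, mu02, mu11)
    theta_rad: float
    ecc_ratio: float
    radii_px: tuple[float, float]  # (r_a major, r_b minor)
    mean_raw_intensity: float
    integrated_raw_intensity: float

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        """Region pixels as a set of (u, v) tuples, for containment tests."""
        return {(int(u), int(v)) for u, v in self.pixels}


def _as_region(region) -> np.ndarray:
    arr = np.asarray(list(region) if isinstance(region, set) else region, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("region is empty")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("region must be an (N, 2) array of (u, v) coordinates")
    return arr


def region_from_mask(mask: np.ndarray) -> np.ndarray:
    """Extract the (u, v) = (col, row) coordinate list of a binary mask."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    return np.column_stack([cols, rows])


def raw_moment(region, p: int, q: int) -> float:
    """Raw image moment m_pq = sum over (u, v) in R of u^p v^q."""
    if p < 0 or q < 0:
        raise ValueError("moment orders must be nonnegative")
    arr = _as_region(region)
    return float(np.sum(arr[:, 0] ** p * arr[:, 1] ** q))


def centroid(region) -> tuple[float, float]:
    """Gravity centre (x_bar, y_bar) = (m10/m00, m01/m00) of a binary region."""
    arr = _as_region(region)
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def central_moments(region) -> tuple[float, float, float]:
    """Second-order central moments (mu20, mu02, mu11) about the centroid."""
    arr = _as_region(region)
    du = arr[:, 0] - arr[:, 0].mean()
    dv = arr[:, 1] - arr[:, 1].mean()
    return (float(np.sum(du * du)), float(np.sum(dv * dv)), float(np.sum(du * dv)))


def ellipse_params(
    mu20: float, mu02: float, mu11: float, area: float
) -> tuple[float, float, float, float]:
    """Orientation, eccentricity ratio and radii of the moment ellipse.

    Returns ``(theta_rad, ecc_ratio, r_a, r_b)`` where theta is the angle
    between the x-axis and the major axis, computed with the two-argument
    arctangent ``0.5 * atan2(2*mu11, mu20 - mu02)`` so the quadrant is
    correct when mu20 < mu02 (theta = 0 by convention for mu11 = 0 and
    mu20 = mu02); ``ecc_ratio = lambda1/lambda2 >= 1`` is the eigenvalue
    ratio of the moment matrix (infinity for a degenerate line or point
    region, in which case r_b = 0); ``r_a = 2*sqrt(lambda1/area)`` and
    ``r_b = 2*sqrt(lambda2/area)`` are the major and minor radii in pixels.
    """
    if area < 1:
        raise ValueError("area must be >= 1")
    disc = math.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11 * mu11)
    lam1 = 0.5 * (mu20 + mu02 + disc)
    lam2 = 0.5 * (mu20 + mu02 - disc)
    lam2 = max(lam2, 0.0)  # guard tiny negative round-off
    if mu11 == 0.0 and mu20 == mu02:
        theta = 0.0
    else:
        theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    ecc = lam1 / lam2 if lam2 > 0 else ECC_DEGENERATE
    r_a = 2.0 * math.sqrt(lam1 / area)
    r_b = 2.0 * math.sqrt(lam2 / area)
    return (theta, ecc, r_a, r_b)


def measure_slice_foci(
    binary_masks: list[np.ndarray],
    raw_stack: ImageStack | np.ndarray,
    nucleus_label: int = 1,
) -> list[SliceFocus]:
    """Label per-slice masks (8-connected) and measure every focus region.

    ``binary_masks`` holds one boolean raster per z-slice; ``raw_stack`` is
    the matching raw focus-channel crop on which intensities are read.
    Returns one :class:`SliceFocus` per connected component, ordered by
    z-index then by label raster order.
    """
    data = raw_stack.data if isinstance(raw_stack, ImageStack) else np.asarray(raw_stack)
    if len(binary_masks) != data.shape[0]:
        raise ValueError("one binary mask per raw slice is required")
    out: list[SliceFocus] = []
    for z, mask in enumerate(binary_masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != data.shape[1:]:
            raise ValueError("mask dimensions do not match raw slices")
        labels, n = ndimage.label(mask, structure=_EIGHT)
        for lab in range(1, n + 1):
            region = region_from_mask(labels == lab)
            area = region.shape[0]
            cx, cy = centroid(region)
            mu = central_moments(region)
            theta, ecc, r_a, r_b = ellipse_params(*mu, area)
            vals = data[z][region[:, 1], region[:, 0]].astype(np.float64)
            out.append(
                SliceFocus(
                    nucleus_label=nucleus_label,
                    z_index=z,
                    pixels=region,
                    area_px=int(area),
                    centroid_px=(cx, cy),
                    central_moments=mu,
                    theta_rad=theta,
                    ecc_ratio=ecc,
                    radii_px=(r_a, r_b),
                    mean_raw_intensity=float(vals.mean()),
                    integrated_raw_intensity=float(vals.sum()),
                )
            )
    return out
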