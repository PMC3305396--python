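"""The focus-detection filter chain.

Each per-nucleus focus-channel stack is turned into per-slice binary focus
masks through five stages:

1. pre-smoothing — iterated 3x3 mean filtering that removes high-frequency
   noise spikes before differentiation;
2. a Laplacian with a configurable sensitivity kernel, plus a normalisation
   offset (default 1500) so that intensity peaks become non-negative
   troughs;
3. the Crimmins geometric speckle-reduction filter, which raises pixels
   significantly darker than their directional neighbours and lowers those
   significantly lighter, removing noise amplified by the Laplacian;
4. a maximum-entropy (Kapur) threshold computed from the global histogram
   of the whole stack (optionally of all nuclei in a folder), not per
   slice — accumulating signal and noise over every slice makes the two
   classes separate more cleanly and stops pure-noise slices from being
   split into "strong noise" foci;
5. a morphological closing with a fixed 3x3 structuring element that fills
   single-pixel gaps inside foci.

After the Laplacian, foci are troughs; the chain negates the filtered image
before histogramming so that "above threshold" uniformly means "focus".
All filter arithmetic is floating point; values are placed into integer
histogram bins by rounding half away from zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import ImageStack
from .nucleus_segmentation import DegenerateHistogramError

__all__ = [
    "FilterSettings",
    "IntHistogram",
    "presmooth",
    "laplacian",
    "crimmins",
    "max_entropy_threshold",
    "build_global_histogram",
    "binarize_and_close",
    "class_separation",
    "analysis_mask",
    "filter_stack",
    "detect_foci_masks",
]

log = logging.getLogger(__name__)

DEFAULT_NORMALISATION = 1500

def _log_kernel(sigma: float, gain: float = 0.6) -> np.ndarray:
    """Gain-normalised Laplacian-of-Gaussian kernel (centre negative).

    Sampled out to 3.5 sigma, adjusted to exact zero sum, and scaled so the
    response to a broad bright plateau of height h is ``-gain * h``: the
    deepest trough any structure can produce stays within the normalisation
    offset, so the post-offset clamp rarely engages.
    """
    half = int(math.ceil(3.5 * sigma))
    y, x = np.mgrid[-half: half + 1, -half: half + 1]
    r2 = (x * x + y * y).astype(np.float64)
    k = (r2 - 2.0 * sigma ** 2) / sigma ** 4 * np.exp(-r2 / (2.0 * sigma ** 2))
    k -= k.mean()
    k *= gain / (-k[k < 0].sum())
    return k


#: Laplacian kernels by sensitivity.  ``low`` and ``medium`` are the classic
#: 4- and 8-neighbour operators, responding to the sharpest structures;
#: ``high`` is a broad Laplacian-of-Gaussian (sigma = 3 px) whose larger
#: neighbourhood responds to broader structures — gain-normalised so its
#: output stays within the normalisation offset (see :func:`_log_kernel`).
LAPLACIAN_KERNELS = {
    "low": np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64),
    "medium": np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=np.float64),
    "high": _log_kernel(3.0),
}

_CLOSING_SE = np.ones((3, 3), dtype=bool)
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class FilterSettings:
    """Tunable detection parameters for the filter chain.

    ``pre_iterations`` and ``post_iterations`` are the smoothing passes
    before and after the Laplacian (the quantities explored during batch
    optimisation).  ``laplacian_sensitivity`` selects the kernel: ``low`` is
    the 4-neighbour Laplacian, ``medium`` the 8-neighbour one, ``high`` a
    5x5 Laplacian-of-Gaussian — larger neighbourhoods respond to broader
    structures.  ``normalisation_value`` is added after the Laplacian so
    focus troughs stay non-negative.  ``histogram_scope`` selects whether
    the threshold histogram pools one nucleus stack or all nuclei of a
    folder.  ``min_focus_px`` drops binary components smaller than this
    many pixels after closing (residual salt).
    """

    pre_iterations: int = 3
    post_iterations: int = 3
    laplacian_sensitivity: str = "low"
    normalisation_value: int = DEFAULT_NORMALISATION
    histogram_scope: str = "stack"
    min_focus_px: int = 4
    min_separation_sd: float = 10.0

    @property
    def kernel_radius(self) -> int:
        return (LAPLACIAN_KERNELS[self.laplacian_sensitivity].shape[0] - 1) // 2

    @property
    def boundary_margin_px(self) -> int:
        """Width of the nuclear-boundary band excluded from analysis.

        Masking zeroes all signal outside the nucleus, so the mask edge is
        an intensity step that rings under smoothing and the Laplacian; the
        ring is confined to the filter support, pre-smoothing spread plus
        kernel radius (plus one pixel of slack), and is excluded from both
        the threshold histogram and the binary output.
        """
        return self.pre_iterations + self.kernel_radius + 1

    def __post_init__(self) -> None:
        if self.pre_iterations < 0 or self.post_iterations < 0:
            raise ValueError("iteration counts must be >= 0")
        if self.laplacian_sensitivity not in LAPLACIAN_KERNELS:
            raise ValueError(f"unknown sensitivity {self.laplacian_sensitivity!r}")
        if self.normalisation_value < 0:
            raise ValueError("normalisation_value must be >= 0")
        if self.histogram_scope not in ("stack", "folder"):
            raise ValueError(f"histogram_scope must be 'stack' or 'folder'")
        if self.min_focus_px < 1:
            raise ValueError("min_focus_px must be >= 1")
        if self.min_separation_sd < 0:
            raise ValueError("min_separation_sd must be >= 0")


@dataclass(frozen=True)
class IntHistogram:
    """Integer-binned histogram: ``counts[i]`` is the count of level ``i + offset``."""

    counts: np.ndarray
    offset: int = 0

    def __add__(self, other: "IntHistogram") -> "IntHistogram":
        lo = min(self.offset, other.offset)
        hi = max(self.offset + self.counts.size, other.offset + other.counts.size)
        counts = np.zeros(hi - lo, dtype=np.int64)
        counts[self.offset - lo: self.offset - lo + self.counts.size] += self.counts
        counts[other.offset - lo: other.offset - lo + other.counts.size] += other.counts
        return IntHistogram(counts, lo)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (reproducible binning)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def presmooth(image: np.ndarray, iterations: int) -> np.ndarray:
    """Iterated 3x3 mean smoothing with reflective borders.

    ``iterations=0`` returns the input unchanged (as float).  Operates on a
    2D slice or on a (z, rows, cols) stack slice-wise.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = np.asarray(image, dtype=np.float64)
    size = (3, 3) if out.ndim == 2 else (1, 3, 3)
    for _ in range(iterations):
        out = ndimage.uniform_filter(out, size=size, mode="reflect")
    return out


def laplacian(
    image: np.ndarray,
    sensitivity: str = "low",
    normalisation_value: int = DEFAULT_NORMALISATION,
) -> np.ndarray:
    """Discrete Laplacian plus a normalisation offset; peaks become troughs.

    The kernel is selected by ``sensitivity`` (see :data:`LAPLACIAN_KERNELS`);
    convolution uses reflective borders.  ``normalisation_value`` is added so
    focus troughs stay non-negative; any value still below zero (very bright,
    sharp peaks) is clamped to 0 with a logged warning.  Operates slice-wise
    on a stack.
    """
    kernel = LAPLACIAN_KERNELS[sensitivity]
    x = np.asarray(image, dtype=np.float64)
    k = kernel if x.ndim == 2 else kernel[np.newaxis, :, :]
    out = ndimage.convolve(x, k, mode="reflect") + float(normalisation_value)
    neg = out < 0
    if neg.any():
        log.warning(
            "%d pixel(s) below zero after normalisation offset %d; clamped",
            int(neg.sum()), normalisation_value,
        )
        out[neg] = 0.0
    return out


# The Crimmins speckle-removal pass structure: for each of the four
# directions (S-N, E-W, NE-SW, SE-NW) a dark pass raises pixels that sit in
# a local valley along that direction, then a light pass lowers pixels on a
# local ridge; each pass is made of four synchronous +-1 sub-steps driven by
# the two neighbours a (behind) and c (ahead) of the current pixel b.
_DIRECTIONS = [(1, 0), (0, 1), (1, 1), (1, -1)]


def _shift(x: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift a 2D array (or stack, over the last two axes) with edge replication."""
    axes = (x.ndim - 2, x.ndim - 1)
    out = x
    for axis, d in zip(axes, (dr, dc)):
        if d == 0:
            continue
        out = np.roll(out, d, axis=axis)
        idx = [slice(None)] * x.ndim
        if d > 0:
            idx[axis] = slice(0, d)
            src = [slice(None)] * x.ndim
            src[axis] = slice(d, d + 1)
        else:
            idx[axis] = slice(d, None)
            src = [slice(None)] * x.ndim
            src[axis] = slice(d - 1, d)
        out[tuple(idx)] = out[tuple(src)]
    return out


def _crimmins_half(b: np.ndarray, dr: int, dc: int, dark: bool) -> np.ndarray:
    """One directional dark (or light) pass: four synchronous sub-steps."""
    sign = 1.0 if dark else -1.0
    for step in range(4):
        a = _shift(b, dr, dc)      # neighbour behind
        c = _shift(b, -dr, -dc)    # neighbour ahead
        if step == 0:
            cond = sign * (a - b) >= 2
        elif step == 1:
            cond = (sign * (a - b) > 0) & (sign * (b - c) <= 0)
        elif step == 2:
            cond = (sign * (c - b) > 0) & (sign * (b - a) <= 0)
        else:
            cond = sign * (c - b) >= 2
        b = b + np.where(cond, sign, 0.0)
    return b


def crimmins(image: np.ndarray, iterations: int) -> np.ndarray:
    """Crimmins geometric speckle reduction.

    One iteration applies, for each of the four directions (vertical,
    horizontal, both diagonals), a dark pass that brightens pixels
    significantly darker than their neighbours followed by a light pass that
    darkens pixels significantly lighter; each pass consists of the four
    classic +-1 adjustment sub-steps, applied synchronously over the whole
    raster.  ``iterations=0`` is the identity.  Operates slice-wise on a
    stack.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    b = np.asarray(image, dtype=np.float64).copy()
    for _ in range(iterations):
        for dr, dc in _DIRECTIONS:
            b = _crimmins_half(b, dr, dc, dark=True)
        for dr, dc in _DIRECTIONS:
            b = _crimmins_half(b, dr, dc, dark=False)
    return b


def max_entropy_threshold(histogram: np.ndarray | IntHistogram, offset: int = 0) -> int:
    """Kapur maximum-entropy threshold for an integer gray-level histogram.

    Returns the level ``t`` maximising the sum of Shannon entropies of the
    background class {levels <= t} and foreground class {levels > t}, over
    all splits that leave both classes nonempty; ties break toward the
    lowest level.
    """
    if isinstance(histogram, IntHistogram):
        offset = histogram.offset
        histogram = histogram.counts
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.ndim != 1 or counts.sum() <= 0:
        raise ValueError("histogram must be a 1D array of nonnegative counts")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied gray levels")

    p = counts / counts.sum()
    # partial entropy S(t) = -sum_{i<=t} p_i ln p_i, with 0 ln 0 := 0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S = np.cumsum(plogp)
    P = np.cumsum(p)
    # candidates restricted to occupied levels (empty bins form plateaus)
    valid = (P > 0) & (P < 1) & (counts > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_back = np.log(P) - S / P
        h_fore = np.log1p(-P) - (S[-1] - S) / (1.0 - P)
    crit = h_back + h_fore
    crit[~valid] = -np.inf
    best = int(np.argmax(crit))
    return best + offset


def build_global_histogram(
    filtered_stacks: list[np.ndarray],
    nucleus_masks: list[np.ndarray],
) -> IntHistogram:
    """Accumulate the integer histogram of in-mask pixels over filtered stacks.

    ``filtered_stacks`` are (z, rows, cols) float rasters from the same
    filter chain; ``nucleus_masks`` are the aligned 2D nuclear masks (one
    per stack, applied to every slice).  Passing one stack realises
    stack-scope thresholding; passing all nuclei of a folder realises
    folder-scope.  Bins are one per integer level over the observed
    min..max; values are binned by rounding half away from zero.
    """
    if len(filtered_stacks) != len(nucleus_masks):
        raise ValueError("need exactly one mask per filtered stack")
    values = []
    for stack, mask in zip(filtered_stacks, nucleus_masks):
        if stack.shape[1:] != mask.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not align with stack slices {stack.shape[1:]}"
            )
        sel = np.broadcast_to(mask, stack.shape)
        values.append(round_half_away(stack[sel]).astype(np.int64))
    if not values:
        raise ValueError("no stacks supplied")
    allv = np.concatenate(values)
    if allv.size == 0:
        raise ValueError("masks select no pixels")
    lo = int(allv.min())
    counts = np.bincount(allv - lo)
    return IntHistogram(counts=counts, offset=lo)


def binarize_and_close(
    filtered_slice: np.ndarray,
    threshold: int,
    polarity_inverted: bool = True,
) -> np.ndarray:
    """Threshold one filtered slice and close gaps with the fixed 3x3 element.

    With ``polarity_inverted=True`` (the chain's convention: the filtered
    image has been negated so foci are maxima) focus pixels are those with
    rounded value strictly above the threshold; otherwise strictly below.
    Binary closing (dilation then erosion) with the full 3x3 structuring
    element fills single-pixel gaps; it is idempotent.
    """
    rounded = round_half_away(np.asarray(filtered_slice, dtype=np.float64))
    fg = rounded > threshold if polarity_inverted else rounded < threshold
    return ndimage.binary_closing(fg, structure=_CLOSING_SE)


def dump_stages(
    stack_data: np.ndarray,
    settings: FilterSettings,
    folder,
    slice_index: int | None = None,
) -> list:
    """Write each filter stage of one slice as a TIFF audit trail.

    Saves the raw, pre-smoothed, Laplacian(+offset), Crimmins-filtered and
    negated rasters plus the final binary mask for ``slice_index``
    (default: the middle slice) into ``folder``.  Intended for visual
    inspection when tuning settings; float stages are stored as 32-bit
    TIFFs.
    """
    import tifffile
    from pathlib import Path

    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    data = np.asarray(stack_data, dtype=np.float64)
    z = data.shape[0] // 2 if slice_index is None else slice_index

    stages = {"0_raw": data}
    pre = presmooth(data, settings.pre_iterations)
    stages["1_presmoothed"] = pre
    lap = laplacian(pre, settings.laplacian_sensitivity, settings.normalisation_value)
    stages["2_laplacian"] = lap
    cri = crimmins(lap, settings.post_iterations)
    stages["3_crimmins"] = cri
    stages["4_negated"] = -cri
    mask = np.ones(data.shape[1:], dtype=bool)
    hist = build_global_histogram([-cri], [mask])
    try:
        t = max_entropy_threshold(hist)
        stages["5_binary"] = binarize_and_close(-cri[z], t).astype(np.float32)[np.newaxis]
    except DegenerateHistogramError:
        pass

    paths = []
    for name, arr in stages.items():
        plane = arr[z] if arr.shape[0] > z else arr[0]
        path = folder / f"{name}.tif"
        tifffile.imwrite(path, plane.astype(np.float32))
        paths.append(path)
    return paths


def filter_stack(stack_data: np.ndarray, settings: FilterSettings) -> np.ndarray:
    """Run the continuous part of the chain and negate so foci are maxima.

    presmooth(pre) -> Laplacian(+offset) -> Crimmins(post) -> negation.
    Returns a float (z, rows, cols) raster on which thresholds operate with
    a uniform "above threshold = focus" convention.
    """
    x = presmooth(np.asarray(stack_data, dtype=np.float64), settings.pre_iterations)
    x = laplacian(x, settings.laplacian_sensitivity, settings.normalisation_value)
    x = crimmins(x, settings.post_iterations)
    return -x


def class_separation(histogram: IntHistogram, threshold: int) -> float:
    """Separation of the split classes in units of background spread.

    Returns ``(mean_foreground - mean_background) / sd_background`` for the
    split background={levels <= threshold}, foreground={levels > threshold}.
    A genuine focus class sits far above what the tail of the noise
    distribution alone can produce; the detection chain treats a split
    whose separation is below ``FilterSettings.min_separation_sd`` as
    noise-only (no distinct focus class) and reports no foci.
    """
    levels = np.arange(histogram.counts.size, dtype=np.float64) + histogram.offset
    counts = histogram.counts.astype(np.float64)
    split = threshold - histogram.offset + 1
    bg_c, fg_c = counts[:split], counts[split:]
    bg_l, fg_l = levels[:split], levels[split:]
    if bg_c.sum() <= 0 or fg_c.sum() <= 0:
        return 0.0
    bg_mean = (bg_c * bg_l).sum() / bg_c.sum()
    fg_mean = (fg_c * fg_l).sum() / fg_c.sum()
    bg_var = (bg_c * (bg_l - bg_mean) ** 2).sum() / bg_c.sum()
    # the background spread cannot be resolved below the bin width, so the
    # denominator is floored at one gray level
    bg_sd = max(np.sqrt(bg_var), 1.0)
    return float((fg_mean - bg_mean) / bg_sd)


def analysis_mask(mask: np.ndarray, settings: FilterSettings) -> np.ndarray:
    """Nuclear mask eroded by the boundary margin of ``settings``.

    This is the mask within which filtered values are histogrammed and
    focus pixels may be reported; it removes the edge-ringing band created
    by zeroing all signal outside the nucleus.
    """
    m = np.asarray(mask, dtype=bool)
    margin = settings.boundary_margin_px
    if margin <= 0:
        return m
    return ndimage.binary_erosion(m, structure=_EIGHT, iterations=margin)


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    if min_px <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def detect_foci_masks(
    nucleus_stack: ImageStack | np.ndarray,
    mask: np.ndarray,
    settings: FilterSettings,
    external_histogram: IntHistogram | None = None,
) -> list[np.ndarray]:
    """Full chain: per-slice binary focus masks for one cropped nucleus stack.

    The threshold is taken from the Kapur criterion on the stack-global
    histogram (or on ``external_histogram`` when folder-scope pooling is in
    effect).  Out-of-mask pixels are always False.  A degenerate histogram
    (e.g. an all-zero crop) yields empty masks with a logged warning.
    """
    data = nucleus_stack.data if isinstance(nucleus_stack, ImageStack) else nucleus_stack
    filtered = filter_stack(data, settings)
    m = analysis_mask(mask, settings)
    hist = external_histogram
    if hist is None:
        hist = build_global_histogram([filtered], [m])
    try:
        t = max_entropy_threshold(hist)
    except DegenerateHistogramError:
        log.warning("degenerate focus histogram: no foci detected in this scope")
        return [np.zeros(mask.shape, dtype=bool) for _ in range(filtered.shape[0])]
    sep = class_separation(hist, t)
    if sep < settings.min_separation_sd:
        log.info(
            "no distinct focus class (separation %.1f sd < %.1f): no foci in this scope",
            sep, settings.min_separation_sd,
        )
        return [np.zeros(mask.shape, dtype=bool) for _ in range(filtered.shape[0])]
    out = []
    for plane in filtered:
        binary = binarize_and_close(plane, t) & m
        out.append(_drop_small(binary, settings.min_focus_px))
    return out
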