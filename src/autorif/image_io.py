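"""Reading and writing of TIFF z-series and maximum-intensity projections.

A field of view is stored on disk as one folder containing one grayscale
TIFF per z-slice, the two fluorescence channels distinguished by a substring
in the filename (``dapi`` for the nuclear counterstain, ``rif`` for the
focus marker by default).  Plain TIFF series carry no physical metadata, so
pixel scale and z-step are supplied by the caller; the defaults correspond
to a widefield setup with a 100x objective (0.07 um/pixel) sampling at
0.5 um axial intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Calibration",
    "ImageStack",
    "read_stack",
    "write_stack",
    "max_intensity_projection",
    "MissingDataError",
    "FormatError",
]

DEFAULT_PIXEL_SCALE_UM = 0.07
DEFAULT_Z_STEP_UM = 0.5

#: default filename substrings identifying each channel (case-insensitive)
CHANNEL_PATTERNS = {"nuclear": "dapi", "focus": "rif"}


class MissingDataError(FileNotFoundError):
    """No usable image files were found where some were expected."""


class FormatError(ValueError):
    """An image file could not be interpreted as a single-plane grayscale slice."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a stack: lateral pixel scale and axial step, in um."""

    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM

    def __post_init__(self) -> None:
        if self.pixel_scale_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_scale_um and z_step_um must be positive")


@dataclass
class ImageStack:
    """An ordered z-series of 2D grayscale slices for one channel of one field.

    ``data`` is a (z, rows, cols) unsigned-integer array; slice order follows
    monotonically increasing z.  Coordinates are 0-based (row, col) = (y, x);
    conversions to micrometres happen only in reporting and 3D geometry.
    """

    data: np.ndarray
    bit_depth: int
    calibration: Calibration = field(default_factory=Calibration)
    channel_tag: str = "focus"
    source_path: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"stack data must be 3D (z, rows, cols), got shape {self.data.shape}")
        if self.data.shape[0] == 0:
            raise FormatError("stack must contain at least one slice")
        if not (8 <= self.bit_depth <= 16):
            raise ValueError(f"bit_depth must be in [8, 16], got {self.bit_depth}")
        if not np.issubdtype(self.data.dtype, np.unsignedinteger):
            raise FormatError(f"pixel data must be unsigned integer, got {self.data.dtype}")
        if self.data.size and int(self.data.max()) >= 2 ** self.bit_depth:
            raise ValueError(
                f"pixel values exceed bit depth {self.bit_depth} "
                f"(max={int(self.data.max())})"
            )
        if self.channel_tag not in ("nuclear", "focus"):
            raise ValueError(f"channel_tag must be 'nuclear' or 'focus', got {self.channel_tag!r}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def pixel_scale_um(self) -> float:
        return self.calibration.pixel_scale_um

    @property
    def z_step_um(self) -> float:
        return self.calibration.z_step_um

    def slices(self):
        """Iterate over 2D slice views in z order."""
        return iter(self.data)

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """Copy of this stack with different pixel data but identical metadata."""
        return replace(self, data=data)


_TRAILING_INT = re.compile(r"(\d+)\D*$")


def _z_key(path: Path) -> tuple[int, str]:
    m = _TRAILING_INT.search(path.stem)
    return (int(m.group(1)) if m else -1, path.name)


def read_stack(
    folder: str | Path,
    channel_tag: str = "focus",
    calibration: Calibration | None = None,
    pattern: str | None = None,
    bit_depth: int | None = None,
) -> ImageStack:
    """Read a TIFF z-series from ``folder`` into an :class:`ImageStack`.

    Files whose name contains ``pattern`` (case-insensitive; defaults to the
    channel's conventional substring) are sorted by the trailing integer in
    their stem, which encodes the z index.  All files must decode as
    single-plane grayscale rasters of identical dimensions.

    Parameters
    ----------
    folder:
        Directory holding one TIFF per z-slice.
    channel_tag:
        ``"nuclear"`` or ``"focus"``; selects the default filename pattern.
    calibration:
        Physical calibration; defaults to 0.07 um/pixel, 0.5 um z-step.
    pattern:
        Override the filename substring used to select this channel's files.
    bit_depth:
        Override the inferred bit depth (e.g. 14 for 14-bit data stored in a
        16-bit container).
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise MissingDataError(f"not a directory: {folder}")
    if pattern is None:
        pattern = CHANNEL_PATTERNS.get(channel_tag, "")
    pattern = pattern.lower()
    files = sorted(
        (p for p in folder.iterdir()
         if p.suffix.lower() in (".tif", ".tiff") and pattern in p.name.lower()),
        key=_z_key,
    )
    if not files:
        raise MissingDataError(f"no TIFF files matching {pattern!r} in {folder}")

    planes = []
    for f in files:
        arr = tifffile.imread(f)
        if arr.ndim != 2:
            raise FormatError(f"{f.name}: expected single-plane grayscale, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.unsignedinteger):
            raise FormatError(f"{f.name}: unsupported sample format {arr.dtype}")
        planes.append(arr)
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent slice dimensions in {folder}: {sorted(shapes)}")

    data = np.stack(planes)
    if bit_depth is None:
        bit_depth = data.dtype.itemsize * 8
    return ImageStack(
        data=data,
        bit_depth=bit_depth,
        calibration=calibration or Calibration(),
        channel_tag=channel_tag,
        source_path=str(folder),
    )


def write_stack(stack: ImageStack, folder: str | Path, prefix: str | None = None) -> list[Path]:
    """Write ``stack`` as one losslessly-encoded TIFF per slice.

    Filenames are ``{prefix}_z{ii}.tif`` with a zero-padded z index so that
    lexical and numeric ordering coincide; the prefix defaults to the
    channel's conventional substring.  Bit depths above 8 are stored in a
    16-bit container with pixel values preserved exactly.
    """
    if stack.n_slices == 0:
        raise ValueError("cannot write an empty stack")
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    if prefix is None:
        prefix = CHANNEL_PATTERNS.get(stack.channel_tag, stack.channel_tag)
    dtype = np.uint8 if stack.bit_depth <= 8 else np.uint16
    width = max(2, len(str(stack.n_slices - 1)))
    paths = []
    for z, plane in enumerate(stack.slices()):
        path = folder / f"{prefix}_z{z:0{width}d}.tif"
        tifffile.imwrite(path, plane.astype(dtype))
        paths.append(path)
    return paths


def max_intensity_projection(stack: ImageStack) -> np.ndarray:
    """Collapse a z-stack into a 2D raster of per-pixel maxima (MIP)."""
    if stack.n_slices == 0:
        raise ValueError("cannot project an empty stack")
    return stack.data.max(axis=0)
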