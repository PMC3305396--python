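"""Synthetic two-channel z-stacks with known ground truth.

The generator emulates the acquisition geometry the pipeline is designed
for: 22-slice stacks at 0.5 um axial intervals, 14-bit intensities at a
lateral scale of 0.07 um/pixel.  Nuclei are filled ellipses constant
across z; foci are 3D Gaussian blobs clipped to their nucleus, riding on a
flat (optionally tilted) background with Poisson shot noise and additive
Gaussian read noise.  Everything is deterministic given a seed, and the
ground truth serialises to a JSON sidecar so detector output can be scored
against it.

A focus's ground-truth "diameter" is its lateral full width at half
maximum, FWHM = 2*sqrt(2*ln 2)*sigma_xy, converted to micrometres — the
quantity the small/medium/large size categories bin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .image_io import Calibration, ImageStack, write_stack
from .reconstruction_3d import Focus3D, size_category

__all__ = [
    "NucleusSpec",
    "FocusSpec",
    "NoiseModel",
    "GroundTruth",
    "render_field",
    "render_linking_cases",
    "place_foci",
    "default_truth",
    "write_field",
    "score_against_truth",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548


@dataclass(frozen=True)
class NucleusSpec:
    centre_px: tuple[float, float]  # (x, y)
    semi_axes_px: tuple[float, float]  # (a along x, b along y) before rotation
    orientation_rad: float = 0.0
    intensity: float = 3000.0


@dataclass(frozen=True)
class FocusSpec:
    nucleus_index: int
    centre_3d_px: tuple[float, float, float]  # (x, y, z) in pixel/slice units
    sigma_xy_px: float
    sigma_z_slices: float
    peak_intensity: float


@dataclass(frozen=True)
class NoiseModel:
    gaussian_sd: float = 20.0
    poisson: bool = True
    background_level: float = 400.0
    background_gradient: tuple[float, float] = (0.0, 0.0)  # per-pixel slope in (x, y)


@dataclass
class GroundTruth:
    """Full description of one synthetic field of view."""

    nuclei: list[NucleusSpec]
    foci: list[FocusSpec]
    noise: NoiseModel = field(default_factory=NoiseModel)
    calibration: Calibration = field(default_factory=Calibration)
    bit_depth: int = 14
    seed: int = 0

    def focus_fwhm_um(self, focus: FocusSpec) -> float:
        return FWHM_PER_SIGMA * focus.sigma_xy_px * self.calibration.pixel_scale_um

    def focus_size_category(self, focus: FocusSpec) -> str:
        return size_category(self.focus_fwhm_um(focus))

    # ---- serialisation -------------------------------------------------
    def to_json(self) -> str:
        d = {
            "nuclei": [asdict(n) for n in self.nuclei],
            "foci": [asdict(f) for f in self.foci],
            "noise": asdict(self.noise),
            "calibration": asdict(self.calibration),
            "bit_depth": self.bit_depth,
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)

        def _tup(obj, keys):
            return {k: tuple(v) if isinstance(v, list) else v for k, v in obj.items()}

        return cls(
            nuclei=[NucleusSpec(**_tup(n, None)) for n in d["nuclei"]],
            foci=[FocusSpec(**_tup(f, None)) for f in d["foci"]],
            noise=NoiseModel(**_tup(d["noise"], None)),
            calibration=Calibration(**d["calibration"]),
            bit_depth=d["bit_depth"],
            seed=d["seed"],
        )


def _nucleus_footprint(spec: NucleusSpec, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = np.mgrid[0: shape[0], 0: shape[1]]
    dx = cols - spec.centre_px[0]
    dy = rows - spec.centre_px[1]
    c, s = math.cos(spec.orientation_rad), math.sin(spec.orientation_rad)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    a, b = spec.semi_axes_px
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _inside_nucleus(spec: NucleusSpec, x: float, y: float, margin: float = 0.0) -> bool:
    dx, dy = x - spec.centre_px[0], y - spec.centre_px[1]
    c, s = math.cos(spec.orientation_rad), math.sin(spec.orientation_rad)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    a = max(spec.semi_axes_px[0] - margin, 1.0)
    b = max(spec.semi_axes_px[1] - margin, 1.0)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_field(
    truth: GroundTruth, shape: tuple[int, int, int]
) -> tuple[ImageStack, ImageStack]:
    """Render the (nuclear, focus) channel stacks for one field of view.

    ``shape`` is (slices, rows, cols).  The nuclear channel is the sum of
    filled nucleus ellipses, constant across z; the focus channel is the
    background plus every focus's 3D Gaussian clipped to its nucleus
    footprint.  Noise follows the truth's noise model; both channels are
    clipped and quantised to the truth's bit depth.  Deterministic given
    ``truth.seed``.
    """
    n_z, n_rows, n_cols = shape
    rng = np.random.default_rng(truth.seed)

    footprints = [_nucleus_footprint(n, (n_rows, n_cols)) for n in truth.nuclei]
    for f in truth.foci:
        if not (0 <= f.nucleus_index < len(truth.nuclei)):
            raise ValueError(f"focus references nucleus {f.nucleus_index} which does not exist")
        if not _inside_nucleus(truth.nuclei[f.nucleus_index], f.centre_3d_px[0], f.centre_3d_px[1]):
            raise ValueError(f"focus centre {f.centre_3d_px} lies outside its nucleus")

    nuclear = np.zeros((n_z, n_rows, n_cols), dtype=np.float64)
    nuc2d = np.zeros((n_rows, n_cols), dtype=np.float64)
    for spec, fp in zip(truth.nuclei, footprints):
        nuc2d[fp] += spec.intensity
    nuclear += nuc2d  # constant across z
    nuclear += truth.noise.background_level / 4.0  # faint non-specific background

    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    gx, gy = truth.noise.background_gradient
    background = truth.noise.background_level + gx * cols + gy * rows
    focus = np.broadcast_to(background, (n_z, n_rows, n_cols)).astype(np.float64).copy()

    for f in truth.foci:
        x0, y0, z0 = f.centre_3d_px
        s_xy, s_z = f.sigma_xy_px, f.sigma_z_slices
        half = max(3, int(math.ceil(4 * s_xy)))
        r0, r1 = max(0, int(y0) - half), min(n_rows, int(y0) + half + 1)
        c0, c1 = max(0, int(x0) - half), min(n_cols, int(x0) + half + 1)
        sub_r = rows[r0:r1, c0:c1]
        sub_c = cols[r0:r1, c0:c1]
        lateral = np.exp(-((sub_c - x0) ** 2 + (sub_r - y0) ** 2) / (2 * s_xy ** 2))
        axial = np.exp(-((np.arange(n_z) - z0) ** 2) / (2 * s_z ** 2))
        clip = footprints[f.nucleus_index][r0:r1, c0:c1]
        blob = f.peak_intensity * lateral * clip
        focus[:, r0:r1, c0:c1] += axial[:, None, None] * blob[None, :, :]

    max_val = 2 ** truth.bit_depth - 1

    def _finish(signal: np.ndarray) -> np.ndarray:
        out = signal
        if truth.noise.poisson:
            out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
        if truth.noise.gaussian_sd > 0:
            out = out + rng.normal(0.0, truth.noise.gaussian_sd, size=out.shape)
        return np.clip(np.rint(out), 0, max_val).astype(np.uint16)

    nuclear_stack = ImageStack(
        _finish(nuclear), bit_depth=truth.bit_depth,
        calibration=truth.calibration, channel_tag="nuclear", source_path="synthetic",
    )
    focus_stack = ImageStack(
        _finish(focus), bit_depth=truth.bit_depth,
        calibration=truth.calibration, channel_tag="focus", source_path="synthetic",
    )
    return nuclear_stack, focus_stack


def place_foci(
    nucleus: NucleusSpec,
    nucleus_index: int,
    k: int,
    sigma_choices_xy_px: list[float],
    sigma_z_slices: float,
    peak_intensity: float,
    z_range: tuple[float, float],
    rng: np.random.Generator,
    min_sep_factor: float = 3.0,
    max_tries: int = 20000,
) -> list[FocusSpec]:
    """Place ``k`` non-crowded foci inside a nucleus by dart throwing.

    Lateral sigmas are drawn uniformly from ``sigma_choices_xy_px``; a new
    centre is accepted only if its distance to every accepted centre is at
    least ``min_sep_factor * max(sigma_i, sigma_j)`` and it lies at least
    ``min_sep_factor * sigma`` inside the nucleus boundary.
    """
    placed: list[FocusSpec] = []
    tries = 0
    while len(placed) < k:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {k} foci after {max_tries} attempts")
        sigma = float(rng.choice(sigma_choices_xy_px))
        a, b = nucleus.semi_axes_px
        x = nucleus.centre_px[0] + rng.uniform(-a, a)
        y = nucleus.centre_px[1] + rng.uniform(-b, b)
        if not _inside_nucleus(nucleus, x, y, margin=min_sep_factor * sigma):
            continue
        ok = True
        for p in placed:
            lim = min_sep_factor * max(sigma, p.sigma_xy_px)
            if math.hypot(x - p.centre_3d_px[0], y - p.centre_3d_px[1]) < lim:
                ok = False
                break
        if not ok:
            continue
        z = rng.uniform(*z_range)
        placed.append(
            FocusSpec(
                nucleus_index=nucleus_index,
                centre_3d_px=(float(x), float(y), float(z)),
                sigma_xy_px=sigma,
                sigma_z_slices=sigma_z_slices,
                peak_intensity=peak_intensity,
            )
        )
    return placed


#: lateral sigmas (px) whose FWHM at 0.07 um/px is 0.3, 0.7 and 1.5 um
SIGMA_SMALL_PX = 0.3 / FWHM_PER_SIGMA / 0.07
SIGMA_MEDIUM_PX = 0.7 / FWHM_PER_SIGMA / 0.07
SIGMA_LARGE_PX = 1.5 / FWHM_PER_SIGMA / 0.07


def default_truth(
    k_foci: int,
    seed: int,
    shape: tuple[int, int, int] = (22, 512, 512),
    sigma_choices_xy_px: list[float] | None = None,
    sigma_z_slices: float = 1.0,
    peak_intensity: float = 2000.0,
) -> GroundTruth:
    """A one-nucleus field in the standard acquisition geometry.

    22 slices, 14-bit, 0.07 um/pixel and 0.5 um z-step by default, with a
    single elliptical nucleus filling most of the frame and ``k_foci``
    well-separated foci whose lateral FWHMs are drawn from the three size
    classes (0.3, 0.7 and 1.5 um).  Peak intensity 2000 counts over a
    background of 400 gives a signal-to-noise ratio far above 5 under the
    default shot + read noise model.
    """
    n_z, n_rows, n_cols = shape
    rng = np.random.default_rng(seed)
    nucleus = NucleusSpec(
        centre_px=(n_cols / 2.0, n_rows / 2.0),
        semi_axes_px=(0.40 * n_cols, 0.33 * n_rows),
        orientation_rad=float(rng.uniform(0, math.pi)),
    )
    if sigma_choices_xy_px is None:
        sigma_choices_xy_px = [SIGMA_SMALL_PX, SIGMA_MEDIUM_PX, SIGMA_LARGE_PX]
    z_margin = min(4.0, 0.25 * (n_z - 1))
    foci = place_foci(
        nucleus, 0, k_foci, sigma_choices_xy_px, sigma_z_slices,
        peak_intensity, z_range=(z_margin, n_z - 1 - z_margin), rng=rng,
    )
    return GroundTruth(nuclei=[nucleus], foci=foci, seed=seed)


def write_field(truth: GroundTruth, folder: str | Path,
                shape: tuple[int, int, int]) -> tuple[Path, Path]:
    """Render a field and write it in the on-disk layout real data uses.

    One folder per field with ``dapi_z*.tif`` and ``rif_z*.tif`` series plus
    a ``truth.json`` sidecar.  Returns (folder, sidecar path).
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    nuclear, focus = render_field(truth, shape)
    write_stack(nuclear, folder)
    write_stack(focus, folder)
    sidecar = folder / "truth.json"
    sidecar.write_text(truth.to_json())
    return folder, sidecar


def render_linking_cases() -> dict[str, dict]:
    """Canonical two-slice linking cases with expected 3D focus counts.

    ``centre_inside``: the upper focus's centre falls within the lower
    focus's area -> one 3D focus.  ``centre_outside``: the two regions
    overlap but neither centre falls inside the other -> two foci.
    ``z_gap``: coaxial regions separated by an empty slice -> two foci.
    Each case maps to ``{"masks": [per-slice boolean rasters],
    "expected_count": int}``.
    """

    def blank():
        return np.zeros((24, 24), dtype=bool)

    def disc(mask, cx, cy, r):
        rows, cols = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
        mask |= (cols - cx) ** 2 + (rows - cy) ** 2 <= r * r
        return mask

    # A: big disc below, small disc above shifted but centre still inside
    a0 = disc(blank(), 11, 11, 6)
    a1 = disc(blank(), 14, 11, 3)  # centre (14, 11) inside the r=6 disc at (11, 11)
    # B: two equal discs overlapping, centres mutually outside
    b0 = disc(blank(), 8, 11, 4)
    b1 = disc(blank(), 15, 11, 4)  # centres 7 px apart, radius 4: overlap, no containment
    # gap: coaxial discs on slices 0 and 2, slice 1 empty
    g0 = disc(blank(), 11, 11, 4)
    g2 = disc(blank(), 11, 11, 4)

    return {
        "centre_inside": {"masks": [a0, a1], "expected_count": 1},
        "centre_outside": {"masks": [b0, b1], "expected_count": 2},
        "z_gap": {"masks": [g0, blank(), g2], "expected_count": 2},
    }


def score_against_truth(
    results: list[Focus3D],
    truth: GroundTruth,
    match_radius_um: float = 0.5,
    detected_origin_px: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """Score detected 3D foci against the generator's ground truth.

    Greedy nearest-neighbour matching in 3D (um) within ``match_radius_um``:
    closest pairs are matched first, each focus at most once.  Detected
    centroids measured in a cropped frame are shifted back to the field
    frame with ``detected_origin_px`` = (col, row) of the crop origin.
    Returns a dict with ``count_error`` (detected - true), ``n_matched``,
    ``localisation_rmse_um`` plus per-axis pixel/slice RMSEs, and a 3x3
    ``size_confusion`` matrix (rows = true small/medium/large, cols =
    detected).
    """
    cal = truth.calibration
    true_pts = np.array(
        [
            (
                f.centre_3d_px[0] * cal.pixel_scale_um,
                f.centre_3d_px[1] * cal.pixel_scale_um,
                f.centre_3d_px[2] * cal.z_step_um,
            )
            for f in truth.foci
        ]
    ).reshape(-1, 3)
    off = np.array([
        detected_origin_px[0] * cal.pixel_scale_um,
        detected_origin_px[1] * cal.pixel_scale_um,
        0.0,
    ])
    det_pts = np.array([f.centroid_3d_um for f in results]).reshape(-1, 3) + off

    pairs = []
    for i in range(true_pts.shape[0]):
        for j in range(det_pts.shape[0]):
            d = float(np.linalg.norm(true_pts[i] - det_pts[j]))
            if d <= match_radius_um:
                pairs.append((d, i, j))
    pairs.sort()
    used_t, used_d, matches = set(), set(), []
    for d, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        matches.append((i, j, d))

    cats = ["small", "medium", "large"]
    confusion = np.zeros((3, 3), dtype=int)
    err_sq = np.zeros(3)
    for i, j, _ in matches:
        delta = det_pts[j] - true_pts[i]
        err_sq += delta ** 2
        confusion[
            cats.index(truth.focus_size_category(truth.foci[i])),
            cats.index(results[j].size_category),
        ] += 1
    n = max(len(matches), 1)
    rmse_axes = np.sqrt(err_sq / n)
    return {
        "count_error": len(results) - len(truth.foci),
        "n_true": len(truth.foci),
        "n_detected": len(results),
        "n_matched": len(matches),
        "localisation_rmse_um": float(np.sqrt(err_sq.sum() / n)),
        "rmse_x_px": float(rmse_axes[0] / cal.pixel_scale_um),
        "rmse_y_px": float(rmse_axes[1] / cal.pixel_scale_um),
        "rmse_z_slices": float(rmse_axes[2] / cal.z_step_um),
        "size_confusion": confusion,
    }
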