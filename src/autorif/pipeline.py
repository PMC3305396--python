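"""End-to-end orchestration: batch optimisation, experiment runs, reports.

An experiment is a root folder containing one sub-folder per field of
view, each holding the two TIFF z-series.  ``run_experiment`` reads every
field, segments nuclei on the DAPI channel, runs the focus filter chain on
every retained nucleus, measures and links foci, and writes three CSV
tables (per-focus, per-nucleus, distances) plus a run log and the resolved
configuration for provenance.

``optimise_batch`` mirrors the pre-run settings scan: a seeded ~10% sample
of nuclei is processed under every grid point of candidate filter
settings, each scored by a salt-and-pepper count (1-pixel binary
components, the hallmark of under-filtering) and by the drift in focus
count relative to the lightest setting (a proxy for morphology
distortion); the recommended setting is the one with the fewest total
iterations whose salt-and-pepper score stays under a cap.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import Calibration, ImageStack, read_stack, CHANNEL_PATTERNS, MissingDataError
from .nucleus_segmentation import (
    DEFAULT_MIN_NUCLEUS_PX,
    NucleusRegion,
    crop_nucleus,
    segment_nuclei,
)
from .focus_filtering import (
    FilterSettings,
    analysis_mask,
    build_global_histogram,
    detect_foci_masks,
    filter_stack,
)
from .focus_geometry import measure_slice_foci
from .reconstruction_3d import Focus3D, pairwise_distances, reconstruct_3d

__all__ = [
    "RunConfig",
    "ExperimentResults",
    "optimise_batch",
    "run_experiment",
    "write_reports",
    "write_contact_sheet",
]

log = logging.getLogger(__name__)

FOCI_COLUMNS = [
    "field", "nucleus_label", "focus_id", "x_um", "y_um", "z_um", "z_extent",
    "area_px_max", "volume_um3", "volume_ellipsoid_um3", "equivalent_diameter_um",
    "size_category", "theta_rad", "ecc_ratio", "axis_ratio", "r_a_um", "r_b_um",
    "mean_intensity", "integrated_intensity",
]
NUCLEI_COLUMNS = [
    "field", "nucleus_label", "area_px", "centroid_x_px", "centroid_y_px",
    "excluded", "exclusion_reason", "n_foci", "n_small", "n_medium", "n_large",
]
DISTANCE_COLUMNS = ["field", "nucleus_label", "focus_id_a", "focus_id_b", "distance_um"]


@dataclass
class RunConfig:
    """Resolved configuration of one processing run."""

    input_root: Path
    output_dir: Path
    filter_settings: FilterSettings = field(default_factory=FilterSettings)
    calibration: Calibration = field(default_factory=Calibration)
    min_nucleus_px: int = DEFAULT_MIN_NUCLEUS_PX
    channel_patterns: dict = field(default_factory=lambda: dict(CHANNEL_PATTERNS))
    optimisation_fraction: float = 0.10
    seed: int = 0  # used only for batch-optimisation sampling

    def __post_init__(self) -> None:
        self.input_root = Path(self.input_root)
        self.output_dir = Path(self.output_dir)
        if not (0 < self.optimisation_fraction <= 1):
            raise ValueError("optimisation_fraction must be in (0, 1]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["input_root"] = str(self.input_root)
        d["output_dir"] = str(self.output_dir)
        return json.dumps(d, indent=1)


@dataclass
class ExperimentResults:
    foci: pd.DataFrame
    nuclei: pd.DataFrame
    distances: pd.DataFrame
    log_lines: list[str]


def _discover_fields(root: Path) -> list[Path]:
    fields = sorted(
        p for p in root.iterdir()
        if p.is_dir() and any(f.suffix.lower() in (".tif", ".tiff") for f in p.iterdir())
    )
    return fields


def _read_field(config: RunConfig, folder: Path) -> tuple[ImageStack, ImageStack]:
    nuclear = read_stack(
        folder, "nuclear", config.calibration, pattern=config.channel_patterns["nuclear"]
    )
    focus = read_stack(
        folder, "focus", config.calibration, pattern=config.channel_patterns["focus"]
    )
    return nuclear, focus


def _nuclear_centre_um(nucleus: NucleusRegion, stack: ImageStack) -> tuple[float, float, float]:
    """Nuclear centre: 2D mask centroid laterally, z-range midpoint axially."""
    cal = stack.calibration
    cx, cy = nucleus.centroid_xy
    zc = (stack.n_slices - 1) / 2.0
    return (cx * cal.pixel_scale_um, cy * cal.pixel_scale_um, zc * cal.z_step_um)


def process_nucleus(
    focus_stack: ImageStack,
    nucleus: NucleusRegion,
    settings: FilterSettings,
    external_histogram=None,
) -> list[Focus3D]:
    """Detect, measure and 3D-link foci for one retained nucleus."""
    crop, mask_crop = crop_nucleus(focus_stack, nucleus)
    masks = detect_foci_masks(crop, mask_crop, settings, external_histogram)
    slice_foci = measure_slice_foci(masks, crop, nucleus_label=nucleus.label)
    return reconstruct_3d(slice_foci, focus_stack.calibration)


def run_experiment(config: RunConfig) -> ExperimentResults:
    """Process every field under ``config.input_root``.

    Unreadable folders are skipped with a logged error; fields in which
    every nucleus is excluded contribute nucleus rows but no foci.  With
    ``histogram_scope='folder'`` the Kapur threshold for each field is
    computed from the pooled histogram of all its retained nuclei.
    """
    fields = _discover_fields(config.input_root)
    if not fields:
        raise MissingDataError(f"no field folders under {config.input_root}")

    settings = config.filter_settings
    foci_rows, nuclei_rows, dist_frames, log_lines = [], [], [], []
    cal = config.calibration

    for folder in fields:
        try:
            nuclear_stack, focus_stack = _read_field(config, folder)
        except (MissingDataError, ValueError) as exc:
            log.error("skipping field %s: %s", folder.name, exc)
            log_lines.append(f"field {folder.name}: SKIPPED ({exc})")
            continue

        regions = segment_nuclei(nuclear_stack, config.min_nucleus_px)
        kept = [r for r in regions if not r.excluded]
        for r in regions:
            if r.excluded:
                log_lines.append(
                    f"field {folder.name}: nucleus {r.label} excluded ({r.exclusion_reason})"
                )

        external = None
        crops = {}
        if settings.histogram_scope == "folder" and kept:
            filtered, masks = [], []
            for r in kept:
                crop, mcrop = crop_nucleus(focus_stack, r)
                crops[r.label] = (crop, mcrop)
                filtered.append(filter_stack(crop.data, settings))
                masks.append(analysis_mask(mcrop, settings))
            external = build_global_histogram(filtered, masks)

        for r in kept:
            if r.label in crops:
                crop, mcrop = crops[r.label]
            else:
                crop, mcrop = crop_nucleus(focus_stack, r)
            masks3 = detect_foci_masks(crop, mcrop, settings, external)
            slice_foci = measure_slice_foci(masks3, crop, nucleus_label=r.label)
            foci3d = reconstruct_3d(slice_foci, cal)

            # crop-frame -> field-frame offset for reported coordinates
            r0, c0 = r.bbox[0], r.bbox[1]
            off_x, off_y = c0 * cal.pixel_scale_um, r0 * cal.pixel_scale_um
            counts = {"small": 0, "medium": 0, "large": 0}
            for f in foci3d:
                counts[f.size_category] += 1
                biggest = max(f.members, key=lambda m: m.area_px)
                foci_rows.append(
                    {
                        "field": folder.name,
                        "nucleus_label": r.label,
                        "focus_id": f.focus_id,
                        "x_um": f.centroid_3d_um[0] + off_x,
                        "y_um": f.centroid_3d_um[1] + off_y,
                        "z_um": f.centroid_3d_um[2],
                        "z_extent": f.z_extent,
                        "area_px_max": f.max_slice_area_px,
                        "volume_um3": f.volume_um3,
                        "volume_ellipsoid_um3": f.volume_ellipsoid_um3,
                        "equivalent_diameter_um": f.equivalent_diameter_um,
                        "size_category": f.size_category,
                        "theta_rad": biggest.theta_rad,
                        "ecc_ratio": biggest.ecc_ratio,
                        "axis_ratio": (
                            biggest.radii_px[0] / biggest.radii_px[1]
                            if biggest.radii_px[1] > 0 else math.inf
                        ),
                        "r_a_um": biggest.radii_px[0] * cal.pixel_scale_um,
                        "r_b_um": biggest.radii_px[1] * cal.pixel_scale_um,
                        "mean_intensity": f.mean_intensity,
                        "integrated_intensity": f.integrated_intensity,
                    }
                )
            centre = _nuclear_centre_um(r, focus_stack)
            centre_crop = (centre[0] - off_x, centre[1] - off_y, centre[2])
            dists = pairwise_distances(foci3d, centre_crop, nucleus_label=r.label)
            dists.insert(0, "field", folder.name)
            dist_frames.append(dists)
            nuclei_rows.append(
                {
                    "field": folder.name, "nucleus_label": r.label, "area_px": r.area_px,
                    "centroid_x_px": r.centroid_xy[0], "centroid_y_px": r.centroid_xy[1],
                    "excluded": False, "exclusion_reason": "none",
                    "n_foci": len(foci3d), "n_small": counts["small"],
                    "n_medium": counts["medium"], "n_large": counts["large"],
                }
            )
        for r in regions:
            if r.excluded:
                nuclei_rows.append(
                    {
                        "field": folder.name, "nucleus_label": r.label, "area_px": r.area_px,
                        "centroid_x_px": r.centroid_xy[0], "centroid_y_px": r.centroid_xy[1],
                        "excluded": True, "exclusion_reason": r.exclusion_reason,
                        "n_foci": 0, "n_small": 0, "n_medium": 0, "n_large": 0,
                    }
                )
        log_lines.append(
            f"field {folder.name}: {len(kept)} nuclei retained, "
            f"{len(regions) - len(kept)} excluded"
        )

    foci = pd.DataFrame(foci_rows, columns=FOCI_COLUMNS)
    nuclei = pd.DataFrame(nuclei_rows, columns=NUCLEI_COLUMNS)
    distances = (
        pd.concat(dist_frames, ignore_index=True)
        if dist_frames else pd.DataFrame(columns=DISTANCE_COLUMNS)
    )
    distances = distances.reindex(columns=DISTANCE_COLUMNS)
    return ExperimentResults(foci=foci, nuclei=nuclei, distances=distances, log_lines=log_lines)


def write_reports(results: ExperimentResults, output_dir: str | Path,
                  config: RunConfig | None = None) -> dict[str, Path]:
    """Write foci.csv, nuclei.csv, distances.csv, run.log (and the config).

    CSVs are UTF-8 with RFC-4180 quoting; floats carry enough digits to
    round-trip to 6 significant figures.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("foci", results.foci), ("nuclei", results.nuclei), ("distances", results.distances)
    ):
        path = output_dir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.8g", lineterminator="\n")
        paths[name] = path
    log_path = output_dir / "run.log"
    log_path.write_text("\n".join(results.log_lines) + "\n")
    paths["log"] = log_path
    if config is not None:
        cfg_path = output_dir / "config.json"
        cfg_path.write_text(config.to_json())
        paths["config"] = cfg_path
    return paths


# ---------------------------------------------------------------------------
# batch optimisation


def _salt_and_pepper_score(masks: list[np.ndarray]) -> int:
    """Number of 1-pixel binary components across all slices of one nucleus."""
    eight = np.ones((3, 3), dtype=bool)
    count = 0
    for m in masks:
        labels, n = ndimage.label(m, structure=eight)
        if n:
            sizes = np.bincount(labels.ravel())[1:]
            count += int((sizes == 1).sum())
    return count


def optimise_batch(
    config: RunConfig,
    grid: dict,
    salt_pepper_cap: float = 2.0,
    preview_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Scan candidate filter settings on a seeded sample of nuclei.

    ``grid`` maps ``pre_iterations``, ``post_iterations`` and
    ``sensitivity`` to lists of candidate values.  About
    ``config.optimisation_fraction`` of all nuclei (at least one per
    field sampled, seeded) are processed under every grid point.  Each
    point is scored by its mean salt-and-pepper count per nucleus
    (1-pixel components; min_focus_px filtering is disabled for scoring so
    under-filtering is visible) and its mean absolute focus-count change
    versus the lightest setting.  The returned table is ranked: settings
    whose salt-and-pepper score is at most ``salt_pepper_cap`` come first,
    ordered by total iterations, then by score; row 0 is the
    recommendation.  When ``preview_dir`` is set, the central-slice binary
    mask of the first sampled nucleus is saved per grid point.
    """
    pres = list(grid.get("pre_iterations", [config.filter_settings.pre_iterations]))
    posts = list(grid.get("post_iterations", [config.filter_settings.post_iterations]))
    senss = list(grid.get("sensitivity", [config.filter_settings.laplacian_sensitivity]))
    if not (pres and posts and senss):
        raise ValueError("grid must contain at least one candidate per dimension")

    fields = _discover_fields(config.input_root)
    if not fields:
        raise MissingDataError(f"no field folders under {config.input_root}")

    # collect all retained nuclei across fields, then take a seeded sample
    pool = []
    for folder in fields:
        try:
            nuclear_stack, focus_stack = _read_field(config, folder)
        except (MissingDataError, ValueError) as exc:
            log.error("skipping field %s: %s", folder.name, exc)
            continue
        for r in segment_nuclei(nuclear_stack, config.min_nucleus_px, include_excluded=False):
            pool.append((folder.name, focus_stack, r))
    if not pool:
        raise MissingDataError("no retained nuclei found for batch optimisation")

    rng = np.random.default_rng(config.seed)
    n_sample = max(1, int(round(config.optimisation_fraction * len(pool))))
    sample_idx = sorted(rng.choice(len(pool), size=n_sample, replace=False).tolist())
    sample = [pool[i] for i in sample_idx]

    rows = []
    counts_by_setting = {}
    for sens in senss:
        for pre in sorted(pres):
            for post in sorted(posts):
                settings = dataclasses.replace(
                    config.filter_settings,
                    pre_iterations=pre, post_iterations=post,
                    laplacian_sensitivity=sens, min_focus_px=1,
                )
                sp_scores, counts = [], []
                for k, (field_name, focus_stack, r) in enumerate(sample):
                    crop, mcrop = crop_nucleus(focus_stack, r)
                    masks = detect_foci_masks(crop, mcrop, settings)
                    sp_scores.append(_salt_and_pepper_score(masks))
                    slice_foci = measure_slice_foci(masks, crop, nucleus_label=r.label)
                    counts.append(len(reconstruct_3d(slice_foci, config.calibration)))
                    if k == 0 and preview_dir is not None:
                        _save_preview(masks, preview_dir, sens, pre, post)
                counts_by_setting[(sens, pre, post)] = counts
                rows.append(
                    {
                        "sensitivity": sens, "pre_iterations": pre, "post_iterations": post,
                        "total_iterations": pre + post,
                        "salt_pepper_per_nucleus": float(np.mean(sp_scores)),
                        "mean_focus_count": float(np.mean(counts)),
                        "n_nuclei_sampled": len(sample),
                    }
                )

    report = pd.DataFrame(rows)
    # morphology-distortion proxy: focus-count drift vs the lightest setting scanned
    lightest = min(counts_by_setting, key=lambda k: (k[1] + k[2], k[1]))
    base = np.asarray(counts_by_setting[lightest], dtype=float)
    report["count_drift_vs_lightest"] = [
        float(np.mean(np.abs(np.asarray(counts_by_setting[(s, p, q)], dtype=float) - base)))
        for s, p, q in zip(report["sensitivity"], report["pre_iterations"],
                           report["post_iterations"])
    ]
    report["acceptable"] = report["salt_pepper_per_nucleus"] <= salt_pepper_cap
    # a setting under which detection collapses entirely while others find
    # foci is itself an under-filtering artefact (noise swamps the
    # histogram); such settings rank below detecting ones
    report["detects_foci"] = report["mean_focus_count"] > 0
    report = report.sort_values(
        by=["acceptable", "detects_foci", "total_iterations", "salt_pepper_per_nucleus"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return report


def write_contact_sheet(config: RunConfig, out_path: str | Path,
                        max_fields: int = 25) -> Path:
    """Save a grid of nuclear-channel MIPs for pre-analysis screening.

    One panel per field (up to ``max_fields``), annotated with the field
    name — a quick way to spot poorly stained or overlapping nuclei that
    should be excluded before batch processing.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .image_io import max_intensity_projection

    fields = _discover_fields(config.input_root)[:max_fields]
    if not fields:
        raise MissingDataError(f"no field folders under {config.input_root}")
    n = len(fields)
    cols = int(math.ceil(math.sqrt(n)))
    rows_n = int(math.ceil(n / cols))
    fig, axes = plt.subplots(rows_n, cols, figsize=(3 * cols, 3 * rows_n), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, folder in zip(axes.ravel(), fields):
        try:
            nuclear = read_stack(folder, "nuclear", config.calibration,
                                 pattern=config.channel_patterns["nuclear"])
        except (MissingDataError, ValueError) as exc:
            ax.set_title(f"{folder.name}: unreadable", fontsize=8)
            log.error("contact sheet: %s (%s)", folder.name, exc)
            continue
        ax.imshow(max_intensity_projection(nuclear), cmap="gray")
        ax.set_title(folder.name, fontsize=8)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return out_path


def _save_preview(masks: list[np.ndarray], preview_dir: str | Path,
                  sens: str, pre: int, post: int) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    preview_dir = Path(preview_dir)
    preview_dir.mkdir(parents=True, exist_ok=True)
    mid = masks[len(masks) // 2]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(mid, cmap="gray", interpolation="nearest")
    ax.set_title(f"{sens} pre={pre} post={post}")
    ax.axis("off")
    fig.savefig(preview_dir / f"preview_{sens}_pre{pre}_post{post}.png",
                dpi=120, bbox_inches="tight")
    plt.close(fig)
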