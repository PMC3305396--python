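"""Linking of per-slice foci into 3D foci and derived 3D measurements.

Two foci on adjacent z-slices belong to the same 3D focus when the rounded
centroid of either lies within the binary pixel region of the other; foci
that overlap in x/y but are separated by a slice with no focus remain
independent.  The transitive closure of this predicate over adjacent-slice
pairs (union-find) partitions the slice foci into 3D chains.  Each chain
gets an area-weighted 3D centroid, a voxel-sum volume, an
equivalent-circle diameter from its largest slice area (mirroring the
manual convention of sizing a focus on its most in-focus plane), a
small/medium/large size category, and raw-channel intensity totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .image_io import Calibration
from .focus_geometry import SliceFocus

__all__ = [
    "Focus3D",
    "link_predicate",
    "reconstruct_3d",
    "weighted_centroid_3d",
    "volume_and_size",
    "size_category",
    "pairwise_distances",
    "SIZE_EDGES_UM",
]

#: size-category bin edges in um: small d < 0.5, medium 0.5 <= d <= 1.0, large d > 1.0
SIZE_EDGES_UM = (0.5, 1.0)


@dataclass
class Focus3D:
    """A chain of z-linked slice foci forming one 3D focus."""

    focus_id: int
    members: list[SliceFocus]
    centroid_3d_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    volume_um3: float = 0.0
    volume_ellipsoid_um3: float = 0.0
    max_slice_area_px: int = 0
    equivalent_diameter_um: float = 0.0
    size_category: str = ""
    integrated_intensity: float = 0.0
    mean_intensity: float = 0.0
    junction: bool = False  # True when linking merged a branching (Y-shaped) chain

    @property
    def z_extent(self) -> int:
        return len(self.members)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def link_predicate(f1: SliceFocus, f2: SliceFocus) -> bool:
    """Containment linking rule for foci on adjacent slices.

    True iff the centroid of either focus, rounded to the nearest pixel,
    lies within the other focus's binary pixel region.  The two foci must
    sit on consecutive z-indices of the same nucleus.
    """
    if abs(f1.z_index - f2.z_index) != 1:
        raise ValueError("link predicate applies to foci on adjacent z-slices only")
    if f1.nucleus_label != f2.nucleus_label:
        raise ValueError("link predicate applies within one nucleus only")
    c1 = (_round_half_up(f1.centroid_px[0]), _round_half_up(f1.centroid_px[1]))
    c2 = (_round_half_up(f2.centroid_px[0]), _round_half_up(f2.centroid_px[1]))
    return c1 in f2.pixel_set or c2 in f1.pixel_set


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def reconstruct_3d(
    slice_foci: list[SliceFocus],
    calibration: Calibration | None = None,
) -> list[Focus3D]:
    """Partition slice foci of one nucleus into 3D foci.

    Links are tested only between consecutive z-indices, so a z-gap always
    separates chains; a branching junction (one focus linked to two
    unlinked foci on the next slice) is merged by transitive closure and
    flagged on the resulting focus.  Every slice focus ends up in exactly
    one chain.  When a calibration is given, all derived 3D measurements
    are filled in.
    """
    n = len(slice_foci)
    uf = _UnionFind(n)
    by_z: dict[int, list[int]] = {}
    for i, f in enumerate(slice_foci):
        by_z.setdefault(f.z_index, []).append(i)

    links_of: dict[int, int] = {i: 0 for i in range(n)}
    for z, idxs in sorted(by_z.items()):
        for i in idxs:
            for j in by_z.get(z + 1, []):
                if (slice_foci[i].nucleus_label == slice_foci[j].nucleus_label
                        and link_predicate(slice_foci[i], slice_foci[j])):
                    uf.union(i, j)
                    links_of[i] += 1
                    links_of[j] += 1

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    foci: list[Focus3D] = []
    # deterministic order: by (z of first member, then raster order of measurement)
    ordered = sorted(groups.values(), key=lambda idxs: min(idxs))
    for fid, idxs in enumerate(ordered, start=1):
        members = sorted((slice_foci[i] for i in idxs), key=lambda f: f.z_index)
        # a member with >2 links (or >1 at the chain end) marks a branch merge
        junction = len(idxs) > len({slice_foci[i].z_index for i in idxs}) or any(
            links_of[i] > 2 for i in idxs
        )
        focus = Focus3D(focus_id=fid, members=members, junction=junction)
        if calibration is not None:
            _finalise(focus, calibration)
        foci.append(focus)
    return foci


def weighted_centroid_3d(
    focus: Focus3D, calibration: Calibration
) -> tuple[float, float, float]:
    """Area-weighted 3D centroid in micrometres.

    x and y are the area-weighted means of the member centroids, z the
    area-weighted mean of the member z-indices (weight = member pixel
    count, the same mass concept as the 2D centroid); the result is scaled
    by the pixel scale laterally and the z-step axially.
    """
    w = np.array([m.area_px for m in focus.members], dtype=np.float64)
    xs = np.array([m.centroid_px[0] for m in focus.members])
    ys = np.array([m.centroid_px[1] for m in focus.members])
    zs = np.array([m.z_index for m in focus.members], dtype=np.float64)
    total = w.sum()
    px, dz = calibration.pixel_scale_um, calibration.z_step_um
    return (
        float((w * xs).sum() / total * px),
        float((w * ys).sum() / total * px),
        float((w * zs).sum() / total * dz),
    )


def size_category(equivalent_diameter_um: float) -> str:
    """Small/medium/large size bin: d < 0.5, 0.5 <= d <= 1.0, d > 1.0 um."""
    lo, hi = SIZE_EDGES_UM
    if equivalent_diameter_um < lo:
        return "small"
    if equivalent_diameter_um <= hi:
        return "medium"
    return "large"


def volume_and_size(
    focus: Focus3D, calibration: Calibration
) -> tuple[float, float, str]:
    """Voxel-sum volume, equivalent-circle diameter and size category.

    Volume is the sum of member slice areas times the voxel footprint
    (pixel_scale^2 * z_step).  The equivalent diameter is that of a circle
    with the area of the largest member slice, 2*sqrt(A_max * px^2 / pi) —
    the focus sized on its most in-focus plane.
    """
    px, dz = calibration.pixel_scale_um, calibration.z_step_um
    areas = [m.area_px for m in focus.members]
    volume = float(sum(areas)) * px * px * dz
    a_max = max(areas)
    d_eq = 2.0 * math.sqrt(a_max * px * px / math.pi)
    return volume, d_eq, size_category(d_eq)


def _ellipsoid_volume(focus: Focus3D, calibration: Calibration) -> float:
    """Secondary ellipsoid-model volume from the largest slice's fitted radii."""
    px, dz = calibration.pixel_scale_um, calibration.z_step_um
    biggest = max(focus.members, key=lambda m: m.area_px)
    r_a_um = biggest.radii_px[0] * px
    r_b_um = biggest.radii_px[1] * px
    half_depth = focus.z_extent * dz / 2.0
    return 4.0 / 3.0 * math.pi * r_a_um * r_b_um * half_depth


def _finalise(focus: Focus3D, calibration: Calibration) -> None:
    focus.centroid_3d_um = weighted_centroid_3d(focus, calibration)
    focus.volume_um3, focus.equivalent_diameter_um, focus.size_category = volume_and_size(
        focus, calibration
    )
    focus.volume_ellipsoid_um3 = _ellipsoid_volume(focus, calibration)
    focus.max_slice_area_px = max(m.area_px for m in focus.members)
    integrated = sum(m.integrated_raw_intensity for m in focus.members)
    n_px = sum(m.area_px for m in focus.members)
    focus.integrated_intensity = float(integrated)
    focus.mean_intensity = float(integrated / n_px)


def pairwise_distances(
    foci: list[Focus3D],
    nuclear_centre_um: tuple[float, float, float],
    nucleus_label: int = 1,
) -> pd.DataFrame:
    """Euclidean distances between all focus pairs and to the nuclear centre.

    Returns a table with columns (nucleus_label, focus_id_a, focus_id_b,
    distance_um); the nuclear centre appears as partner ``"CENTRE"``.
    Distances are symmetric and each unordered pair is listed once.
    """
    rows = []
    for fa, fb in combinations(foci, 2):
        d = math.dist(fa.centroid_3d_um, fb.centroid_3d_um)
        rows.append((nucleus_label, fa.focus_id, str(fb.focus_id), d))
    for f in foci:
        d = math.dist(f.centroid_3d_um, nuclear_centre_um)
        rows.append((nucleus_label, f.focus_id, "CENTRE", d))
    return pd.DataFrame(
        rows, columns=["nucleus_label", "focus_id_a", "focus_id_b", "distance_um"]
    )
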