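"""3D linking of slice foci, weighted centroids, volumes, distances."""

import math

import numpy as np
import pytest

from autorif import (
    Calibration,
    link_predicate,
    measure_slice_foci,
    pairwise_distances,
    reconstruct_3d,
    size_category,
    volume_and_size,
    weighted_centroid_3d,
)
from autorif.focus_geometry import SliceFocus
from autorif.image_io import ImageStack
from autorif.reconstruction_3d import Focus3D
from autorif.synthetic_fixtures import render_linking_cases

CAL = Calibration()  # 0.07 um/px, 0.5 um z-step


def make_focus(z, pixels, nucleus_label=1):
    """SliceFocus from an explicit (u, v) pixel list; descriptors minimal."""
    pixels = np.asarray(pixels)
    cx, cy = pixels[:, 0].mean(), pixels[:, 1].mean()
    return SliceFocus(
        nucleus_label=nucleus_label, z_index=z, pixels=pixels,
        area_px=len(pixels), centroid_px=(float(cx), float(cy)),
        central_moments=(0.0, 0.0, 0.0), theta_rad=0.0, ecc_ratio=1.0,
        radii_px=(1.0, 1.0), mean_raw_intensity=10.0,
        integrated_raw_intensity=10.0 * len(pixels),
    )


def disc_pixels(cx, cy, r):
    pts = []
    for u in range(cx - r, cx + r + 1):
        for v in range(cy - r, cy + r + 1):
            if (u - cx) ** 2 + (v - cy) ** 2 <= r * r:
                pts.append((u, v))
    return pts


class TestLinkPredicate:
    def test_coincident_centres_link(self):
        f1 = make_focus(0, disc_pixels(10, 10, 4))
        f2 = make_focus(1, disc_pixels(10, 10, 2))
        assert link_predicate(f1, f2)

    def test_centre_inside_other_area_links(self):
        f1 = make_focus(0, disc_pixels(10, 10, 5))
        f2 = make_focus(1, disc_pixels(13, 10, 2))  # centre (13,10) inside r=5 disc
        assert link_predicate(f1, f2)

    def test_overlap_without_containment_does_not_link(self):
        f1 = make_focus(0, disc_pixels(8, 10, 4))
        f2 = make_focus(1, disc_pixels(15, 10, 4))  # overlap, centres outside
        assert not link_predicate(f1, f2)

    def test_disjoint_footprints_do_not_link(self):
        f1 = make_focus(0, disc_pixels(5, 5, 2))
        f2 = make_focus(1, disc_pixels(20, 20, 2))
        assert not link_predicate(f1, f2)

    def test_non_adjacent_slices_rejected(self):
        f1 = make_focus(0, disc_pixels(5, 5, 2))
        f2 = make_focus(2, disc_pixels(5, 5, 2))
        with pytest.raises(ValueError):
            link_predicate(f1, f2)

    def test_symmetric_in_arguments(self):
        big = make_focus(0, disc_pixels(10, 10, 5))
        small = make_focus(1, disc_pixels(13, 10, 2))
        assert link_predicate(big, small) == link_predicate(
            make_focus(0, small.pixels), make_focus(1, big.pixels)
        )


def transitive_closure_oracle(slice_foci):
    """Brute-force partition: BFS over the adjacent-slice link graph."""
    n = len(slice_foci)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if slice_foci[j].z_index == slice_foci[i].z_index + 1:
                if link_predicate(slice_foci[i], slice_foci[j]):
                    adj[i].append(j)
                    adj[j].append(i)
    seen, groups = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp, queue = {s}, [s]
        while queue:
            i = queue.pop()
            for j in adj[i]:
                if j not in comp:
                    comp.add(j)
                    queue.append(j)
        seen |= comp
        groups.append(frozenset(comp))
    return set(groups)


class TestReconstruct3D:
    def test_coaxial_chain_is_single_focus(self):
        foci = [make_focus(z, disc_pixels(10, 10, 3)) for z in (0, 1, 2)]
        out = reconstruct_3d(foci, CAL)
        assert len(out) == 1
        assert out[0].z_extent == 3

    def test_z_gap_separates(self):
        foci = [make_focus(0, disc_pixels(10, 10, 3)), make_focus(2, disc_pixels(10, 10, 3))]
        out = reconstruct_3d(foci, CAL)
        assert len(out) == 2

    def test_y_junction_merged_and_flagged(self):
        base = make_focus(0, disc_pixels(10, 10, 6))
        left = make_focus(1, disc_pixels(7, 10, 2))
        right = make_focus(1, disc_pixels(13, 10, 2))
        assert not link_predicate(left, make_focus(2, right.pixels))  # not mutually linked
        out = reconstruct_3d([base, left, right], CAL)
        assert len(out) == 1
        assert out[0].junction

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(10):
            foci = []
            for z in range(4):
                for _ in range(int(rng.integers(1, 4))):
                    cx, cy = int(rng.integers(5, 26)), int(rng.integers(5, 26))
                    foci.append(make_focus(z, disc_pixels(cx, cy, int(rng.integers(2, 5)))))
            ours = {
                frozenset(id(m) for m in f.members) for f in reconstruct_3d(foci, CAL)
            }
            oracle = {
                frozenset(id(foci[i]) for i in grp)
                for grp in transitive_closure_oracle(foci)
            }
            assert ours == oracle

    def test_partition_property(self, rng):
        foci = [
            make_focus(z, disc_pixels(int(rng.integers(5, 26)), int(rng.integers(5, 26)), 3))
            for z in range(5) for _ in range(2)
        ]
        out = reconstruct_3d(foci, CAL)
        assert sum(f.z_extent for f in out) == len(foci)
        ids = [id(m) for f in out for m in f.members]
        assert len(ids) == len(set(ids))

    def test_invariant_to_z_reversal(self):
        foci = [
            make_focus(0, disc_pixels(10, 10, 5)),
            make_focus(1, disc_pixels(12, 10, 3)),
            make_focus(2, disc_pixels(20, 20, 3)),
        ]
        flipped = [make_focus(2 - f.z_index, f.pixels.tolist()) for f in foci]
        a = sorted(f.z_extent for f in reconstruct_3d(foci, CAL))
        b = sorted(f.z_extent for f in reconstruct_3d(flipped, CAL))
        assert a == b


class TestCanonicalLinkingCases:
    def test_canonical_linking_truth_table(self):
        raw = ImageStack(np.full((3, 24, 24), 50, dtype=np.uint16), bit_depth=14)
        for name, case in render_linking_cases().items():
            masks = case["masks"]
            stack = raw.with_data(raw.data[: len(masks)])
            foci = measure_slice_foci(masks, stack)
            out = reconstruct_3d(foci, CAL)
            assert len(out) == case["expected_count"], name


class TestWeightedCentroid:
    def test_single_member_converts_units(self):
        f = Focus3D(1, [make_focus(4, disc_pixels(10, 12, 2))])
        x, y, z = weighted_centroid_3d(f, CAL)
        assert x == pytest.approx(10 * 0.07)
        assert y == pytest.approx(12 * 0.07)
        assert z == pytest.approx(4 * 0.5)

    def test_area_weighted_z(self):
        a = make_focus(4, disc_pixels(10, 10, 3))   # 29 px
        b = make_focus(5, disc_pixels(10, 10, 3))
        a.area_px, b.area_px = 30, 10
        f = Focus3D(1, [a, b])
        _, _, z = weighted_centroid_3d(f, CAL)
        assert z == pytest.approx((30 * 4 + 10 * 5) / 40 * 0.5)

    def test_symmetric_members_centre_z(self):
        ms = [make_focus(z, disc_pixels(10, 10, r)) for z, r in ((3, 2), (4, 4), (5, 2))]
        f = Focus3D(1, ms)
        _, _, z = weighted_centroid_3d(f, CAL)
        assert z == pytest.approx(4 * 0.5)

    def test_equals_voxel_union_centroid(self, rng):
        members = [make_focus(z, disc_pixels(10 + z, 10, 3)) for z in (2, 3, 4)]
        f = Focus3D(1, members)
        x, y, z = weighted_centroid_3d(f, CAL)
        vox = np.array([
            (u, v, m.z_index) for m in members for u, v in m.pixels
        ], dtype=float)
        assert x == pytest.approx(vox[:, 0].mean() * 0.07)
        assert y == pytest.approx(vox[:, 1].mean() * 0.07)
        assert z == pytest.approx(vox[:, 2].mean() * 0.5)


class TestVolumeAndSize:
    def test_hundred_pixel_single_slice(self):
        m = make_focus(3, [(u, v) for u in range(10) for v in range(10)])
        f = Focus3D(1, [m])
        vol, d, cat = volume_and_size(f, CAL)
        assert vol == pytest.approx(100 * 0.07 ** 2 * 0.5)  # 0.245 um^3
        assert d == pytest.approx(2 * math.sqrt(100 * 0.0049 / math.pi), rel=1e-9)
        assert cat == "medium"

    @pytest.mark.parametrize(
        "d,expected",
        [(0.4, "small"), (0.5, "medium"), (0.75, "medium"), (1.0, "medium"), (1.5, "large")],
    )
    def test_category_bin_edges(self, d, expected):
        assert size_category(d) == expected

    def test_volume_scales_with_pixel_area(self):
        m = make_focus(0, disc_pixels(5, 5, 3))
        f = Focus3D(1, [m])
        v1, _, _ = volume_and_size(f, CAL)
        v2, _, _ = volume_and_size(f, Calibration(pixel_scale_um=0.14, z_step_um=0.5))
        assert v2 == pytest.approx(4 * v1)

    def test_equivalent_diameter_uses_largest_slice(self):
        small = make_focus(0, disc_pixels(5, 5, 2))
        big = make_focus(1, disc_pixels(5, 5, 6))
        f = Focus3D(1, [small, big])
        _, d, _ = volume_and_size(f, CAL)
        expected = 2 * math.sqrt(big.area_px * 0.07 ** 2 / math.pi)
        assert d == pytest.approx(expected)


class TestPairwiseDistances:
    def _focus_at(self, fid, xyz):
        f = Focus3D(fid, [make_focus(0, disc_pixels(5, 5, 2))])
        f.centroid_3d_um = xyz
        return f

    def test_three_four_five(self):
        foci = [self._focus_at(1, (0, 0, 0)), self._focus_at(2, (3, 4, 0))]
        table = pairwise_distances(foci, (0, 0, 0))
        pair = table[table.focus_id_b != "CENTRE"]
        assert len(pair) == 1
        assert pair.distance_um.iloc[0] == pytest.approx(5.0)

    def test_single_focus_only_centre_row(self):
        table = pairwise_distances([self._focus_at(1, (1, 2, 2))], (1, 2, 0))
        assert len(table) == 1
        assert table.focus_id_b.iloc[0] == "CENTRE"
        assert table.distance_um.iloc[0] == pytest.approx(2.0)

    def test_matches_double_loop(self, rng):
        foci = [self._focus_at(i + 1, tuple(rng.uniform(0, 10, 3))) for i in range(6)]
        centre = tuple(rng.uniform(0, 10, 3))
        table = pairwise_distances(foci, centre)
        pairs = {
            (r.focus_id_a, r.focus_id_b): r.distance_um
            for r in table.itertuples()
        }
        for i, fa in enumerate(foci):
            for fb in foci[i + 1:]:
                expect = math.dist(fa.centroid_3d_um, fb.centroid_3d_um)
                assert pairs[(fa.focus_id, str(fb.focus_id))] == pytest.approx(expect)
            assert pairs[(fa.focus_id, "CENTRE")] == pytest.approx(
                math.dist(fa.centroid_3d_um, centre)
            )
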