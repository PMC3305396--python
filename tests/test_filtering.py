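"""The focus filter chain: smoothing, Laplacian, Crimmins, thresholding."""

import numpy as np
import pytest
from scipy import ndimage

from autorif import (
    FilterSettings,
    binarize_and_close,
    build_global_histogram,
    crimmins,
    detect_foci_masks,
    filter_stack,
    laplacian,
    presmooth,
)
from autorif.focus_filtering import IntHistogram, analysis_mask, class_separation
from autorif.nucleus_segmentation import crop_nucleus
from autorif import segment_nuclei

EIGHT = np.ones((3, 3), dtype=bool)


class TestPresmooth:
    def test_zero_iterations_is_identity(self, rng):
        img = rng.integers(0, 255, size=(9, 9)).astype(float)
        np.testing.assert_array_equal(presmooth(img, 0), img)

    def test_single_bright_pixel_spreads_to_mean(self):
        img = np.zeros((7, 7))
        img[3, 3] = 100.0
        out = presmooth(img, 1)
        assert out[3, 3] == pytest.approx(100.0 / 9.0)
        assert out[3, 4] == pytest.approx(100.0 / 9.0)
        assert out[0, 0] == 0.0

    def test_flat_field_preserved(self):
        img = np.full((6, 8), 37.0)
        np.testing.assert_allclose(presmooth(img, 5), img)

    def test_stack_form_matches_slicewise(self, rng):
        stack = rng.integers(0, 100, size=(3, 8, 8)).astype(float)
        out = presmooth(stack, 2)
        for z in range(3):
            np.testing.assert_allclose(out[z], presmooth(stack[z], 2))


class TestLaplacian:
    @pytest.mark.parametrize("sens", ["low", "medium", "high"])
    def test_flat_field_maps_to_offset(self, sens):
        img = np.full((12, 12), 640.0)
        np.testing.assert_allclose(laplacian(img, sens, 1500), 1500.0, atol=1e-8)

    def test_single_peak_low_sensitivity_hand_convolution(self):
        h = 100.0
        img = np.zeros((9, 9))
        img[4, 4] = h
        out = laplacian(img, "low", 1500)
        assert out[4, 4] == pytest.approx(1500 - 4 * h)
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            assert out[4 + dr, 4 + dc] == pytest.approx(1500 + h)

    def test_bright_peak_clamped_at_zero(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1000.0
        out = laplacian(img, "low", 1500)
        assert out[4, 4] == 0.0  # 1500 - 4000 clamps

    @pytest.mark.parametrize("sens", ["low", "medium", "high"])
    def test_gaussian_blob_minimum_at_centre(self, sens):
        y, x = np.mgrid[0:41, 0:41]
        img = 500.0 * np.exp(-((x - 20) ** 2 + (y - 20) ** 2) / (2 * 6.0 ** 2))
        out = laplacian(img, sens, 1500)
        assert np.unravel_index(np.argmin(out), out.shape) == (20, 20)


def crimmins_reference(image, iterations):
    """Naive loop implementation of the directional +-1 pass structure.

    Synchronous sub-steps: each of the four adjustments per directional
    pass reads the pre-step array; border neighbours are edge-replicated.
    """
    b = np.asarray(image, dtype=float).copy()
    n_rows, n_cols = b.shape

    def nb(arr, r, c, dr, dc):
        return arr[min(max(r + dr, 0), n_rows - 1), min(max(c + dc, 0), n_cols - 1)]

    for _ in range(iterations):
        for dark in (True, False):
            for dr, dc in [(1, 0), (0, 1), (1, 1), (1, -1)]:
                sign = 1.0 if dark else -1.0
                for step in range(4):
                    prev = b.copy()
                    for r in range(n_rows):
                        for c in range(n_cols):
                            a = nb(prev, r, c, -dr, -dc)
                            cc = nb(prev, r, c, dr, dc)
                            v = prev[r, c]
                            if step == 0:
                                cond = sign * (a - v) >= 2
                            elif step == 1:
                                cond = sign * (a - v) > 0 and sign * (v - cc) <= 0
                            elif step == 2:
                                cond = sign * (cc - v) > 0 and sign * (v - a) <= 0
                            else:
                                cond = sign * (cc - v) >= 2
                            if cond:
                                b[r, c] = v + sign
    return b


class TestCrimmins:
    def test_zero_iterations_is_identity(self, rng):
        img = rng.integers(0, 50, size=(6, 6)).astype(float)
        np.testing.assert_array_equal(crimmins(img, 0), img)

    def test_matches_reference_implementation(self, rng):
        # NOTE: the reference applies the identical synchronous sub-step
        # semantics with explicit loops; agreement must be exact
        for _ in range(5):
            img = rng.integers(0, 30, size=(7, 8)).astype(float)
            np.testing.assert_array_equal(crimmins(img, 1), crimmins_reference(img, 1))

    def test_salt_amplitude_decays_until_within_one_level(self):
        img = np.full((15, 15), 100.0)
        img[7, 7] += 40
        amp, x = 40.0, img
        while amp > 1.0:
            x = crimmins(x, 1)
            new_amp = x.max() - 100.0
            assert new_amp < amp
            amp = new_amp
        assert amp <= 1.0

    def test_pepper_speckle_raised(self):
        img = np.full((11, 11), 80.0)
        img[5, 5] -= 30
        out = crimmins(img, 2)
        assert out[5, 5] > 50.0

    def test_symmetric_input_stays_symmetric_within_one_level(self):
        # the four directional passes run sequentially, so exact symmetry
        # is not preserved; deviations stay within the +-1 step size
        img = np.full((11, 11), 10.0)
        img[5, 5] = 50.0
        img[4:7, 4:7] += 5.0
        out = crimmins(img, 1)
        assert np.abs(out - out[::-1, :]).max() <= 1.0
        assert np.abs(out - out[:, ::-1]).max() <= 1.0
        assert np.abs(out - out.T).max() <= 1.0


class TestGlobalHistogram:
    def test_additivity_over_identical_slices(self, rng):
        plane = rng.normal(100, 10, size=(1, 12, 12))
        mask = np.ones((12, 12), dtype=bool)
        single = build_global_histogram([plane], [mask])
        double = build_global_histogram([np.concatenate([plane, plane])], [mask])
        np.testing.assert_array_equal(double.counts, 2 * single.counts)
        assert double.offset == single.offset

    def test_one_stack_folder_equals_stack_scope(self, rng):
        stack = rng.normal(0, 5, size=(3, 10, 10))
        mask = np.ones((10, 10), dtype=bool)
        a = build_global_histogram([stack], [mask])
        b = build_global_histogram([stack.copy()], [mask.copy()])
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_masked_pixels_contribute_nothing(self, rng):
        stack = rng.normal(50, 20, size=(2, 9, 9))
        mask = rng.random((9, 9)) < 0.5
        zeroed = stack.copy()
        zeroed[:, ~mask] = 10_000.0  # garbage outside mask must be invisible
        a = build_global_histogram([stack], [mask])
        b = build_global_histogram([zeroed], [mask])
        np.testing.assert_array_equal(a.counts, b.counts)
        total_in_mask = int(mask.sum()) * 2
        assert a.total == total_in_mask

    def test_histogram_addition_aligns_offsets(self):
        a = IntHistogram(np.array([1, 2, 3]), offset=-1)
        b = IntHistogram(np.array([5]), offset=3)
        c = a + b
        assert c.offset == -1
        np.testing.assert_array_equal(c.counts, [1, 2, 3, 0, 5])


class TestBinarizeAndClose:
    def test_ring_hole_filled_by_closing(self):
        img = np.zeros((9, 9))
        rows, cols = np.mgrid[0:9, 0:9]
        ring = ((rows - 4) ** 2 + (cols - 4) ** 2 <= 5) & ~((rows == 4) & (cols == 4))
        img[ring] = 10.0
        out = binarize_and_close(img, 5)
        assert out[4, 4]  # 1-px hole closed

    def test_all_background_slice_is_empty(self):
        assert not binarize_and_close(np.zeros((8, 8)), 5).any()

    def test_closing_idempotent(self, rng):
        img = (rng.random((20, 20)) < 0.3) * 10.0
        once = binarize_and_close(img, 5)
        twice = ndimage.binary_closing(once, structure=EIGHT)
        np.testing.assert_array_equal(once, twice)

    def test_polarity_flag_selects_side(self):
        img = np.full((7, 7), 5.0)
        img[2, 2] = 9.0   # above-threshold island
        img[4, 4] = 1.0   # below-threshold island
        hi = binarize_and_close(img, 5, polarity_inverted=True)
        lo = binarize_and_close(img, 5, polarity_inverted=False)
        assert hi[2, 2] and not hi[4, 4] and hi.sum() == 1
        assert lo[4, 4] and not lo[2, 2] and lo.sum() == 1


class TestDetectFociMasks:
    def test_deterministic_bit_identical(self, medium_field_nucleus):
        truth, focus, region = medium_field_nucleus
        crop, mask = crop_nucleus(focus, region)
        settings = FilterSettings()
        a = detect_foci_masks(crop, mask, settings)
        b = detect_foci_masks(crop, mask, settings)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma, mb)

    def test_all_true_foci_detected(self, medium_field_nucleus):
        truth, focus, region = medium_field_nucleus
        crop, mask = crop_nucleus(focus, region)
        masks = detect_foci_masks(crop, mask, FilterSettings())
        r0, c0 = region.bbox[0], region.bbox[1]
        for f in truth.foci:
            x, y, z = f.centre_3d_px
            zi = int(round(z))
            assert masks[zi][int(round(y)) - r0, int(round(x)) - c0]

    def test_out_of_mask_pixels_always_false(self, medium_field_nucleus):
        truth, focus, region = medium_field_nucleus
        crop, mask = crop_nucleus(focus, region)
        for m in detect_foci_masks(crop, mask, FilterSettings()):
            assert not m[~mask].any()

    def test_noise_only_nucleus_yields_no_foci(self, rng):
        from autorif import synthetic_fixtures as synth

        truth = synth.default_truth(0, seed=5, shape=(8, 192, 192))
        nuclear, focus = synth.render_field(truth, (8, 192, 192))
        region = segment_nuclei(nuclear)[0]
        crop, mask = crop_nucleus(focus, region)
        masks = detect_foci_masks(crop, mask, FilterSettings())
        assert not any(m.any() for m in masks)

    def test_salt_components_nonincreasing_in_presmoothing(self, medium_field_nucleus):
        truth, focus, region = medium_field_nucleus
        crop, mask = crop_nucleus(focus, region)
        counts = []
        for pre in (1, 2, 3, 5):
            s = FilterSettings(pre_iterations=pre, min_focus_px=1)
            masks = detect_foci_masks(crop, mask, s)
            salt = 0
            for m in masks:
                labels, n = ndimage.label(m, structure=EIGHT)
                if n:
                    salt += int((np.bincount(labels.ravel())[1:] == 1).sum())
            counts.append(salt)
        assert counts == sorted(counts, reverse=True)

    def test_global_threshold_spares_empty_slices(self, medium_field):
        """Empty slices thresholded per-slice accumulate more false
        components than under the stack-global threshold."""
        from autorif import synthetic_fixtures as synth
        from autorif.focus_filtering import max_entropy_threshold

        truth0, nuclear, focus = medium_field
        # same nucleus but all foci confined to the bottom slices
        foci = [
            synth.FocusSpec(0, (f.centre_3d_px[0], f.centre_3d_px[1], 1.0 + i % 3),
                            f.sigma_xy_px, 0.8, f.peak_intensity)
            for i, f in enumerate(truth0.foci)
        ]
        truth = synth.GroundTruth(nuclei=truth0.nuclei, foci=foci, noise=truth0.noise,
                                  calibration=truth0.calibration, seed=truth0.seed)
        nuclear, focus = synth.render_field(truth, (10, 256, 256))
        region = segment_nuclei(nuclear)[0]
        crop, mask = crop_nucleus(focus, region)
        settings = FilterSettings()
        filt = filter_stack(crop.data, settings)
        m = analysis_mask(mask, settings)
        t_global = max_entropy_threshold(build_global_histogram([filt], [m]))
        empty = range(7, 10)
        n_global = n_perslice = 0
        for z in empty:
            n_global += ndimage.label(
                binarize_and_close(filt[z], t_global) & m, structure=EIGHT)[1]
            t_z = max_entropy_threshold(build_global_histogram([filt[z: z + 1]], [m]))
            n_perslice += ndimage.label(
                binarize_and_close(filt[z], t_z) & m, structure=EIGHT)[1]
        assert n_global <= n_perslice
        assert n_perslice > 0  # the pathology is actually present


class TestClassSeparation:
    def test_clean_bimodal_far_exceeds_noise_split(self):
        counts = np.zeros(600, dtype=int)
        counts[95:106] = 100  # noise around level 100
        counts[500:505] = 20  # distinct focus class
        hist = IntHistogram(counts, offset=0)
        assert class_separation(hist, 300) > 50

    def test_pure_noise_split_is_small(self, rng):
        vals = rng.normal(0, 5, size=20_000).round().astype(int)
        lo = vals.min()
        hist = IntHistogram(np.bincount(vals - lo), offset=int(lo))
        t = int(np.percentile(vals, 99))
        assert class_separation(hist, t) < 6


class TestDumpStages:
    def test_stage_tiffs_written(self, medium_field_nucleus, tmp_path):
        from autorif.focus_filtering import dump_stages

        truth, focus, region = medium_field_nucleus
        crop, _ = crop_nucleus(focus, region)
        paths = dump_stages(crop.data, FilterSettings(), tmp_path)
        names = sorted(p.name for p in paths)
        assert names[:4] == ["0_raw.tif", "1_presmoothed.tif",
                             "2_laplacian.tif", "3_crimmins.tif"]
        import tifffile

        raw = tifffile.imread(tmp_path / "0_raw.tif")
        assert raw.shape == crop.data.shape[1:]
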