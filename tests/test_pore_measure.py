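"""The pore-area algorithm: every stage plus end-to-end properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stomapore import pore_measure as pm
from stomapore import synthgen
from stomapore.synthgen import SceneSpec, extract_patch, generate_scene


def _clean_patch(seed, polarity="dark", blur=0.0):
    spec = SceneSpec(
        height=220, width=220, n_stomata=1, seed=seed,
        polarity_mix=(1.0 if polarity == "light" else 0.0),
        blur_sigma_range=(blur, blur), vein_density=0.0,
        artifact_rate=0.0, noise_sigma=0.0,
    )
    scene = generate_scene(spec)
    return extract_patch(scene, scene.stomata[0]) + (scene.stomata[0],)


class TestEnhance:
    def test_constant_patch_unchanged(self):
        out = pm.enhance(np.full((30, 30), 90, dtype=np.uint8))
        assert (out == 90).all()

    def test_rgb_luminance_weights(self):
        # 0.299 R + 0.587 G + 0.114 B, hand-checked on two pixels
        px = np.array([[[255, 0, 0], [0, 255, 0]]], dtype=np.uint8)
        from stomapore.imaging_io import to_gray

        gray = to_gray(px)
        np.testing.assert_allclose(gray[0], [0.299 * 255, 0.587 * 255], atol=1e-9)

    def test_low_contrast_ramp_stretched_to_full_range(self):
        ramp = np.tile(np.linspace(100, 140, 64).astype(np.uint8), (64, 1))
        out = pm.enhance(ramp)
        assert out.min() == 0
        assert out.max() == 255

    def test_single_pixel_passthrough(self):
        out = pm.enhance(np.array([[42]], dtype=np.uint8))
        assert out.shape == (1, 1)

    def test_inversion_antisymmetry(self, rng):
        """E(255-x) == 255 - E(x) up to rounding of the 8-bit output."""
        img = rng.integers(0, 256, size=(48, 48)).astype(np.uint8)
        a = pm.enhance(img).astype(int)
        b = pm.enhance(255 - img).astype(int)
        assert np.abs(a + b - 255).max() <= 1


def _otsu_oracle(gray):
    """Exhaustive search over all 256 cut points, smallest-t tie-break."""
    g = gray.ravel().astype(float)
    best_t, best_v = None, -1.0
    for t in range(256):
        lo, hi = g[g <= t], g[g > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        w0, w1 = len(lo) / len(g), len(hi) / len(g)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_two_level_40_60(self):
        img = np.array([10] * 40 + [200] * 60, dtype=np.uint8).reshape(10, 10)
        assert pm.otsu_threshold(img) == _otsu_oracle(img) == 10

    def test_extreme_two_level(self):
        img = np.array([0, 255] * 8, dtype=np.uint8).reshape(4, 4)
        assert pm.otsu_threshold(img) == _otsu_oracle(img) == 0

    def test_oracle_equivalence_50_random_images(self, rng):
        for _ in range(50):
            img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
            assert pm.otsu_threshold(img) == _otsu_oracle(img)

    def test_constant_image_degenerate(self):
        with pytest.raises(pm.DegenerateInputError):
            pm.otsu_threshold(np.full((8, 8), 7, dtype=np.uint8))


class TestFilterRegions:
    def _blob(self, shape, spots):
        out = np.zeros(shape, dtype=bool)
        for r, c, size in spots:
            out[r : r + size, c : c + size] = True
        return out

    def test_at_cutoff_removed(self):
        mask = self._blob((30, 30), [(2, 2, 7)])  # 49 px
        assert not pm.filter_regions(mask, 50).any()

    def test_above_cutoff_kept(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2:9, 2:9] = True
        mask[8, 9] = True  # 50} biased: 49+1=50 -> still removed
        mask[9, 9] = True  # 51 px total (8-connected)
        out = pm.filter_regions(mask, 50)
        np.testing.assert_array_equal(out, mask)

    def test_mixed_sizes_enumerated(self):
        # areas 10/49/81; cutoff 49 removes "no larger than" 49
        mask = np.zeros((60, 60), dtype=bool)
        mask[0:2, 0:5] = True       # 10
        mask[10:17, 10:17] = True   # 49
        mask[30:39, 30:39] = True   # 81
        out = pm.filter_regions(mask, 49)
        assert out[30:39, 30:39].all()
        assert not out[0:2, 0:5].any()
        assert not out[10:17, 10:17].any()

    @settings(max_examples=20, deadline=None)
    @given(cutoff=st.integers(0, 120), seed=st.integers(0, 10_000))
    def test_monotone_in_cutoff(self, cutoff, seed):
        from scipy import ndimage as ndi

        rng = np.random.default_rng(seed)
        mask = rng.random((40, 40)) < 0.35
        bigger = pm.filter_regions(mask, cutoff)
        smaller = pm.filter_regions(mask, cutoff + 17)
        n_big = ndi.label(bigger, structure=np.ones((3, 3)))[1]
        n_small = ndi.label(smaller, structure=np.ones((3, 3)))[1]
        assert n_small <= n_big
        assert not (smaller & ~bigger).any()  # output shrinks with cutoff


class TestSelectRegion:
    def test_centered_blob_selected(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[25:35, 20:40] = True
        region = pm.select_stomate_region(mask)
        assert region is not None
        assert region.area_px == 200

    def test_corner_blob_rejected_small_central_wins(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[0:30, 0:30] = True       # large, corner: centroid (14.5, 14.5)
        mask[45:55, 45:55] = True     # small, central
        region = pm.select_stomate_region(mask, central_fraction=0.5)
        assert region.area_px == 100

    def test_empty_mask_is_no_detection(self):
        assert pm.select_stomate_region(np.zeros((40, 40), dtype=bool)) is None

    def test_spanning_band_is_not_a_stomate(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[:, 28:33] = True  # vertical band through the centre
        assert pm.select_stomate_region(mask) is None

    def test_annulus_hole_filled(self):
        rr, cc = np.mgrid[0:80, 0:80]
        d2 = (rr - 40.0) ** 2 / 400 + (cc - 40.0) ** 2 / 144
        annulus = (d2 <= 1.0) & (d2 > 0.5)
        region = pm.select_stomate_region(annulus)
        assert region is not None
        assert region.mask[40, 40]  # interior included


class TestAlign:
    def _ellipse_mask(self, angle, shape=(120, 120), a=30, b=12):
        canvas = np.full(shape, 180.0)
        _, _, stomate = synthgen.render_stomate(
            canvas, (shape[0] / 2, shape[1] / 2), (a, b), angle, "dark"
        )
        return canvas.astype(np.uint8), stomate

    def test_horizontal_is_noop(self):
        gray, mask = self._ellipse_mask(0.0)
        region = pm.RegionMask.from_mask(mask)
        _, rot_region, angle = pm.align_to_major_axis(gray, region)
        assert abs(angle) < 2.0
        assert abs(rot_region.orientation) < 2.0

    @pytest.mark.parametrize("true_angle", [37.0, -37.0, 90.0, -65.0])
    def test_recovers_known_rotation(self, true_angle):
        gray, mask = self._ellipse_mask(true_angle)
        region = pm.RegionMask.from_mask(mask)
        expected = true_angle if true_angle != 90.0 else 90.0
        if expected > 90.0:
            expected -= 180.0
        assert region.orientation == pytest.approx(expected % 180.0 if expected > 90 else expected, abs=2.0)
        _, rot_region, _ = pm.align_to_major_axis(gray, region)
        assert abs(rot_region.orientation) <= 2.0

    def test_circular_mask_skips_rotation(self):
        rr, cc = np.mgrid[0:60, 0:60]
        disk = (rr - 30.0) ** 2 + (cc - 30.0) ** 2 <= 15**2
        gray = np.full((60, 60), 100, dtype=np.uint8)
        _, _, angle = pm.align_to_major_axis(gray, pm.RegionMask.from_mask(disk))
        assert angle == 0.0


class TestCrossSection:
    def _profile_from(self, values):
        """Build an aligned image whose centroid column equals `values`."""
        values = np.asarray(values, dtype=float)
        gray = np.tile(values[:, None], (1, 9))
        mask = np.zeros_like(gray, dtype=bool)
        mask[1:-1, 3:6] = True
        return pm.cross_section(gray, pm.RegionMask.from_mask(mask))

    def test_v_profile_single_valley(self):
        # hand-smoothed [200,150,80,150,200] (window 3, edges replicated)
        # -> [183.3, 143.3, 126.7, 143.3, 183.3]: one valley at index 2
        prof = self._profile_from([200, 150, 80, 150, 200])
        assert prof.valleys == [2]
        assert prof.peaks == []

    def test_inverted_profile_single_peak(self):
        prof = self._profile_from([55, 105, 175, 105, 55])
        assert prof.peaks == [2]
        assert prof.valleys == []

    def test_monotone_ramp_no_extrema(self):
        prof = self._profile_from([10, 50, 90, 130, 170, 210, 250])
        assert prof.peaks == [] and prof.valleys == []
        assert pm.find_pore_center(prof) is None

    def test_too_short_profile_is_none(self):
        gray = np.full((4, 4), 50.0)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        assert pm.cross_section(gray, pm.RegionMask.from_mask(mask)) is None


class TestFindPoreCenter:
    def _profile(self, values, peaks, valleys, centroid):
        return pm.CrossSectionProfile(
            values=np.asarray(values, dtype=float),
            raw_values=np.asarray(values, dtype=float),
            peaks=peaks, valleys=valleys,
            centroid_index=centroid, row_start=0, col=0,
        )

    def test_single_valley(self):
        values = np.full(40, 100.0)
        values[10] = 20
        prof = self._profile(values, [], [10], 12)
        assert pm.find_pore_center(prof) == (10, "dark")

    def test_nearest_wins(self):
        values = np.full(40, 100.0)
        values[8] = 20
        values[30] = 200
        prof = self._profile(values, [30], [8], 12)
        assert pm.find_pore_center(prof) == (8, "dark")

    def test_distance_tie_breaks_on_prominence(self):
        # peak at 14 (prominence 40) vs valley at 10 (prominence 20),
        # centroid 12: equal distance, more prominent peak wins
        values = np.full(30, 100.0)
        values[10] = 80
        values[14] = 140
        prof = self._profile(values, [14], [10], 12)
        assert pm.find_pore_center(prof) == (14, "light")


class TestGrowPore:
    def test_flat_image_floods_everything(self):
        mask = pm.grow_pore(np.full((20, 20), 50.0), (10, 10), tolerance=5.0)
        assert mask.all()

    def test_dark_square_exact(self):
        img = np.full((20, 20), 220.0)
        img[8:13, 8:13] = 40.0
        mask = pm.grow_pore(img, (10, 10), tolerance=0.10 * (220 - 40))
        expect = np.zeros((20, 20), dtype=bool)
        expect[8:13, 8:13] = True
        np.testing.assert_array_equal(mask, expect)

    def test_bright_wall_blocks_connectivity(self):
        img = np.full((10, 21), 220.0)
        img[:, 0:10] = 40.0
        img[:, 11:] = 40.0  # second dark block behind a bright 1-px wall
        mask = pm.grow_pore(img, (5, 4), tolerance=20.0)
        assert mask[:, 0:10].all()
        assert not mask[:, 11:].any()

    def test_seed_outside_rejected(self):
        with pytest.raises(ValueError):
            pm.grow_pore(np.zeros((5, 5)), (9, 0), 1.0)


class TestEstimatePore:
    def test_clean_dark_pore_accepted(self):
        (patch, true_pore, gt) = _clean_patch(301, "dark")
        est = pm.estimate_pore(patch)
        assert est.accepted
        assert est.polarity == "dark"
        assert pm.mask_iou(est.pore_mask, true_pore) >= 0.7

    def test_clean_light_pore_accepted(self):
        (patch, true_pore, gt) = _clean_patch(302, "light")
        est = pm.estimate_pore(patch)
        assert est.accepted
        assert est.polarity == "light"
        assert pm.mask_iou(est.pore_mask, true_pore) >= 0.7

    def test_blank_patch_is_no_detection(self, rng):
        blank = rng.normal(180, 3, size=(90, 90)).clip(0, 255).astype(np.uint8)
        est = pm.estimate_pore(pm.PorePatch(blank))
        assert est.status == pm.STATUS_NO_DETECTION

    def test_area_unit_conversion_exact(self):
        (patch, _, _) = _clean_patch(303, "dark")
        patch.pixel_scale = 0.25
        est = pm.estimate_pore(patch)
        assert est.accepted
        assert est.area_um2 == est.area_px * 0.25**2

    def test_rotation_consistency(self):
        """Pre-rotating the patch by 90 deg changes the area <= 10%."""
        (patch, _, _) = _clean_patch(304, "dark")
        est = pm.estimate_pore(patch)
        rot = pm.PorePatch(np.rot90(patch.pixels).copy(), patch.pixel_scale)
        est_rot = pm.estimate_pore(rot)
        assert est.accepted and est_rot.accepted
        assert abs(est.area_px - est_rot.area_px) <= 0.10 * est.area_px

    @pytest.mark.parametrize("seed,polarity", [(311, "dark"), (312, "light")])
    def test_polarity_flip_under_inversion(self, seed, polarity):
        (patch, _, _) = _clean_patch(seed, polarity)
        est = pm.estimate_pore(patch)
        inv = pm.PorePatch(255 - patch.pixels, patch.pixel_scale)
        est_inv = pm.estimate_pore(inv)
        assert est.accepted and est_inv.accepted
        assert est_inv.polarity != est.polarity
        assert pm.mask_iou(est_inv.pore_mask, est.pore_mask) >= 0.9

    def test_parameter_recovery_with_blur(self):
        """Moderate defocus (sigma = 2 px): >= 70% accepted with IoU >= 0.5."""
        good = 0
        n = 40
        for i in range(n):
            (patch, true_pore, _) = _clean_patch(500 + i, "light" if i % 2 else "dark", blur=2.0)
            est = pm.estimate_pore(patch)
            if est.accepted and pm.mask_iou(est.pore_mask, true_pore) >= 0.5:
                good += 1
        assert good / n >= 0.70
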