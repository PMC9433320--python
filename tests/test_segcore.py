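import numpy as np
import pytest
from scipy.ndimage import gaussian_filter, label

from oracles import maxima_bruteforce, otsu_threshold_bruteforce, phansalkar_bruteforce

from mitoquant.imgio import BinaryMask, Calibration
from mitoquant import segcore


class TestGaussianDenoise:
    def test_sigma_zero_is_identity(self):
        img = np.random.default_rng(0).random((20, 20))
        assert np.array_equal(segcore.gaussian_denoise(img, 0), img)

    def test_constant_preserved(self):
        out = segcore.gaussian_denoise(np.full((30, 30), 7.0), 2.0)
        assert np.allclose(out, 7.0)

    def test_mass_conserved_for_interior_spot(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1000.0
        out = segcore.gaussian_denoise(img, 2.0)
        assert out.sum() == pytest.approx(1000.0, rel=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            segcore.gaussian_denoise(np.zeros((4, 4)), -1)


class TestOtsu:
    def test_bimodal_separation(self):
        img = np.full((10, 10), 10.0)
        img.ravel()[:10] = 200.0
        mask = segcore.otsu_dark_mask(img)
        assert np.array_equal(mask.values, img == 200.0)

    def test_blob_apex_in_excluded_background_out(self):
        yy, xx = np.mgrid[0:60, 0:60]
        img = 100 * np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / 50)
        mask = segcore.otsu_dark_mask(img)
        assert mask.values[30, 30]
        assert not mask.values[2, 2]

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            segcore.otsu_dark_mask(np.ones((5, 5)))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_argmax(self, seed):
        rng = np.random.default_rng(seed)
        n0 = rng.integers(200, 800)
        img = np.concatenate(
            [
                rng.normal(rng.uniform(20, 80), rng.uniform(3, 15), n0),
                rng.normal(rng.uniform(120, 250), rng.uniform(5, 30), 1024 - n0),
            ]
        ).reshape(32, 32)
        mask = segcore.otsu_dark_mask(img)
        t = otsu_threshold_bruteforce(img)
        assert np.array_equal(mask.values, img > t)


class TestPhansalkar:
    def test_constant_image_empty(self):
        mask = segcore.phansalkar_mask(np.full((20, 20), 5.0), 3)
        assert not mask.values.any()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_pixel_formula(self, seed):
        rng = np.random.default_rng(100 + seed)
        img = rng.random((24, 24))
        radius = int(rng.integers(2, 7))
        mask = segcore.phansalkar_mask(img, radius)
        assert np.array_equal(mask.values, phansalkar_bruteforce(img, radius))

    def test_bright_line_detected_on_noisy_background(self):
        rng = np.random.default_rng(5)
        img = rng.normal(100, 5, (64, 64))
        img[32, 10:54] += 300
        mask = segcore.phansalkar_mask(img, 8)
        assert mask.values[32, 10:54].mean() > 0.9
        assert mask.values[10].mean() < 0.2

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            segcore.phansalkar_mask(np.zeros((5, 5)), 0)


class TestFindMaxima:
    def test_two_separated_peaks(self):
        img = np.zeros((40, 40))
        img[10, 10] = 1000.0
        img[30, 30] = 1000.5
        spots = segcore.find_maxima(img, 100)
        assert len(spots) == 2

    def test_single_low_peak_below_prominence(self):
        img = np.zeros((20, 20))
        img[10, 10] = 50.0
        assert len(segcore.find_maxima(img, 100)) == 0

    def test_plateau_reported_once_at_centroid(self):
        img = np.zeros((20, 20))
        img[8:11, 8:12] = 500.0
        spots = segcore.find_maxima(img, 100)
        assert len(spots) == 1
        assert tuple(spots.positions[0]) == (9.0, 9.5)

    def test_edge_maxima_excluded(self):
        img = np.zeros((20, 20))
        img[0, 5] = 1000.0
        assert len(segcore.find_maxima(img, 100, exclude_edges=True)) == 0
        assert len(segcore.find_maxima(img, 100, exclude_edges=False)) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_flood_fill_prominence_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        img = gaussian_filter(rng.normal(size=(48, 48)), 3.0)
        prom = 0.05
        spots = segcore.find_maxima(img, prom)
        mine = sorted((int(round(y)), int(round(x))) for y, x in spots.positions)
        assert mine == maxima_bruteforce(img, prom)

    def test_prominence_must_be_positive(self):
        with pytest.raises(ValueError):
            segcore.find_maxima(np.zeros((5, 5)), 0)


class TestMorphology:
    def test_offset_zero_identity(self, disc_mask):
        out = segcore.morph_offset(disc_mask, 0.0)
        assert np.array_equal(out.values, disc_mask.values)

    def test_erosion_shrinks_disc_radius(self, disc_mask):
        out = segcore.morph_offset(disc_mask, -0.2)  # 3 μm disc → 2.8 μm
        r_eff = np.sqrt(out.values.sum() / np.pi)
        assert r_eff == pytest.approx(28.0, abs=1.0)

    def test_dilation_grows_disc_radius(self, disc_mask):
        out = segcore.morph_offset(disc_mask, 0.5)
        r_eff = np.sqrt(out.values.sum() / np.pi)
        assert r_eff == pytest.approx(35.0, abs=1.0)

    def test_closing_covers_original_convex_mask(self, disc_mask):
        grown = segcore.morph_offset(disc_mask, 0.4)
        back = segcore.morph_offset(grown, -0.4)
        missing = disc_mask.values & ~back.values
        # any residual confined to a 1-px shell at the boundary
        interior = segcore.morph_offset(disc_mask, -0.1 * disc_mask.pixel_size)
        assert not (missing & interior.values).any()

    def test_ring_roi_is_annulus(self, cal01):
        yy, xx = np.mgrid[0:120, 0:120]
        disc = BinaryMask((yy - 60) ** 2 + (xx - 60) ** 2 <= 20**2, cal01)  # r=2 μm
        ring = segcore.ring_roi(disc, 1.5, 0.5)
        rr = np.hypot(yy - 60, xx - 60)[ring.values]
        assert rr.min() >= 29.0 and rr.max() <= 35.5  # 3.0–3.5 μm ± 1 px

    def test_ring_empty_mask(self, cal01):
        ring = segcore.ring_roi(BinaryMask(np.zeros((20, 20), bool), cal01), 1.0, 0.5)
        assert not ring.values.any()

    def test_ring_requires_valid_widths(self, disc_mask):
        with pytest.raises(ValueError):
            segcore.ring_roi(disc_mask, 0.5, 1.0)


class TestRollingBall:
    def test_constant_image_to_zero(self):
        out = segcore.rolling_ball_background(np.full((30, 30), 42.0), 5)
        assert np.allclose(out, 0.0)

    def test_thin_line_preserved_background_removed(self):
        img = np.full((80, 80), 50.0)
        img[40, 10:70] += 500.0
        out = segcore.rolling_ball_background(img, 10)
        assert out[40, 20:60].mean() == pytest.approx(500.0, rel=0.01)
        assert out[10].mean() <= 0.01 * 50.0

    def test_slow_ramp_flattened(self):
        yy, xx = np.mgrid[0:100, 0:100]
        ramp = 100.0 + 0.3 * xx
        out = segcore.rolling_ball_background(ramp, 12)
        assert out.std() <= 0.1 * ramp.std()

    def test_huge_radius_subtracts_global_min(self):
        img = np.random.default_rng(0).random((20, 20)) + 5.0
        out = segcore.rolling_ball_background(img, 100)
        assert np.allclose(out, img - img.min())


class TestSkeleton:
    def test_bar_length(self, cal01):
        mask = np.zeros((20, 110), bool)
        mask[9:12, 5:105] = True
        _, length = segcore.skeletonize_length(
            BinaryMask(mask, Calibration(0.05))
        )
        assert length == pytest.approx(99 * 0.05, abs=2 * 0.05)

    def test_empty_mask_zero_length(self, cal01):
        _, length = segcore.skeletonize_length(BinaryMask(np.zeros((10, 10), bool), cal01))
        assert length == 0.0

    def test_diagonal_line_length(self):
        mask = np.zeros((50, 50), bool)
        for i in range(10, 40):
            mask[i, i] = True
        _, length = segcore.skeletonize_length(BinaryMask(mask, Calibration(1.0)))
        assert length == pytest.approx(29 * np.sqrt(2))


class TestLineProfile:
    def test_constant_image_flat_profile(self, cal01):
        prof = segcore.line_profile(np.full((30, 30), 3.0), (5, 5), (25, 20), 5, cal01)
        assert np.allclose(prof.intensities, 3.0)
        assert prof.distances_um[0] == 0.0
        assert np.all(np.diff(prof.distances_um) > 0)

    def test_step_edge_at_known_position(self, cal01):
        img = np.zeros((40, 60))
        img[:, 30:] = 100.0
        prof = segcore.line_profile(img, (20, 10), (20, 50), 3, cal01)
        # 50% crossing should sit at the edge, 19.5 px from start → 1.95 μm
        d = prof.distances_um
        v = prof.intensities
        crossing = np.interp(50.0, v, d)
        assert crossing == pytest.approx(1.95, abs=0.1)

    def test_width_irrelevant_on_constant_image(self, cal01):
        img = np.full((30, 30), 9.0)
        p1 = segcore.line_profile(img, (15, 2), (15, 27), 1, cal01)
        p5 = segcore.line_profile(img, (15, 2), (15, 27), 5, cal01)
        assert np.allclose(p1.intensities, p5.intensities)

    def test_zero_length_rejected(self, cal01):
        with pytest.raises(ValueError):
            segcore.line_profile(np.zeros((10, 10)), (5, 5), (5, 5), 1, cal01)


class TestRadialProfile:
    def test_uniform_disc_scales_like_circumference(self):
        yy, xx = np.mgrid[0:200, 0:200]
        img = ((yy - 100) ** 2 + (xx - 100) ** 2 <= 80**2).astype(float)
        prof = segcore.radial_profile(img, (100, 100))
        r = np.arange(10, 70)
        ratio = prof.sums[r] / (2 * np.pi * r)
        assert np.all(np.abs(ratio - 1) < 0.25)  # per-bin discretization
        assert np.abs(ratio.mean() - 1) < 0.02

    def test_point_mass_single_bin(self):
        img = np.zeros((50, 50))
        img[25, 35] = 7.0  # radius 10 along +x
        prof = segcore.radial_profile(img, (25, 25))
        assert prof.sums[10] == 7.0
        assert prof.sums.sum() == 7.0

    def test_half_plane_sector_excludes_other_side(self):
        img = np.zeros((50, 50))
        img[:, :20] = 5.0  # strictly x < center
        prof = segcore.radial_profile(img, (25, 25), angle_deg=180.0, orientation_deg=0.0)
        assert prof.sums.sum() == 0.0


class TestRegions:
    def test_min_size_filters_small_regions(self, cal01):
        mask = np.zeros((40, 40), bool)
        mask[5:12, 5:13] = True  # 56 px
        mask[30:31, 30:33] = True  # 3 px
        rs = segcore.regions_from_mask(BinaryMask(mask, cal01), min_size_px=5)
        assert rs.n_regions == 1

    def test_empty_mask(self, cal01):
        rs = segcore.regions_from_mask(BinaryMask(np.zeros((10, 10), bool), cal01))
        assert rs.n_regions == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_labels_match_flood_fill(self, cal01, seed):
        rng = np.random.default_rng(seed)
        mask = gaussian_filter(rng.random((48, 48)), 2) > 0.55
        rs = segcore.regions_from_mask(BinaryMask(mask, cal01), min_size_px=0)
        ref, n = label(mask, structure=np.ones((3, 3)))
        assert rs.n_regions == n
        # identical partition of pixels (labels may be permuted)
        for rid in range(1, n + 1):
            sel = ref == rid
            assert len(np.unique(rs.labels[sel])) == 1


class TestSurfaceDistance:
    def test_disc_center_negative_radius(self, disc_mask):
        d = segcore.distance_to_mask_surface([(50, 50)], disc_mask)
        assert d[0] == pytest.approx(-3.0, abs=0.1)

    def test_boundary_point_near_zero(self, disc_mask):
        d = segcore.distance_to_mask_surface([(50, 80)], disc_mask)
        assert abs(d[0]) <= 0.1

    def test_outside_point_positive(self, disc_mask):
        d = segcore.distance_to_mask_surface([(50, 90)], disc_mask)
        assert d[0] == pytest.approx(1.0, abs=0.1)

    def test_empty_mask_rejected(self, cal01):
        with pytest.raises(ValueError):
            segcore.distance_to_mask_surface([(1, 1)], BinaryMask(np.zeros((5, 5), bool), cal01))


class TestShiftEquivariance:
    """Translating the input by whole pixels translates the output."""

    def test_otsu_mask_shift(self):
        rng = np.random.default_rng(3)
        img = gaussian_filter(rng.random((40, 40)), 2)
        big = np.zeros((60, 60))
        big[5:45, 5:45] = img
        shifted = np.zeros((60, 60))
        shifted[12:52, 9:49] = img
        m1 = segcore.otsu_dark_mask(big).values[5:45, 5:45]
        m2 = segcore.otsu_dark_mask(shifted).values[12:52, 9:49]
        assert np.array_equal(m1, m2)

    def test_find_maxima_shift(self):
        rng = np.random.default_rng(4)
        img = gaussian_filter(rng.normal(size=(40, 40)), 3)
        big = np.full((60, 60), img.min())
        big[5:45, 5:45] = img
        shifted = np.full((60, 60), img.min())
        shifted[10:50, 13:53] = img
        s1 = segcore.find_maxima(big, 0.05).positions
        s2 = segcore.find_maxima(shifted, 0.05).positions
        assert np.allclose(sorted(map(tuple, s1 + [5, 8])), sorted(map(tuple, s2)))


def test_calibration_invariance_of_morph_offset():
    """Halving pixel size and doubling resolution changes physical results <2%."""
    cal_lo = Calibration(0.1)
    cal_hi = Calibration(0.05)
    yy, xx = np.mgrid[0:100, 0:100]
    m_lo = BinaryMask((yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2, cal_lo)
    yy, xx = np.mgrid[0:200, 0:200]
    m_hi = BinaryMask((yy - 100) ** 2 + (xx - 100) ** 2 <= 60**2, cal_hi)
    a_lo = segcore.morph_offset(m_lo, -0.5).values.sum() * cal_lo.pixel_size_xy**2
    a_hi = segcore.morph_offset(m_hi, -0.5).values.sum() * cal_hi.pixel_size_xy**2
    assert a_lo == pytest.approx(a_hi, rel=0.02)
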