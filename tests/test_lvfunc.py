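import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mousecmr.lvfunc import (CardiacFunction, SegmentationConfig,
                             SegmentationError, area_correlation,
                             calibrate_threshold_factor, cnr_wall_cavity,
                             deviation_stats, lv_mass, lv_volumes, segment_lv,
                             wall_thickness_profile)
from mousecmr.phantom import PhantomConfig, make_heart_frame
from mousecmr.pipeline import analysis_rois


def annulus_scene(n=100, r_in=15, r_out=25, cavity=0.2, wall=1.0, bg=0.0):
    yy, xx = np.indices((n, n))
    r = np.sqrt((yy - n / 2) ** 2 + (xx - n / 2) ** 2)
    img = np.full((n, n), bg)
    img[r < r_out] = wall
    img[r < r_in] = cavity
    roi = r < r_out + 3
    return img, roi


class TestSegmentLV:
    def test_two_level_roi_split_at_0p36(self):
        img = np.zeros((10, 10))
        img[:, :5] = 0.2
        img[:, 5:] = 1.0
        roi = np.ones((10, 10), dtype=bool)
        wall, cavity = segment_lv(img, roi)
        # mean 0.6 -> tau 0.36: exact two-class split
        assert cavity.sum() == 50 and wall.sum() == 50
        assert np.all(img[cavity] == 0.2) and np.all(img[wall] == 1.0)

    def test_annulus_geometry(self):
        img, roi = annulus_scene()
        wall, cavity = segment_lv(img, roi)
        assert cavity.sum() == pytest.approx(np.pi * 15 ** 2, rel=0.03)
        assert wall.sum() == pytest.approx(np.pi * (25 ** 2 - 15 ** 2), rel=0.05)

    def test_uniform_roi_fails_loudly(self):
        img = np.full((20, 20), 0.7)
        with pytest.raises(SegmentationError, match="cavity"):
            segment_lv(img, np.ones((20, 20), dtype=bool))

    def test_empty_roi_rejected(self):
        with pytest.raises(SegmentationError):
            segment_lv(np.ones((8, 8)), np.zeros((8, 8), dtype=bool))

    def test_zero_image_rejected(self):
        with pytest.raises(SegmentationError):
            segment_lv(np.zeros((8, 8)), np.ones((8, 8), dtype=bool))


class TestVolumes:
    def test_voxel_counting_arithmetic(self):
        masks = np.zeros((2, 1, 40, 40), dtype=bool)
        masks[0, 0].flat[:1000] = True
        masks[1, 0].flat[:100] = True
        vols, fn = lv_volumes(masks, (0.162, 0.162, 1.0))
        assert vols[0] == pytest.approx(26.24, abs=0.01)
        assert fn.ed_frame == 0 and fn.es_frame == 1

    def test_derived_parameters(self):
        fn = CardiacFunction(edv_ul=40.0, esv_ul=10.0, ed_frame=0, es_frame=5)
        assert fn.sv_ul == 30.0
        assert fn.ef_percent == 75.0

    def test_esv_cannot_exceed_edv(self):
        with pytest.raises(ValueError):
            CardiacFunction(edv_ul=10.0, esv_ul=40.0, ed_frame=0, es_frame=5)

    def test_volumes_scale_linearly_with_slice_thickness(self):
        masks = np.zeros((1, 2, 8, 8), dtype=bool)
        masks[0, :, 2:6, 2:6] = True
        v1, _ = lv_volumes(masks, (0.2, 0.2, 1.0))
        v2, _ = lv_volumes(masks, (0.2, 0.2, 2.0))
        assert v2[0] == pytest.approx(2 * v1[0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_ef_invariant_to_voxel_rescaling(self, scale):
        masks = np.zeros((2, 1, 10, 10), dtype=bool)
        masks[0, 0, :6, :6] = True
        masks[1, 0, :3, :3] = True
        _, a = lv_volumes(masks, (0.2, 0.2, 1.0))
        _, b = lv_volumes(masks, (0.2 * scale, 0.2 * scale, 1.0))
        assert a.ef_percent == pytest.approx(b.ef_percent)


class TestMass:
    def test_mass_arithmetic(self):
        mask = np.zeros((1, 40, 40), dtype=bool)
        mask.flat[:1000] = True
        assert lv_mass(mask, (0.162, 0.162, 1.0)) == pytest.approx(27.56,
                                                                   abs=0.01)

    def test_empty_mask_weighs_nothing(self):
        assert lv_mass(np.zeros((1, 8, 8), dtype=bool), (0.2, 0.2, 1.0)) == 0.0

    def test_invalid_voxels_rejected(self):
        with pytest.raises(ValueError):
            lv_mass(np.ones((1, 4, 4), dtype=bool), (0.0, 0.2, 1.0))

    def test_segmented_annulus_mass_matches_analytic(self):
        img, roi = annulus_scene()
        wall, _ = segment_lv(img, roi)
        vox = (0.1, 0.1, 1.0)
        analytic = np.pi * (2.5 ** 2 - 1.5 ** 2) * 1.0 * 1.05  # mm^3 * density
        assert lv_mass(wall, vox) == pytest.approx(analytic, rel=0.05)


class TestCNR:
    def test_formula_default_rms_denominator(self):
        rng = np.random.default_rng(0)
        img = np.zeros((200, 2))
        img[:, 0] = 1.0 + 0.1 * rng.standard_normal(200)
        img[:, 1] = 0.2 + 0.1 * rng.standard_normal(200)
        wall = np.zeros_like(img, dtype=bool)
        wall[:, 0] = True
        cavity = ~wall
        rep = cnr_wall_cavity(img, wall, cavity)
        expected = abs(img[wall].mean() - img[cavity].mean()) / np.sqrt(
            (img[wall].std() ** 2 + img[cavity].std() ** 2) / 2)
        assert rep.cnr == pytest.approx(expected)
        assert rep.cnr == pytest.approx(8.0, rel=0.2)

    def test_identical_distributions_give_near_zero(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0.5, 0.1, (100, 2))
        wall = np.zeros_like(img, dtype=bool)
        wall[:, 0] = True
        assert cnr_wall_cavity(img, wall, ~wall).cnr < 0.3

    @pytest.mark.parametrize("c", [0.5, 3.0, 100.0])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(2)
        img = np.abs(rng.normal(0.6, 0.2, (50, 2)))
        wall = np.zeros_like(img, dtype=bool)
        wall[:, 0] = True
        r1 = cnr_wall_cavity(img, wall, ~wall).cnr
        r2 = cnr_wall_cavity(c * img, wall, ~wall).cnr
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_overlapping_masks_rejected(self):
        img = np.ones((4, 4))
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            cnr_wall_cavity(img, m, m)


class TestWallProfile:
    def test_annulus_thickness_one_mm(self):
        # r_in 15 px, r_out 25 px at 0.1 mm/px -> 1.0 mm everywhere
        img, roi = annulus_scene()
        wall, _ = segment_lv(img, roi)
        prof = wall_thickness_profile(wall, (50.0, 50.0), pixel_mm=0.1)
        assert len(prof.thickness_mm) == 24
        assert np.allclose(prof.thickness_mm, 1.0, atol=0.05)
        assert not prof.missed.any()

    def test_ray_missing_wall_reports_zero_and_flag(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[18:22, 25:30] = True  # wall only to the right
        prof = wall_thickness_profile(mask, (20.0, 20.0), pixel_mm=0.1)
        assert prof.missed.any()
        assert np.all(prof.thickness_mm[prof.missed] == 0.0)

    def test_infarct_sector_ratio_half(self):
        cfg = PhantomConfig(matrix=154, infarct=True, infarct_center_deg=0.0,
                            infarct_extent_deg=90.0, infarct_thinning=0.5,
                            lv_center_mm=(0.0, 0.0), include_rv=False)
        img = make_heart_frame(cfg, 0.0, 0.0, 0)
        rois = analysis_rois(cfg)
        wall, cavity = segment_lv(img, rois[0])
        prof = wall_thickness_profile(wall, (77.0, 77.0),
                                      pixel_mm=cfg.pixel_mm)
        in_sector = (np.abs((prof.angles_deg + 180) % 360 - 180)
                     < 45 - 7.5)
        remote = np.abs((prof.angles_deg + 180) % 360 - 180) > 45 + 7.5
        ratio = prof.thickness_mm[in_sector].mean() / prof.thickness_mm[remote].mean()
        assert ratio == pytest.approx(0.5, abs=0.1)


class TestDeviationStats:
    def test_symmetric_example(self):
        assert deviation_stats([10.0, 20.0], [11.0, 18.0]) == pytest.approx(10.0)

    def test_identity_gives_zero(self):
        assert deviation_stats([5.0, 7.0, 9.0], [5.0, 7.0, 9.0]) == 0.0

    def test_single_subject(self):
        assert deviation_stats([40.0], [42.0]) == pytest.approx(5.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            deviation_stats([0.0], [1.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(delta=st.floats(-0.5, 0.5))
    def test_uniform_relative_change_maps_to_its_magnitude(self, delta):
        ref = np.array([10.0, 25.0, 40.0])
        got = deviation_stats(ref, ref * (1 + delta))
        assert got == pytest.approx(100 * abs(delta), abs=1e-9)


class TestAreaCorrelation:
    def test_identical_arrays(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r2 = area_correlation(x, x)
        assert slope == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_doubling(self):
        x = np.array([1.0, 2.0, 3.0])
        slope, _, r2 = area_correlation(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_noisy_identity_slope_near_one(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(5.0, 15.0, 50)
        y = x + rng.normal(0.0, 0.05 * x.mean(), 50)
        slope, _, _ = area_correlation(x, y)
        assert 0.9 < slope < 1.1

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            area_correlation([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestThresholdCalibration:
    def test_calibrated_factor_beats_default_on_direct_frames(self):
        from mousecmr.phantom import compute_ground_truth

        cfg = PhantomConfig(matrix=96)
        rois = analysis_rois(cfg)
        factor = calibrate_threshold_factor(cfg, rois)
        assert 0.55 <= factor <= 0.95
        truth = compute_ground_truth(cfg, 2)
        vox = cfg.pixel_mm ** 2

        def edv_error(f):
            seg = SegmentationConfig(threshold_factor=f)
            vol = 0.0
            for s in range(cfg.n_slices):
                img = make_heart_frame(cfg, 0.0, 0.0, s)
                _, cav = segment_lv(img, rois[s], seg)
                vol += cav.sum() * vox
            return abs(vol - truth.cavity_volume_ul[0]) / truth.cavity_volume_ul[0]

        assert edv_error(factor) <= edv_error(0.6) + 1e-9
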