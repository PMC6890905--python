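"""SUV conversion and threshold delineation contracts."""

import numpy as np
import pytest
from scipy.optimize import brentq

from petphanq.phantom import ConfigError, GridSpec, VoxelImage
from petphanq.profiles import ProfileParams, cold_wall_profile
from petphanq.segmentation import (
    ReferenceValues,
    RoiBox,
    roi_for_sphere,
    segment_fixed,
    segment_tbc,
    signed_deviation,
    suv_stats,
    to_suv,
)


def _roi_for(img, sphere, margin):
    return roi_for_sphere(img.grid, (0, 0, 0), sphere.outer_radius, margin)


class TestToSuv:
    def _img(self, value):
        grid = GridSpec(shape=(3, 3, 3), voxel_size=(4.1, 4.1, 3.0))
        return VoxelImage(np.full(grid.shape, float(value)), grid)

    def test_reference_suv_high_contrast(self):
        # 36.8 kBq/ml at 34.2 MBq in a 6.595 kg phantom -> SUV 7.1
        suv = to_suv(self._img(36.8), administered=34.2, weight=6.595)
        assert round(float(suv.values[0, 0, 0]), 1) == 7.1

    def test_reference_suv_low_contrast(self):
        suv = to_suv(self._img(20.9), administered=124.8, weight=6.595)
        assert round(float(suv.values[0, 0, 0]), 2) == 1.10

    def test_unit_suv(self):
        suv = to_suv(self._img(34.2 / 6.595), administered=34.2, weight=6.595)
        assert suv.values[1, 1, 1] == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            to_suv(self._img(1.0), administered=0.0, weight=6.595)


class TestSegmentFixed:
    def test_uniform_roi_not_applicable(self):
        grid = GridSpec(shape=(15, 15, 15), voxel_size=(4.1, 4.1, 3.0))
        img = VoxelImage(np.full(grid.shape, 4.0), grid)
        roi = RoiBox((2, 2, 2), (13, 13, 13))
        seg = segment_fixed(img, roi, 0.50)
        assert not seg.applicable
        assert seg.mask.all()

    def test_t50_volume_matches_analytic_isocontour(self, sphere_image):
        for diameter in (69.7, 49.9):
            img, spec, sphere, recon = sphere_image(diameter=diameter, margin=34.0)
            roi = _roi_for(img, sphere, 2 * recon.base_fwhm + 6 * 4.1)
            seg = segment_fixed(img, roi, 0.50)
            assert seg.applicable
            p = ProfileParams(36.8, 2.3, sphere.inner_radius, 1.2, recon.base_fwhm)
            level = 0.5 * img.values[roi.slices].max()
            r_star = brentq(lambda r: cold_wall_profile(r, p) - level, 1e-3, 60.0)
            analytic = 4.0 / 3.0 * np.pi * r_star**3 / 1000.0
            assert seg.mtv == pytest.approx(analytic, rel=0.03)

    def test_threshold_nesting(self, sphere_image):
        img, spec, sphere, recon = sphere_image(diameter=69.7, margin=34.0)
        roi = _roi_for(img, sphere, 2 * recon.base_fwhm + 6 * 4.1)
        m40 = segment_fixed(img, roi, 0.40)
        m50 = segment_fixed(img, roi, 0.50)
        m60 = segment_fixed(img, roi, 0.60)
        assert np.all(m60.mask <= m50.mask)
        assert np.all(m50.mask <= m40.mask)
        assert m60.mtv < m50.mtv < m40.mtv

    def test_mtv_deviation_grows_for_smaller_spheres(self, sphere_image):
        devs = []
        for diameter in (69.7, 49.9, 39.8, 29.9):
            img, spec, sphere, recon = sphere_image(diameter=diameter, margin=34.0)
            roi = _roi_for(img, sphere, 2 * recon.base_fwhm + 6 * 4.1)
            seg = segment_fixed(img, roi, 0.60)
            devs.append(abs(signed_deviation(seg.mtv, sphere.inner_volume_ml)))
        assert devs[0] < devs[-1]


class TestSegmentTbc:
    def test_zero_background_reduces_to_fixed_39(self, sphere_image):
        img, spec, sphere, recon = sphere_image(background=0.0, margin=34.0)
        roi = _roi_for(img, sphere, 2 * recon.base_fwhm + 6 * 4.1)
        tbc = segment_tbc(img, roi)
        fixed = segment_fixed(img, roi, 0.39)
        assert tbc.converged
        assert np.array_equal(tbc.mask, fixed.mask)

    def test_background_and_volume_match_oracle(self, sphere_image):
        img, spec, sphere, recon = sphere_image(diameter=69.7, margin=34.0)
        roi = _roi_for(img, sphere, 2 * recon.base_fwhm + 6 * 4.1)
        seg = segment_tbc(img, roi)
        assert seg.converged and seg.applicable
        assert seg.background_estimate == pytest.approx(2.3, rel=0.05)
        vmax = img.values[roi.slices].max()
        level = 2.3 + 0.39 * (vmax - 2.3)
        p = ProfileParams(36.8, 2.3, sphere.inner_radius, 1.2, recon.base_fwhm)
        r_star = brentq(lambda r: cold_wall_profile(r, p) - level, 1e-3, 60.0)
        analytic = 4.0 / 3.0 * np.pi * r_star**3 / 1000.0
        assert seg.mtv == pytest.approx(analytic, rel=0.03)

    def test_independent_of_initial_fraction(self, sphere_image):
        img, spec, sphere, recon = sphere_image(diameter=49.9, margin=34.0)
        roi = _roi_for(img, sphere, 2 * recon.base_fwhm + 6 * 4.1)
        ref = segment_tbc(img, roi, init_fraction=0.50)
        for init in (0.45, 0.60):
            alt = segment_tbc(img, roi, init_fraction=init)
            assert np.array_equal(alt.mask, ref.mask)

    def test_converges_quickly_noise_free(self, sphere_image):
        for diameter in (29.9, 39.8, 49.9, 69.7):
            img, spec, sphere, recon = sphere_image(diameter=diameter, margin=34.0)
            roi = _roi_for(img, sphere, 2 * recon.base_fwhm + 6 * 4.1)
            seg = segment_tbc(img, roi)
            assert seg.converged
            assert seg.iterations <= 10


class TestSuvStatsAndDeviation:
    def test_single_voxel_mask(self):
        grid = GridSpec(shape=(5, 5, 5), voxel_size=(4.1, 4.1, 3.0))
        vals = np.zeros(grid.shape)
        vals[2, 2, 2] = 9.0
        img = VoxelImage(vals, grid)
        roi = RoiBox((1, 1, 1), (4, 4, 4))
        seg = segment_fixed(img, roi, 0.5)
        smax, smean = suv_stats(img, seg)
        assert smax == smean == 9.0

    def test_partial_volume_mean_matches_profile_average(self, sphere_image):
        img, spec, sphere, recon = sphere_image(diameter=69.7, margin=34.0)
        roi = _roi_for(img, sphere, 2 * recon.base_fwhm + 6 * 4.1)
        seg = segment_fixed(img, roi, 0.50)
        cmax, cmean = suv_stats(img, seg)  # concentration units here
        assert cmean < 36.8  # partial volume: mask mean below true signal
        p = ProfileParams(36.8, 2.3, sphere.inner_radius, 1.2, recon.base_fwhm)
        level = 0.5 * img.values[roi.slices].max()
        r_star = brentq(lambda r: cold_wall_profile(r, p) - level, 1e-3, 60.0)
        rr = np.linspace(0.0, r_star, 4000)
        analytic_mean = np.trapezoid(
            cold_wall_profile(rr, p) * rr**2, rr
        ) / np.trapezoid(rr**2, rr)
        assert cmean == pytest.approx(analytic_mean, rel=0.03)

    def test_signed_deviation_examples(self):
        assert signed_deviation(6.4, 7.1) == pytest.approx(-9.86, abs=0.01)
        assert signed_deviation(7.1, 7.1) == 0.0
        assert signed_deviation(13.6 * 0.9, 13.6) == pytest.approx(-10.0)
        with pytest.raises(ValueError):
            signed_deviation(1.0, 0.0)

    def test_reference_values_validated(self):
        ReferenceValues(reference_suv=7.1)
        with pytest.raises(ValueError):
            ReferenceValues(reference_suv=0.0)
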