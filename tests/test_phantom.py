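"""Phantom painting, reconstruction emulation and noise contracts."""

import math

import numpy as np
import pytest

from petphanq.phantom import (
    ConfigError,
    GeometryError,
    GridSpec,
    PhantomSpec,
    ReconEmulation,
    SphereSpec,
    VoxelImage,
    add_noise,
    default_spheres,
    emulate_reconstruction,
    paint_phantom,
    simulate_reconstructed,
    table_measurements,
)
from petphanq.profiles import ProfileParams, dog_ringing_profile
from petphanq.radial import bin_profile, extract_profile


def centered_grid(half_xy: float, half_z: float, voxel=(4.1, 4.1, 3.0)) -> GridSpec:
    shape = tuple(
        2 * int(np.ceil(h / v)) + 1 for h, v in zip((half_xy, half_xy, half_z), voxel)
    )
    return GridSpec(shape=shape, voxel_size=voxel)


class TestPaintPhantom:
    def test_degenerate_contrast_gives_uniform_interior(self):
        spheres = (SphereSpec((0.0, 0.0, 0.0), 49.9, wall_thickness=0.0),)
        spec = PhantomSpec(5.0, 5.0, 34.2, spheres=spheres)
        grid = centered_grid(60, 60)
        img = paint_phantom(spec, grid, supersample=2)
        x, y, z = grid.center_grids()
        interior = (np.sqrt(x**2 + y**2) < 50) & (np.abs(z) < 50)
        assert np.allclose(img.values[np.broadcast_to(interior, grid.shape)], 5.0)

    def test_table_concentrations_at_sphere_centers_and_background(self):
        spec = table_measurements()["SBR1"]
        grid = centered_grid(105, 108)
        img = paint_phantom(spec, grid, supersample=2)
        for s in spec.spheres:
            idx = tuple(np.round(grid.physical_to_index(s.center)).astype(int))
            assert img.values[idx] == pytest.approx(36.8)
        deep = tuple(np.round(grid.physical_to_index((0.0, 0.0, 50.0))).astype(int))
        assert img.values[deep] == pytest.approx(2.3)
        assert spec.sbr == pytest.approx(36.8 / 2.3)

    def test_total_activity_matches_analytic_region_volumes(self):
        spec = table_measurements()["SBR1"]
        grid = centered_grid(110, 110)  # covers the whole cylinder
        img = paint_phantom(spec, grid, supersample=4)
        v_in = sum(4 / 3 * math.pi * s.inner_radius**3 for s in spec.spheres) / 1000
        v_out = sum(4 / 3 * math.pi * s.outer_radius**3 for s in spec.spheres) / 1000
        analytic = 36.8 * v_in + 2.3 * (spec.cylinder_volume - v_out)
        assert img.total_activity_kbq == pytest.approx(analytic, rel=0.005)

    def test_supersample_refinement_stable_interior_volume(self):
        sphere = SphereSpec((0.0, 0.0, 0.0), 69.7)
        spec = PhantomSpec(36.8, 2.3, 34.2, spheres=(sphere,))
        grid = centered_grid(55, 55)
        vols = []
        for ss in (4, 8):
            img = paint_phantom(spec, grid, supersample=ss)
            interior = img.values > 0.5 * (36.8 + 2.3)
            vols.append(interior.sum() * grid.voxel_volume_ml)
        assert abs(vols[1] - vols[0]) / vols[1] < 0.005

    def test_overlapping_spheres_rejected(self):
        spheres = (
            SphereSpec((0.0, 0.0, 0.0), 49.9),
            SphereSpec((30.0, 0.0, 0.0), 49.9),
        )
        spec = PhantomSpec(10.0, 1.0, 34.2, spheres=spheres)
        with pytest.raises(GeometryError, match="overlap"):
            paint_phantom(spec, centered_grid(80, 60), 2)

    def test_sphere_outside_cylinder_rejected(self):
        spheres = (SphereSpec((90.0, 0.0, 0.0), 49.9),)
        spec = PhantomSpec(10.0, 1.0, 34.2, spheres=spheres)
        with pytest.raises(GeometryError, match="cylinder"):
            paint_phantom(spec, centered_grid(120, 60), 2)

    def test_default_placement_is_valid_geometry(self):
        spheres = default_spheres()
        for i, a in enumerate(spheres):
            for b in spheres[i + 1 :]:
                gap = math.dist(a.center, b.center) - a.outer_radius - b.outer_radius
                assert gap >= 15.0


class TestEmulateReconstruction:
    def test_identity_kernel_limit(self):
        sphere = SphereSpec((0.0, 0.0, 0.0), 49.9)
        spec = PhantomSpec(36.8, 2.3, 34.2, spheres=(sphere,))
        img = paint_phantom(spec, centered_grid(60, 60), 2)
        recon = ReconEmulation(
            psf_fwhm=1e-6, post_filter_fwhm=0.0, compensate_voxel_average=False
        )
        out = emulate_reconstruction(img, recon)
        assert np.allclose(out.values, img.values, atol=1e-9)

    def test_mass_conservation_compact_support(self):
        # zero background: all activity far from the grid edge
        sphere = SphereSpec((0.0, 0.0, 0.0), 49.9)
        spec = PhantomSpec(36.8, 0.0, 34.2, spheres=(sphere,))
        img = paint_phantom(spec, centered_grid(60, 60), 2)
        out = emulate_reconstruction(img, ReconEmulation(psf_fwhm=4.0))
        assert out.values.sum() == pytest.approx(img.values.sum(), rel=1e-3)

    def test_blur_profile_monotone_across_edge(self):
        recon = ReconEmulation(psf_fwhm=4.0)
        for d in (29.9, 39.8, 49.9, 69.7):
            sphere = SphereSpec((0.0, 0.0, 0.0), d)
            spec = PhantomSpec(36.8, 2.3, 34.2, spheres=(sphere,))
            r_max = sphere.inner_radius + 4 * recon.base_fwhm
            grid = centered_grid(r_max + 10, r_max + 10)
            img = simulate_reconstructed(spec, grid, recon, oversample=3)
            bp = bin_profile(extract_profile(img, (0, 0, 0), r_max), 1.0)
            assert np.all(np.diff(bp.bin_means) <= 0.02 * 36.8), f"d={d}"

    def test_ringing_peak_matches_closed_form(self):
        sphere = SphereSpec((0.0, 0.0, 0.0), 69.7, wall_thickness=0.0)
        spec = PhantomSpec(1.0, 0.0, 34.2, spheres=(sphere,))
        recon = ReconEmulation(
            psf_fwhm=4.0, ringing_alpha=1.0, ringing_fwhm_pair=(0.0, 6.0),
            post_filter_fwhm=0.0,
        )
        grid = centered_grid(60, 60)
        img = simulate_reconstructed(spec, grid, recon, oversample=3)
        prof = extract_profile(img, (0, 0, 0), 45.0)
        p = ProfileParams(1.0, 0.0, sphere.inner_radius, 0.0, recon.base_fwhm)
        r_dense = np.linspace(0.0, 45.0, 2000)
        predicted_peak = dog_ringing_profile(r_dense, p, 1.0, 0.0, 6.0).max()
        assert prof.values.max() == pytest.approx(predicted_peak, rel=0.01)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ConfigError):
            ReconEmulation(psf_fwhm=0.0)
        with pytest.raises(ConfigError):
            ReconEmulation(psf_fwhm=4.0, post_filter_fwhm=-1.0)


class TestAddNoise:
    def _blurred(self):
        sphere = SphereSpec((0.0, 0.0, 0.0), 69.7)
        spec = PhantomSpec(36.8, 2.3, 34.2, spheres=(sphere,))
        img = paint_phantom(spec, centered_grid(55, 55), 2)
        return emulate_reconstruction(img, ReconEmulation(psf_fwhm=4.0))

    def test_zero_cv_is_identity(self):
        img = self._blurred()
        out = add_noise(img, 0.0, seed=1)
        assert np.array_equal(out.values, img.values)

    def test_same_seed_bit_identical(self):
        img = self._blurred()
        a = add_noise(img, 0.05, seed=7, reference_level=36.8)
        b = add_noise(img, 0.05, seed=7, reference_level=36.8)
        assert np.array_equal(a.values, b.values)
        c = add_noise(img, 0.05, seed=8, reference_level=36.8)
        assert not np.array_equal(a.values, c.values)

    def test_region_mean_within_clt_bound(self):
        img = self._blurred()
        noisy = add_noise(img, 0.05, seed=3, reference_level=36.8)
        grid = img.grid
        x, y, z = grid.center_grids()
        region = np.broadcast_to(
            np.sqrt(x**2 + y**2 + z**2) < 24.5, grid.shape
        )
        n = int(region.sum())
        assert n > 1000
        per_voxel_sd = 0.05 * np.sqrt(np.maximum(img.values[region], 0) * 36.8)
        se = np.sqrt(np.mean(per_voxel_sd**2) / n)
        dev = noisy.values[region].mean() - img.values[region].mean()
        assert abs(dev) < 3.0 * se


class TestSpecValidation:
    def test_sbr_requires_signal_above_background(self):
        with pytest.raises(ConfigError):
            PhantomSpec(1.0, 2.0, 34.2)

    def test_default_weight_from_volume(self):
        spec = PhantomSpec(36.8, 2.3, 34.2)
        assert spec.phantom_weight == pytest.approx(6.595)

    def test_voxel_center_convention(self):
        grid = GridSpec(shape=(10, 10, 10), voxel_size=(4.0, 4.0, 2.0), origin=(0.0, 0.0, 0.0))
        assert np.allclose(grid.index_to_physical((0, 0, 0)), (2.0, 2.0, 1.0))
        assert np.allclose(grid.physical_to_index((2.0, 2.0, 1.0)), (0, 0, 0))

    def test_image_shape_mismatch_rejected(self):
        grid = GridSpec(shape=(4, 4, 4), voxel_size=(1, 1, 1))
        with pytest.raises(ConfigError):
            VoxelImage(np.zeros((3, 3, 3)), grid)
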