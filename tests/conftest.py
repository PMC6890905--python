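"""Shared fixtures: small single-sphere phantom images built on demand."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from petphanq.phantom import (
    GridSpec,
    PhantomSpec,
    ReconEmulation,
    SphereSpec,
    simulate_reconstructed,
)

#: Ground-truth concentrations (sphere, background) of the three fill levels.
CONCENTRATIONS = {"SBR1": (36.8, 2.3), "SBR2": (28.9, 4.8), "SBR3": (20.9, 9.0)}


def brute_force_profile(R, sigma, radii, h=0.25, background=0.0, signal=1.0, wall=0.0):
    """Independent numeric oracle for the analytic radial profile.

    Voxelises the (cold-wall) sphere on an ``h``-mm grid with linear
    edge antialiasing, convolves with a sampled Gaussian and reads the
    result along a grid axis through the centre.  Entirely independent
    of the closed-form expressions it is used to validate.
    """
    from scipy import ndimage

    half = R + wall + 9.0 * sigma
    n = int(np.ceil(half / h))
    ax = np.arange(-n, n + 1) * h
    d = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    inner = np.clip((R - d) / h + 0.5, 0.0, 1.0)
    vol = signal * inner
    if background > 0 or wall > 0:
        outer = np.clip((R + wall - d) / h + 0.5, 0.0, 1.0)
        vol = vol + background * (1.0 - outer)
    mode = "nearest" if background > 0 else "constant"
    blur = ndimage.gaussian_filter(vol, sigma / h, truncate=8.0, mode=mode)
    return np.interp(radii, ax[n:], blur[n, n, n:])


@lru_cache(maxsize=32)
def _sphere_image_cached(
    diameter: float,
    signal: float,
    background: float,
    psf_fwhm: float,
    ringing_alpha: float,
    fwhm_b: float,
    post_filter: float,
    oversample: int,
    margin: float,
):
    sphere = SphereSpec((0.0, 0.0, 0.0), diameter)
    spec = PhantomSpec(signal, background, 34.2, spheres=(sphere,))
    recon = ReconEmulation(
        psf_fwhm=psf_fwhm,
        ringing_alpha=ringing_alpha,
        ringing_fwhm_pair=(0.0, fwhm_b),
        post_filter_fwhm=post_filter,
    )
    half = sphere.inner_radius + 4.0 * recon.base_fwhm + margin
    n_xy = 2 * int(np.ceil(half / 4.1)) + 1
    n_z = 2 * int(np.ceil(half / 3.0)) + 1
    grid = GridSpec(shape=(n_xy, n_xy, n_z), voxel_size=(4.1, 4.1, 3.0))
    img = simulate_reconstructed(spec, grid, recon, oversample=oversample)
    return img, spec, sphere, recon


@pytest.fixture(scope="session")
def sphere_image():
    """Factory: centred single-sphere phantom image on a 4.1 x 4.1 x 3 grid.

    The sphere centre coincides with a voxel centre, so the measured
    maximum of a noise-free blurred image equals the analytic profile
    at r = 0.  Results are cached across tests.
    """

    def make(
        diameter: float = 69.7,
        signal: float = 36.8,
        background: float = 2.3,
        psf_fwhm: float = 4.0,
        ringing_alpha: float = 0.0,
        fwhm_b: float = 6.0,
        post_filter: float = 2.0,
        oversample: int = 3,
        margin: float = 16.0,
    ):
        return _sphere_image_cached(
            diameter, signal, background, psf_fwhm, ringing_alpha,
            fwhm_b, post_filter, oversample, margin,
        )

    return make
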