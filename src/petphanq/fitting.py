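"""Spatial-resolution estimation by radial-profile model fitting.

The FWHM of the effective point spread function is estimated per sphere
by a bounded non-linear least-squares fit of the analytic cold-wall
sphere profile (see :mod:`petphanq.profiles`) to the unbinned radial
samples.  Four parameters are free — signal, background, sphere radius
and FWHM — while the wall thickness is fixed to its known value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .profiles import FWHM_PER_SIGMA, ProfileParams, cold_wall_profile
from .radial import RadialProfile

__all__ = [
    "PreconditionError",
    "ProfileFit",
    "fit_profile",
    "fwhm_sigma_convert",
    "summarize_resolution",
]


class PreconditionError(ValueError):
    """Input does not satisfy the preconditions of the fit."""


@dataclass(frozen=True)
class ProfileFit:
    """Result of one radial-profile fit."""

    params: ProfileParams  # fitted S, B, R, fwhm; wall fixed
    rmse: float  # kBq/ml
    n_samples: int
    converged: bool
    covariance: np.ndarray  # 4x4, order (S, B, R, fwhm)

    @property
    def fwhm(self) -> float:
        return self.params.fwhm


def fwhm_sigma_convert(x: float, to: str = "sigma") -> float:
    """Convert between Gaussian FWHM and sigma (``to`` = "sigma" or "fwhm")."""
    if x <= 0:
        raise ValueError("x must be positive")
    if to == "sigma":
        return x / FWHM_PER_SIGMA
    if to == "fwhm":
        return x * FWHM_PER_SIGMA
    raise ValueError("to must be 'sigma' or 'fwhm'")


def _residuals(theta: np.ndarray, radii: np.ndarray, values: np.ndarray, wall: float):
    s, b, rad, fwhm = theta
    p = ProfileParams(max(s, 0.0), max(b, 0.0), rad, wall, fwhm)
    return cold_wall_profile(radii, p) - values


def fit_profile(
    profile: RadialProfile,
    nominal_radius: float,
    wall: float = 1.2,
    voxel_size: float = 4.1,
    n_restarts: int = 3,
) -> ProfileFit:
    """Fit the cold-wall sphere profile model to unbinned radial samples.

    Minimises the unweighted sum of squared residuals over
    (signal, background, radius, fwhm) with the wall thickness fixed.
    Initialisation: signal = 99th percentile of the values, background
    = median of samples beyond ``nominal_radius + 3 voxels``, radius =
    ``nominal_radius``, fwhm = 1.5x the voxel size.  Bounds: signal and
    background non-negative, radius within [0.5, 1.5]x nominal, fwhm in
    [0.5x voxel, 4x nominal radius].  On non-convergence the
    initialisation is jittered up to ``n_restarts`` times with fixed
    seeds; a still-unconverged fit is returned flagged, not raised.
    """
    radii = np.asarray(profile.radii, dtype=float)
    values = np.asarray(profile.values, dtype=float)
    if len(radii) < 50:
        raise PreconditionError("need at least 50 radial samples")
    if not (np.any(radii < nominal_radius) and np.any(radii > nominal_radius)):
        raise PreconditionError("samples must span inside and outside the nominal radius")

    outside = radii > nominal_radius + 3.0 * voxel_size
    b0 = float(np.median(values[outside])) if np.any(outside) else float(values.min())
    s0 = float(np.percentile(values, 99))
    x0 = np.array([s0, max(b0, 0.0), nominal_radius, 1.5 * voxel_size])

    lo = np.array([0.0, 0.0, 0.5 * nominal_radius, 0.5 * voxel_size])
    hi = np.array([np.inf, np.inf, 1.5 * nominal_radius, 4.0 * nominal_radius])
    x0 = np.clip(x0, lo + 1e-9, None)

    scale = np.array([max(s0, 1e-6), max(s0, 1e-6), nominal_radius, voxel_size])

    best = None
    for attempt in range(1 + n_restarts):
        start = x0
        if attempt > 0:
            rng = np.random.default_rng(attempt - 1)
            start = np.clip(x0 * (1.0 + 0.1 * rng.standard_normal(4)), lo + 1e-9, None)
            start = np.minimum(start, np.where(np.isfinite(hi), hi - 1e-9, start))
        res = least_squares(
            _residuals,
            start,
            bounds=(lo, hi),
            args=(radii, values, wall),
            x_scale=scale,
            method="trf",
        )
        if best is None or res.cost < best.cost:
            best = res
        if res.status > 0 and np.all(np.isfinite(res.x)):
            best = res if res.cost <= best.cost else best
            break

    converged = bool(best.status > 0 and np.all(np.isfinite(best.x)))
    s, b, rad, fwhm = best.x
    n = len(radii)
    dof = max(n - 4, 1)
    sigma2 = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = sigma2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        cov = np.full((4, 4), np.nan)

    return ProfileFit(
        params=ProfileParams(float(s), float(b), float(rad), wall, float(fwhm)),
        rmse=float(np.sqrt(2.0 * best.cost / n)),
        n_samples=n,
        converged=converged,
        covariance=cov,
    )


def summarize_resolution(fits: list[ProfileFit]) -> tuple[float, tuple[float, float]]:
    """Mean and (min, max) FWHM over the converged fits."""
    vals = [f.fwhm for f in fits if f.converged]
    if not vals:
        raise PreconditionError("no converged fits to summarise")
    return float(np.mean(vals)), (float(min(vals)), float(max(vals)))
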