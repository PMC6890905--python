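"""Synthetic cylinder-and-spheres phantom images.

Generates ground-truth voxel images of a water-filled cylinder phantom
containing cold-wall sphere inserts, and emulates the appearance of
reconstructed PET volumes by Gaussian blurring, optional
difference-of-Gaussians edge sharpening (the overshoot signature of
resolution-recovery reconstructions) and optional noise.

Geometry and activity defaults follow the common image-quality setup:
a 20 cm diameter cylinder (6,595 ml) with four spheres of inner
diameter 29.9 / 39.8 / 49.9 / 69.7 mm and 1.2 mm plastic walls, imaged
on a 200 x 200 in-plane grid with 4.1 x 4.1 mm voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryError",
    "ConfigError",
    "SphereSpec",
    "PhantomSpec",
    "GridSpec",
    "ReconEmulation",
    "VoxelImage",
    "DEFAULT_SPHERE_DIAMETERS",
    "default_spheres",
    "table_measurements",
    "paint_phantom",
    "emulate_reconstruction",
    "simulate_reconstructed",
    "add_noise",
]


class GeometryError(ValueError):
    """Phantom geometry is inconsistent (overlap, outside cylinder, ...)."""


class ConfigError(ValueError):
    """Invalid simulation or reconstruction-emulation configuration."""


#: Inner diameters (mm) of the four standard sphere inserts.
DEFAULT_SPHERE_DIAMETERS = (29.9, 39.8, 49.9, 69.7)


@dataclass(frozen=True)
class SphereSpec:
    """One cold-wall sphere insert.

    ``center`` is the physical position of the sphere centre in mm,
    ``inner_diameter`` the diameter of the active interior, and
    ``wall_thickness`` the thickness of the inactive shell.
    """

    center: tuple[float, float, float]
    inner_diameter: float
    wall_thickness: float = 1.2

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise GeometryError("inner_diameter must be positive")
        if self.wall_thickness < 0:
            raise GeometryError("wall_thickness must be non-negative")

    @property
    def inner_radius(self) -> float:
        return 0.5 * self.inner_diameter

    @property
    def outer_radius(self) -> float:
        return self.inner_radius + self.wall_thickness

    @property
    def inner_volume_ml(self) -> float:
        return (4.0 / 3.0) * math.pi * self.inner_radius**3 / 1000.0


def default_spheres(
    diameters: tuple[float, ...] = DEFAULT_SPHERE_DIAMETERS,
    ring_radius: float = 60.0,
    largest_ring_radius: float = 45.0,
    wall_thickness: float = 1.2,
    z: float = 0.0,
) -> tuple[SphereSpec, ...]:
    """Standard sphere placement: coplanar, equally spaced in azimuth.

    Centres sit near the radial centre of the field of view in the
    central transaxial plane, the two largest spheres on opposite
    sides.  The largest sphere is placed on a slightly smaller ring so
    that its blurred edge and background shell stay clear of the
    cylinder wall; all surface-to-surface gaps exceed 15 mm.
    """
    order = np.argsort(diameters)[::-1]  # largest first
    # largest opposite the 2nd largest, smaller spheres in between
    slots = [0, 2, 1, 3][: len(diameters)]
    angles = np.linspace(0.0, 2.0 * math.pi, num=len(diameters), endpoint=False)
    spheres = []
    for n, (rank, slot) in enumerate(zip(order, slots)):
        a = angles[slot]
        rho = largest_ring_radius if n == 0 else ring_radius
        c = (rho * math.cos(a), rho * math.sin(a), z)
        spheres.append(SphereSpec(c, diameters[rank], wall_thickness))
    return tuple(spheres)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry plus ground-truth activity of one phantom measurement."""

    sphere_concentration: float  # kBq/ml
    background_concentration: float  # kBq/ml
    administered_activity: float  # MBq
    spheres: tuple[SphereSpec, ...] = field(default_factory=default_spheres)
    cylinder_diameter: float = 200.0  # mm
    cylinder_volume: float = 6595.0  # ml
    phantom_weight: float | None = None  # kg; default volume * 1 g/ml

    def __post_init__(self) -> None:
        if self.background_concentration < 0:
            raise ConfigError("background concentration must be non-negative")
        if self.sphere_concentration < self.background_concentration:
            raise ConfigError("sphere concentration must be >= background")
        if self.administered_activity <= 0:
            raise ConfigError("administered activity must be positive")
        if self.phantom_weight is None:
            object.__setattr__(self, "phantom_weight", self.cylinder_volume / 1000.0)

    @property
    def sbr(self) -> float:
        """Signal-to-background ratio of the ground truth."""
        return self.sphere_concentration / self.background_concentration

    @property
    def cylinder_radius(self) -> float:
        return 0.5 * self.cylinder_diameter

    @property
    def cylinder_height(self) -> float:
        """Axial extent (mm) implied by the nominal volume."""
        return self.cylinder_volume * 1000.0 / (math.pi * self.cylinder_radius**2)


def table_measurements(
    spheres: tuple[SphereSpec, ...] | None = None,
) -> dict[str, PhantomSpec]:
    """The three standard fill levels of the phantom protocol.

    Sphere concentration is fixed while activity is added to the
    background between measurements, stepping the signal-to-background
    ratio from ~16:1 down to ~2.3:1.
    """
    rows = {
        "SBR1": (34.2, 36.8, 2.3),
        "SBR2": (53.6, 28.9, 4.8),
        "SBR3": (124.8, 20.9, 9.0),
    }
    out = {}
    for name, (admin, s, b) in rows.items():
        kw = {} if spheres is None else {"spheres": spheres}
        out[name] = PhantomSpec(
            sphere_concentration=s,
            background_concentration=b,
            administered_activity=admin,
            **kw,
        )
    return out


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid with physical coordinates.

    Voxel-centre convention: the centre of voxel (i, j, k) is at
    ``origin + (i + 1/2, j + 1/2, k + 1/2) * voxel_size`` (mm, 0-based
    indices).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (4.1, 4.1, 5.0)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ConfigError("grid shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigError("voxel size must be positive")
        if self.origin is None:
            # centre the grid so that the voxel at index n//2 has its
            # centre exactly at the physical origin
            org = tuple(
                -(n // 2 + 0.5) * v for n, v in zip(self.shape, self.voxel_size)
            )
            object.__setattr__(self, "origin", org)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def center_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (nx,1,1), (1,ny,1), (1,1,nz) centre coordinates."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def index_to_physical(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.voxel_size)

    def physical_to_index(self, pos) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.voxel_size) - 0.5


@dataclass(frozen=True)
class ReconEmulation:
    """Parameters of the reconstruction emulation.

    The emulation stands in for the net effect of a reconstruction
    algorithm on the image: an isotropic Gaussian blur of width
    ``psf_fwhm``, an optional difference-of-Gaussians sharpening
    (``ringing_alpha`` > 0) producing edge overshoot like
    resolution-recovery algorithms, and the routine Gaussian
    post-filter.  ``noise_cv`` adds signal-dependent Gaussian noise.
    """

    psf_fwhm: float  # mm
    ringing_alpha: float = 0.0
    ringing_fwhm_pair: tuple[float, float] = (0.0, 6.0)
    post_filter_fwhm: float = 2.0
    noise_cv: float = 0.0
    seed: int = 0
    compensate_voxel_average: bool = True

    def __post_init__(self) -> None:
        if self.psf_fwhm <= 0:
            raise ConfigError("psf_fwhm must be positive")
        if self.post_filter_fwhm < 0:
            raise ConfigError("post_filter_fwhm must be non-negative")
        fa, fb = self.ringing_fwhm_pair
        if self.ringing_alpha < 0:
            raise ConfigError("ringing_alpha must be non-negative")
        if self.ringing_alpha > 0 and not (fb > fa >= 0):
            raise ConfigError("ringing pair must satisfy fb > fa >= 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")

    @property
    def base_fwhm(self) -> float:
        """FWHM of the pure blur chain (PSF + post-filter in quadrature)."""
        return float(np.hypot(self.psf_fwhm, self.post_filter_fwhm))

    def effective_fwhm(self, kernel_fwhm: float) -> float:
        """Total FWHM of one DoG branch incl. PSF, kernel and post-filter."""
        return float(
            math.sqrt(self.psf_fwhm**2 + kernel_fwhm**2 + self.post_filter_fwhm**2)
        )


@dataclass
class VoxelImage:
    """A 3D activity-concentration image (kBq/ml) on a physical grid."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ConfigError("values shape does not match grid shape")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("image contains non-finite values")

    @property
    def total_activity_kbq(self) -> float:
        """Sum of voxel values times voxel volume (kBq)."""
        return float(self.values.sum() * self.grid.voxel_volume_ml)


# ---------------------------------------------------------------------------
# painting


def _sphere_fill_fraction(grid: GridSpec, center, radius: float, supersample: int) -> np.ndarray:
    """Per-voxel fill fraction of a sphere, supersampling edge voxels only."""
    x, y, z = grid.center_grids()
    dx, dy, dz = (x - center[0]), (y - center[1]), (z - center[2])
    dist = np.sqrt(dx**2 + dy**2 + dz**2)
    half_diag = 0.5 * math.sqrt(sum(v**2 for v in grid.voxel_size))

    frac = np.zeros(grid.shape)
    frac[dist <= radius - half_diag] = 1.0
    edge = (dist > radius - half_diag) & (dist < radius + half_diag)
    if not np.any(edge):
        return frac

    ii, jj, kk = np.nonzero(edge)
    centers = grid.index_to_physical(np.stack([ii, jj, kk], axis=1))
    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5  # fractions of a voxel
    ox, oy, oz = np.meshgrid(
        offs * grid.voxel_size[0], offs * grid.voxel_size[1], offs * grid.voxel_size[2],
        indexing="ij",
    )
    sub = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (s^3, 3)
    pts = centers[:, None, :] + sub[None, :, :] - np.asarray(center)
    inside = (pts**2).sum(axis=2) <= radius**2
    frac[ii, jj, kk] = inside.mean(axis=1)
    return frac


def _cylinder_fill_fraction(
    grid: GridSpec, radius: float, half_height: float, supersample: int
) -> np.ndarray:
    """Fill fraction of a z-aligned cylinder centred at the origin.

    Separable: transaxial disc fraction (supersampled in 2D) times the
    analytic axial interval overlap.
    """
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    rho = np.sqrt(xs[:, None] ** 2 + ys[None, :] ** 2)
    half_diag2d = 0.5 * math.hypot(grid.voxel_size[0], grid.voxel_size[1])

    disc = np.zeros((grid.shape[0], grid.shape[1]))
    disc[rho <= radius - half_diag2d] = 1.0
    edge = (rho > radius - half_diag2d) & (rho < radius + half_diag2d)
    if np.any(edge):
        ii, jj = np.nonzero(edge)
        s = supersample
        offs = (np.arange(s) + 0.5) / s - 0.5
        ox, oy = np.meshgrid(offs * grid.voxel_size[0], offs * grid.voxel_size[1], indexing="ij")
        px = xs[ii][:, None] + ox.ravel()[None, :]
        py = ys[jj][:, None] + oy.ravel()[None, :]
        disc[ii, jj] = (px**2 + py**2 <= radius**2).mean(axis=1)

    zs = grid.axis_centers(2)
    hz = 0.5 * grid.voxel_size[2]
    lo = np.maximum(zs - hz, -half_height)
    hi = np.minimum(zs + hz, half_height)
    zfrac = np.clip(hi - lo, 0.0, None) / (2.0 * hz)
    return disc[:, :, None] * zfrac[None, None, :]


def _validate_geometry(spec: PhantomSpec) -> None:
    h2 = 0.5 * spec.cylinder_height
    for i, s in enumerate(spec.spheres):
        rho = math.hypot(s.center[0], s.center[1])
        if rho + s.outer_radius > spec.cylinder_radius + 1e-9:
            raise GeometryError(f"sphere {i} extends beyond the cylinder wall")
        if abs(s.center[2]) + s.outer_radius > h2 + 1e-9:
            raise GeometryError(f"sphere {i} extends beyond the cylinder end caps")
    for i, a in enumerate(spec.spheres):
        for j, b in enumerate(spec.spheres[i + 1 :], start=i + 1):
            d = math.dist(a.center, b.center)
            if d < a.outer_radius + b.outer_radius:
                raise GeometryError(f"spheres {i} and {j} overlap")


def paint_phantom(spec: PhantomSpec, grid: GridSpec, supersample: int = 4) -> VoxelImage:
    """Voxelise the phantom ground truth onto a grid.

    Each voxel value is the volume-weighted mixture of the sphere
    concentration (inside the inner radius), zero (wall shell),
    background concentration (inside the cylinder, outside all
    spheres) and zero (outside the cylinder); partial-volume voxels at
    region boundaries are resolved by ``supersample^3`` sub-voxel
    sampling (the disc boundary of the cylinder separably in 2D).
    """
    if supersample < 1:
        raise ConfigError("supersample must be >= 1")
    _validate_geometry(spec)

    values = spec.background_concentration * _cylinder_fill_fraction(
        grid, spec.cylinder_radius, 0.5 * spec.cylinder_height, supersample
    )
    for s in spec.spheres:
        inner = _sphere_fill_fraction(grid, s.center, s.inner_radius, supersample)
        if s.wall_thickness > 0:
            outer = _sphere_fill_fraction(grid, s.center, s.outer_radius, supersample)
        else:
            outer = inner
        values += spec.sphere_concentration * inner - spec.background_concentration * outer
    return VoxelImage(values, grid)


# ---------------------------------------------------------------------------
# reconstruction emulation


def _gaussian_transfer(freq2: np.ndarray, fwhm: float) -> np.ndarray:
    """Fourier transform of an isotropic Gaussian, |freq|^2 given."""
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-2.0 * math.pi**2 * sigma**2 * freq2)


def emulate_reconstruction(img: VoxelImage, recon: ReconEmulation) -> VoxelImage:
    """Apply the reconstruction emulation to a painted ground-truth image.

    Computes ``(1 + a) * img (x) G(fa') - a * img (x) G(fb')`` followed by
    the Gaussian post-filter, where each branch FWHM combines the base
    PSF and the kernel FWHM in quadrature and ``(x)`` is continuous 3D
    convolution.  With ``ringing_alpha = 0`` this is a plain Gaussian
    blur.  Every convolution conserves total activity (unit DC gain).

    The convolution is evaluated in the frequency domain on a
    zero-padded grid (padding at least four times the largest kernel
    FWHM) so there is no wrap-around.  Painted voxel values are volume
    averages, i.e. point samples of the scene pre-filtered by the voxel
    box; by default the box transfer function is divided out so output
    voxels are point samples of the blurred continuous scene — the
    sampling model of reconstructed PET and the one the radial profile
    fit assumes.  Within the representable band this compensation is
    bounded (gain < 1.6) and exact at DC.
    """
    fa, fb = recon.ringing_fwhm_pair
    fwhms = [recon.psf_fwhm, recon.post_filter_fwhm, fa, fb]
    pad_mm = 4.0 * max(fwhms)
    pad = [max(4, int(math.ceil(pad_mm / v))) for v in img.grid.voxel_size]
    arr = np.pad(img.values, [(p, p) for p in pad], mode="constant")

    freqs = [
        np.fft.rfftfreq(n, d=v) if ax == 2 else np.fft.fftfreq(n, d=v)
        for ax, (n, v) in enumerate(zip(arr.shape, img.grid.voxel_size))
    ]
    fx = freqs[0][:, None, None]
    fy = freqs[1][None, :, None]
    fz = freqs[2][None, None, :]
    freq2 = fx**2 + fy**2 + fz**2

    a = recon.ringing_alpha
    if a > 0:
        H = (1.0 + a) * _gaussian_transfer(freq2, recon.effective_fwhm(fa)) - a * _gaussian_transfer(
            freq2, recon.effective_fwhm(fb)
        )
    else:
        H = _gaussian_transfer(freq2, recon.base_fwhm)

    if recon.compensate_voxel_average:
        box = (
            np.sinc(img.grid.voxel_size[0] * fx)
            * np.sinc(img.grid.voxel_size[1] * fy)
            * np.sinc(img.grid.voxel_size[2] * fz)
        )
        H = H / box

    out = np.fft.irfftn(np.fft.rfftn(arr) * H, s=arr.shape, axes=(0, 1, 2))
    sl = tuple(slice(p, p + n) for p, n in zip(pad, img.grid.shape))
    return VoxelImage(out[sl], img.grid)


def simulate_reconstructed(
    spec: PhantomSpec,
    grid: GridSpec,
    recon: ReconEmulation,
    supersample: int = 4,
    oversample: int = 1,
    noise_seed: int | None = None,
) -> VoxelImage:
    """Paint, blur and (optionally) add noise in one step.

    ``oversample`` controls the fidelity of the reconstruction
    emulation: for values > 1 (odd) the phantom is painted and
    convolved on a grid refined by that factor and then decimated back
    to ``grid``, so the output voxels are genuine point samples of the
    blurred continuous scene, free of the aliasing that a sharp edge
    sampled at the scanner grid produces.  Oversampling by 3 reduces
    the FWHM bias of downstream profile fits from ~0.2 mm to ~0.01 mm
    at the cost of ~27x the convolution volume; the default of 1 keeps
    large factorial runs cheap.
    """
    if oversample < 1 or oversample % 2 == 0:
        raise ConfigError("oversample must be an odd positive integer")
    if oversample == 1:
        img = emulate_reconstruction(paint_phantom(spec, grid, supersample), recon)
    else:
        f = oversample
        fine = GridSpec(
            shape=tuple(n * f for n in grid.shape),
            voxel_size=tuple(v / f for v in grid.voxel_size),
            origin=grid.origin,
        )
        blurred = emulate_reconstruction(paint_phantom(spec, fine, supersample), recon)
        sl = tuple(slice(f // 2, None, f) for _ in range(3))
        img = VoxelImage(blurred.values[sl], grid)
    if recon.noise_cv > 0:
        if noise_seed is None:
            noise_seed = recon.seed
        img = add_noise(img, recon.noise_cv, noise_seed, reference_level=spec.sphere_concentration)
    return img


def add_noise(
    img: VoxelImage, noise_cv: float, seed: int, reference_level: float | None = None
) -> VoxelImage:
    """Add signal-dependent Gaussian noise emulating reconstructed PET.

    Each voxel receives ``Normal(0, noise_cv * sqrt(max(v, 0) * vbar))``
    noise, where ``vbar`` is the reference (sphere) concentration — a
    Poisson-like variance scaling so the coefficient of variation at
    the sphere level equals ``noise_cv``.  ``reference_level`` defaults
    to the image maximum.  Identical seeds give identical images.
    """
    if noise_cv < 0:
        raise ConfigError("noise_cv must be non-negative")
    if noise_cv == 0:
        return VoxelImage(img.values.copy(), img.grid)
    vbar = float(img.values.max()) if reference_level is None else float(reference_level)
    rng = np.random.default_rng(seed)
    std = noise_cv * np.sqrt(np.maximum(img.values, 0.0) * vbar)
    return VoxelImage(img.values + rng.normal(0.0, 1.0, img.values.shape) * std, img.grid)
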