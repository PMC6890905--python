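"""Threshold-based sphere delineation and SUV quantification.

Implements the four delineation methods compared in sphere-phantom
studies — fixed thresholds at 40/50/60% of the measured maximum (t40,
t50, t60) and the iterative background-corrected method (tBC) that
estimates the local background from a shell around the current mask,
subtracts it, and thresholds at 39% of the background-corrected
maximum — plus SUV conversion, SUVmax/SUVmean statistics and signed
relative deviations from reference values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import ConfigError, GridSpec, VoxelImage

__all__ = [
    "RoiBox",
    "SegmentationResult",
    "ReferenceValues",
    "roi_for_sphere",
    "to_suv",
    "segment_fixed",
    "segment_tbc",
    "suv_stats",
    "signed_deviation",
]

#: 26-connectivity structuring element.
_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Known interior volumes (ml) of the four standard sphere inserts.
REFERENCE_VOLUMES_ML = (13.6, 33.3, 64.7, 176.8)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned voxel-index box containing exactly one sphere plus margin."""

    lo: tuple[int, int, int]  # inclusive
    hi: tuple[int, int, int]  # exclusive

    def __post_init__(self) -> None:
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError("RoiBox must have positive extent on every axis")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))


@dataclass
class SegmentationResult:
    """One delineation of one sphere.

    ``mask`` is a boolean array over the ROI box.  ``mtv`` is the mask
    volume in ml.  SUV statistics are attached separately once an SUV
    image is available.  ``applicable`` is false when the threshold
    fell below the local background (mask reaching the ROI boundary) or
    the tBC initialisation was invalid.
    """

    mask: np.ndarray
    roi: RoiBox
    method: str  # t40 / t50 / t60 / tBC
    mtv: float  # ml
    applicable: bool
    converged: bool = True
    iterations: int = 0
    background_estimate: float | None = None  # kBq/ml (tBC only)
    suv_max: float | None = None
    suv_mean: float | None = None
    threshold: float | None = field(default=None, repr=False)  # kBq/ml


@dataclass(frozen=True)
class ReferenceValues:
    """Ground-truth comparison values for one measurement."""

    reference_suv: float
    reference_volumes: tuple[float, ...] = REFERENCE_VOLUMES_ML

    def __post_init__(self) -> None:
        if self.reference_suv <= 0 or any(v <= 0 for v in self.reference_volumes):
            raise ValueError("reference values must be positive")


def roi_for_sphere(grid: GridSpec, center, outer_radius: float, margin_mm: float) -> RoiBox:
    """Voxel-index box around a sphere centre with a physical margin."""
    half = outer_radius + margin_mm
    lo_f = grid.physical_to_index(np.asarray(center) - half)
    hi_f = grid.physical_to_index(np.asarray(center) + half)
    lo = tuple(int(max(0, np.floor(l))) for l in lo_f)
    hi = tuple(int(min(n, np.ceil(h) + 1)) for h, n in zip(hi_f, grid.shape))
    return RoiBox(lo, hi)


def to_suv(img: VoxelImage, administered: float, weight: float) -> VoxelImage:
    """Convert activity concentration to standardised uptake values.

    SUV = concentration [kBq/ml] / (administered activity [MBq] x 1000
    / weight [kg] x 1000), i.e. concentration divided by administered
    activity per gram, assuming 1 g/ml tissue density — dimensionless.
    """
    if administered <= 0 or weight <= 0:
        raise ConfigError("administered activity and weight must be positive")
    return VoxelImage(img.values / (administered / weight), img.grid)


def _component_of_argmax(binary: np.ndarray, argmax_idx) -> np.ndarray:
    """26-connected component of ``binary`` containing ``argmax_idx``."""
    labels, _ = ndimage.label(binary, structure=_CONN26)
    lab = labels[argmax_idx]
    if lab == 0:  # pragma: no cover - argmax is supra-threshold by construction
        raise RuntimeError("argmax voxel not inside any component")
    return labels == lab


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def _argmax_index(
    sub: np.ndarray,
    img: VoxelImage | None = None,
    roi: RoiBox | None = None,
    seed_center=None,
    seed_radius: float | None = None,
):
    """Index of the hottest voxel; first (lowest linear index) on ties.

    When ``seed_center``/``seed_radius`` are given the search is
    restricted to voxels within that ball — needed when the ROI box of
    one sphere grazes a neighbouring sphere of equal activity.
    """
    if seed_center is None:
        return np.unravel_index(int(np.argmax(sub)), sub.shape)
    grid = img.grid
    x, y, z = (
        grid.axis_centers(a)[roi.lo[a] : roi.hi[a]] for a in range(3)
    )
    dist2 = (
        (x[:, None, None] - seed_center[0]) ** 2
        + (y[None, :, None] - seed_center[1]) ** 2
        + (z[None, None, :] - seed_center[2]) ** 2
    )
    inside = dist2 <= seed_radius**2
    if not np.any(inside):
        raise ValueError("seed ball contains no voxel centres")
    masked = np.where(inside, sub, -np.inf)
    return np.unravel_index(int(np.argmax(masked)), sub.shape)


def segment_fixed(
    img: VoxelImage,
    roi: RoiBox,
    fraction: float,
    seed_center=None,
    seed_radius: float | None = None,
) -> SegmentationResult:
    """Fixed-threshold delineation at ``fraction`` of the ROI maximum.

    The mask is the 26-connected component of supra-threshold voxels
    that contains the hottest voxel.  A mask touching the ROI boundary
    means the threshold fell below the local background; the result is
    then flagged not applicable.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    sub = img.values[roi.slices]
    if sub.size == 0:
        raise ValueError("empty ROI")
    amax = _argmax_index(sub, img, roi, seed_center, seed_radius)
    threshold = fraction * float(sub[amax])
    mask = _component_of_argmax(sub >= threshold, amax)
    return SegmentationResult(
        mask=mask,
        roi=roi,
        method=f"t{int(round(fraction * 100))}",
        mtv=float(mask.sum()) * img.grid.voxel_volume_ml,
        applicable=not _touches_boundary(mask),
        threshold=threshold,
    )


def _shell_background(sub: np.ndarray, mask: np.ndarray, shell: tuple[int, int]) -> float:
    """Mean value over voxels at dilation distance (inner, outer] of the mask."""
    inner, outer = shell
    din = ndimage.binary_dilation(mask, structure=_CONN26, iterations=inner)
    dout = ndimage.binary_dilation(mask, structure=_CONN26, iterations=outer)
    ring = dout & ~din
    if not np.any(ring):  # pragma: no cover - ROI always exceeds the shell here
        raise ValueError("background shell is empty; enlarge the ROI")
    return float(sub[ring].mean())


def segment_tbc(
    img: VoxelImage,
    roi: RoiBox,
    init_fraction: float = 0.50,
    final_fraction: float = 0.39,
    shell: tuple[int, int] = (3, 6),
    max_iter: int = 20,
    seed_center=None,
    seed_radius: float | None = None,
) -> SegmentationResult:
    """Iterative background-corrected threshold delineation.

    Starts from a fixed-threshold mask at ``init_fraction`` of the
    maximum, then alternates between (a) estimating the local
    background as the mean over a shell of voxels at 26-connected
    dilation distance in ``(shell[0], shell[1]]`` from the current
    mask and (b) re-thresholding at
    ``background + final_fraction * (max - background)``, keeping the
    connected component of the hottest voxel, until the mask is stable.
    The result is independent of the initial delineation as long as the
    initial threshold exceeds the background; otherwise it is flagged
    not applicable.  A zero-background image reduces exactly to the
    fixed threshold at ``final_fraction``.
    """
    sub = img.values[roi.slices]
    amax = _argmax_index(sub, img, roi, seed_center, seed_radius)
    vmax = float(sub[amax])

    mask = _component_of_argmax(sub >= init_fraction * vmax, amax)
    background = _shell_background(sub, mask, shell)
    if init_fraction * vmax <= background:
        return SegmentationResult(
            mask=mask, roi=roi, method="tBC",
            mtv=float(mask.sum()) * img.grid.voxel_volume_ml,
            applicable=False, converged=False, iterations=0,
            background_estimate=background,
        )

    seen: list[bytes] = [mask.tobytes()]
    converged = False
    threshold = np.nan
    for it in range(1, max_iter + 1):
        background = _shell_background(sub, mask, shell)
        threshold = background + final_fraction * (vmax - background)
        new = _component_of_argmax(sub >= threshold, amax)
        if np.array_equal(new, mask):
            converged = True
            mask = new
            break
        mask = new
        key = mask.tobytes()
        if key in seen:  # oscillation
            break
        seen.append(key)
    else:
        it = max_iter

    return SegmentationResult(
        mask=mask,
        roi=roi,
        method="tBC",
        mtv=float(mask.sum()) * img.grid.voxel_volume_ml,
        applicable=not _touches_boundary(mask),
        converged=converged,
        iterations=it,
        background_estimate=background,
        threshold=float(threshold),
    )


def suv_stats(img_suv: VoxelImage, result: SegmentationResult) -> tuple[float, float]:
    """SUVmax and SUVmean over a delineated voxel set (also stored on it)."""
    if not result.mask.any():
        raise ValueError("empty mask")
    vals = img_suv.values[result.roi.slices][result.mask]
    result.suv_max = float(vals.max())
    result.suv_mean = float(vals.mean())
    return result.suv_max, result.suv_mean


def signed_deviation(measured: float, reference: float) -> float:
    """Signed relative deviation in percent: 100 * (measured - reference) / reference."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (measured - reference) / reference
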