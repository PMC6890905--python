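"""NIfTI and sidecar I/O for phantom images.

Images are written as NIfTI with the voxel size in the affine/header
and the generating specification as a JSON sidecar next to the image.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import GridSpec, VoxelImage

__all__ = ["save_nifti", "load_nifti", "save_sidecar", "load_sidecar"]


def save_nifti(img: VoxelImage, path) -> Path:
    """Write a voxel image as NIfTI (.nii or .nii.gz) with physical affine."""
    path = Path(path)
    affine = np.diag([*img.grid.voxel_size, 1.0])
    # NIfTI affine maps voxel indices to the coordinates of voxel centres
    affine[:3, 3] = img.grid.index_to_physical((0, 0, 0))
    nib.save(nib.Nifti1Image(np.asarray(img.values, dtype=np.float32), affine), str(path))
    return path


def load_nifti(path) -> VoxelImage:
    """Read a NIfTI image written by :func:`save_nifti` back into a VoxelImage."""
    ni = nib.load(str(path))
    affine = ni.affine
    voxel = tuple(float(affine[i, i]) for i in range(3))
    if any(v <= 0 for v in voxel) or np.abs(
        affine[:3, :3] - np.diag(voxel)
    ).max() > 1e-6:
        raise ValueError("only axis-aligned, positively oriented NIfTI images are supported")
    first_center = affine[:3, 3]
    origin = tuple(float(c - 0.5 * v) for c, v in zip(first_center, voxel))
    grid = GridSpec(shape=tuple(ni.shape), voxel_size=voxel, origin=origin)
    return VoxelImage(np.asarray(ni.get_fdata(), dtype=float), grid)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_sidecar(obj, path) -> Path:
    """Write a dataclass (PhantomSpec, ReconEmulation, ...) as a JSON sidecar."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(obj), indent=1))
    return path


def load_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
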