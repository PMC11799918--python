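"""NIfTI I/O for image and label volumes (nibabel-backed).

The affine encodes ``direction @ diag(spacing)`` with the grid origin as
translation; round-trips preserve voxel values, spacing, origin and
orientation.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .volumes import Grid, ImageVolume, LabelVolume


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = grid.direction_matrix @ np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> Grid:
    M = aff[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    direction = M / spacing
    return Grid(
        shape=tuple(int(s) for s in shape[:3]),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(v) for v in aff[:3, 3]),
        direction=tuple(float(v) for v in direction.ravel()),
    )


def write_volume(volume, path: str) -> str:
    """Write an :class:`ImageVolume` or :class:`LabelVolume` to NIfTI."""
    arr = volume.array
    if isinstance(volume, LabelVolume):
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float32)
    img = nib.Nifti1Image(arr, _affine(volume.grid))
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, path)
    return path


def read_volume(path: str, as_labels: bool = False):
    """Read a NIfTI volume; returns LabelVolume if ``as_labels`` else ImageVolume."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file does not exist: {path}")
    try:
        img = nib.load(path)
        arr = np.asarray(img.dataobj)
    except Exception as exc:  # corrupt / non-NIfTI input
        raise OSError(f"could not read NIfTI volume from {path}: {exc}") from exc
    grid = _grid_from_affine(img.affine, arr.shape)
    if as_labels:
        return LabelVolume(array=np.rint(arr).astype(np.int16), grid=grid)
    return ImageVolume(array=arr.astype(np.float32), grid=grid)
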