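"""NIfTI-1 volume I/O (nibabel-backed)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


class NiftiIOError(IOError):
    """Raised for missing files or malformed headers."""


def default_affine(voxel_size: float = 2.0) -> np.ndarray:
    """Identity orientation scaled by isotropic voxel size (mm)."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def write_nifti(
    path: str | Path, data: np.ndarray, affine: np.ndarray | None = None
) -> None:
    """Write a 3D/4D array; integer arrays keep an integer on-disk dtype."""
    data = np.asarray(data)
    if affine is None:
        affine = default_affine()
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI file, returning (data, affine) at stored precision."""
    path = Path(path)
    if not path.exists():
        raise NiftiIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        return data, img.affine
    except Exception as exc:  # malformed header, truncated file, ...
        raise NiftiIOError(f"cannot read {path}: {exc}") from exc
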