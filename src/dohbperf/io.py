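"""NIfTI-1 volume I/O helpers (nibabel-backed).

Volumes are written with a diagonal affine built from the isotropic voxel
size; arrays round-trip losslessly (float64 on disk for maps, the native
integer dtype for labels/masks).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume"]


def save_volume(path, data: np.ndarray, voxel_size: float) -> Path:
    """Write a 3-D or 4-D array as NIfTI-1 with an isotropic-voxel affine."""
    path = Path(path)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms((voxel_size,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (array, voxel_size)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])
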