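"""Minimal NIfTI-1 I/O helpers shared across modules."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def save_volume(path: str | Path, data: np.ndarray, voxel_size: float) -> None:
    """Write a volume with an isotropic voxel size (mm) in the header."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms((voxel_size,) * 3)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a volume; returns (array, isotropic voxel size in mm)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), float(zooms[0])
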