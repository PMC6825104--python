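"""Thin NIfTI-1 read/write helpers (nibabel) used across the package.

Volumes are stored with voxel spacing (mm) in the header zooms; the affine
is a diagonal scaling so world axes coincide with the package's image-axis
convention. Displacement fields are 4-D with the vector component last.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def write_volume(path: str | Path, data: np.ndarray, spacing) -> None:
    data = np.asarray(data)
    affine = np.diag(list(spacing[:3]) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(spacing[: data.ndim]) if data.ndim <= 3 else tuple(spacing[:3]) + (1.0,))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_mask(path: str | Path, mask: np.ndarray, spacing) -> None:
    write_volume(path, np.asarray(mask, dtype=np.uint8), spacing)


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    data, spacing = read_volume(path)
    return data.astype(bool), spacing
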