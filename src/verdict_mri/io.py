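"""NIfTI volume I/O with geometry bookkeeping.

Thin wrappers around nibabel that keep the affine attached to the voxel
data and refuse to combine volumes whose geometries disagree.  Maps are
always written with the geometry of the acquisition they came from.
Uncompressed ``.nii`` is the default so that repeated runs with the same
seed produce byte-identical artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "read_nifti", "write_nifti", "require_same_geometry"]


@dataclass
class Volume:
    """Voxel data plus its affine."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def read_nifti(path: str | Path) -> Volume:
    img = nib.load(str(path))
    return Volume(data=np.asarray(img.get_fdata()), affine=np.asarray(img.affine))


def write_nifti(data: np.ndarray, affine: np.ndarray | None, path: str | Path) -> None:
    if affine is None:
        affine = np.eye(4)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


def require_same_geometry(a: Volume, b: Volume, what: str = "volumes") -> None:
    """Raise if two volumes differ in (spatial) shape or affine."""
    if a.data.shape[:3] != b.data.shape[:3]:
        raise ValueError(
            f"{what} have different shapes: {a.data.shape[:3]} vs {b.data.shape[:3]}"
        )
    if not np.allclose(a.affine, b.affine, atol=1e-4):
        raise ValueError(f"{what} have different affines")
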