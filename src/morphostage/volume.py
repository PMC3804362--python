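"""Segmented organ label volumes.

A :class:`LabelVolume` is a binary occupancy grid for a single organ,
together with the voxel spacing and the physical coordinate of grid index
(0, 0, 0).  Coordinates are physical millimetres, right-handed, 0-based
voxel indexing; the physical position of index ``(i, j, k)`` is
``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class EmptySegmentationError(ValueError):
    """Raised when an operation receives a label volume with no foreground."""


@dataclass
class LabelVolume:
    """Binary occupancy grid of one segmented organ.

    Parameters
    ----------
    grid : ndarray of {0, 1}, shape (nx, ny, nz)
        Voxel occupancy.  Any nonzero input value is treated as foreground
        and stored as 1.
    spacing : 3-sequence of float
        Physical size of a voxel along each axis, in mm.  Strictly positive.
    origin : 3-sequence of float
        Physical coordinate of grid index (0, 0, 0), in mm.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError(f"grid must be 3-D, got shape {grid.shape}")
        self.grid = (grid != 0).astype(np.uint8)
        spacing = np.asarray(self.spacing, dtype=float)
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise ValueError("spacing must be three strictly positive values")
        self.spacing = tuple(spacing)
        origin = np.asarray(self.origin, dtype=float)
        if origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        self.origin = tuple(origin)

    @property
    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def foreground_volume(self) -> float:
        """Total foreground volume in mm^3 (voxel-counting estimate)."""
        return float(self.grid.sum()) * self.voxel_volume()


def load_label_volume(path: str | Path, organ: str = "") -> LabelVolume:
    """Read a label volume from NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    The affine/transform is reduced to spacing and origin; oblique
    orientations are not supported and raise ``ValueError``.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
        rot = affine[:3, :3]
        spacing = np.linalg.norm(rot, axis=0)
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6 * max(spacing.max(), 1.0)):
            raise ValueError("oblique NIfTI orientations are not supported")
        origin = affine[:3, 3]
        return LabelVolume(data, tuple(np.abs(spacing)), tuple(origin), organ=organ)
    if name.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z).
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return LabelVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()), organ=organ)
    raise ValueError(f"unrecognised label volume format: {path.name}")


def save_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI with a diagonal affine."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.grid.astype(np.uint8), affine), str(Path(path)))
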