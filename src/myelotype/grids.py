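"""3-D intensity volumes and binary masks with voxel geometry.

Lightweight wrappers around numpy arrays carrying the voxel dimensions (mm)
needed to convert voxel counts into millilitres.  All downstream operations
(threshold segmentation, probability maps, volumetry) require that the grids
they combine share both shape and voxel size; :func:`check_same_geometry`
enforces that contract.  NIfTI-1 round-tripping goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarVolume",
    "BinaryMask",
    "GeometryError",
    "check_same_geometry",
]


class GeometryError(ValueError):
    """Raised when grids that must share geometry do not."""


def _as_voxel_mm(voxel_mm) -> tuple[float, float, float]:
    vm = tuple(float(v) for v in voxel_mm)
    if len(vm) != 3 or any(v <= 0 for v in vm):
        raise ValueError(f"voxel_mm must be 3 positive reals, got {voxel_mm!r}")
    return vm


@dataclass
class ScalarVolume:
    """A 3-D intensity grid with voxel dimensions in mm.

    Parameters
    ----------
    data
        3-D float array of intensities (arbitrary units).
    voxel_mm
        Edge lengths of one voxel in mm, per axis.  Anisotropic voxels are
        supported (e.g. 0.94 x 0.94 x 1 mm acquisitions).
    space
        Free-form label for the coordinate space (e.g. ``"native"``,
        ``"template"``).  Operations that pool subjects require equal labels.
    """

    data: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        self.voxel_mm = _as_voxel_mm(self.voxel_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        a, b, c = self.voxel_mm
        return a * b * c

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag((*self.voxel_mm, 1.0))
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms(self.voxel_mm)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, space: str = "native") -> "ScalarVolume":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.dataobj, dtype=np.float64), tuple(zooms), space)


@dataclass
class BinaryMask:
    """A 3-D boolean grid sharing a :class:`ScalarVolume`'s geometry."""

    data: np.ndarray
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        self.voxel_mm = _as_voxel_mm(self.voxel_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        a, b, c = self.voxel_mm
        return a * b * c

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag((*self.voxel_mm, 1.0))
        img = nib.Nifti1Image(self.data.astype(np.uint8), affine)
        img.header.set_zooms(self.voxel_mm)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, space: str = "native") -> "BinaryMask":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asarray(img.dataobj) > 0, tuple(zooms), space)


def check_same_geometry(*grids, what: str = "grids") -> None:
    """Raise :class:`GeometryError` unless all grids share shape and voxel size.

    ``what`` names the offending collection in the error message so callers
    can identify which subject/input failed.
    """
    if not grids:
        return
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if g.shape != ref.shape:
            raise GeometryError(
                f"{what}: grid {i} has shape {g.shape}, expected {ref.shape}"
            )
        if not np.allclose(g.voxel_mm, ref.voxel_mm):
            raise GeometryError(
                f"{what}: grid {i} has voxel_mm {g.voxel_mm}, expected {ref.voxel_mm}"
            )
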