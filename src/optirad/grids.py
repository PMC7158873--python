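"""Regular-grid volume containers with world (RAS mm) affine geometry.

Every image-like object in the pipeline is a 3-D array plus a 4x4 affine
mapping voxel indices (i, j, k) to world coordinates in RAS millimetres,
matching the NIfTI-1 convention.  Three thin wrappers are provided:

``Volume3D``
    float scalar maps (metric maps, visitation maps).
``LabelVolume``
    integer parcellations.
``MaskVolume``
    binary regions of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "LabelVolume",
    "MaskVolume",
    "centered_affine",
    "voxel_centers_world",
]


def centered_affine(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """Axis-aligned RAS affine placing the grid centre at the world origin."""
    shape = np.asarray(shape, dtype=float)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -(shape - 1) / 2.0 * voxel_size
    return affine


@dataclass
class Volume3D:
    """A 3-D scalar volume with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_from_voxel(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world RAS mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_from_world(self, xyz: np.ndarray) -> np.ndarray:
        """Map world RAS mm coordinates (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of all voxel centres."""
        shape = np.asarray(self.shape)
        corners = np.array(
            [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)],
            dtype=float,
        )
        world = self.world_from_voxel(corners)
        return world.min(axis=0), world.max(axis=0)

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str) -> "Volume3D":
        img = nib.load(path)
        return cls(np.asarray(img.get_fdata()), np.asarray(img.affine))


@dataclass
class LabelVolume(Volume3D):
    """Integer-valued parcellation volume."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label volume has non-integer values")
            self.data = rounded.astype(np.int32)

    def mask_for(self, labels: int | tuple[int, ...]) -> "MaskVolume":
        labels = (labels,) if np.isscalar(labels) else tuple(labels)
        return MaskVolume(np.isin(self.data, labels), self.affine)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.int32), self.affine)

    @classmethod
    def load(cls, path: str) -> "LabelVolume":
        img = nib.load(path)
        return cls(np.rint(img.get_fdata()).astype(np.int32), np.asarray(img.affine))


@dataclass
class MaskVolume(Volume3D):
    """Binary region-of-interest volume."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def load(cls, path: str) -> "MaskVolume":
        img = nib.load(path)
        return cls(img.get_fdata() > 0.5, np.asarray(img.affine))


def voxel_centers_world(mask: MaskVolume) -> np.ndarray:
    """World RAS mm coordinates of the centres of all True voxels, (n, 3)."""
    ijk = np.argwhere(mask.data)
    return mask.world_from_voxel(ijk)
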