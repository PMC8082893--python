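"""Voxel volumes with physical spacing — the raster side of the pipeline.

A :class:`VolumeImage` is an intensity grid in Hounsfield-unit-like values;
a :class:`BinaryMask` is its segmented counterpart. Both carry per-axis
voxel spacing (mm) and a world origin so surface extraction lands in the
same millimetre coordinates the meshes use. Volumes round-trip through
NIfTI (nibabel), the pinned raster format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "BinaryMask", "read_volume", "write_volume"]


def _validate_grid(shape, spacing, origin):
    spacing = np.asarray(spacing, float).reshape(3)
    origin = np.asarray(origin, float).reshape(3)
    if np.any(spacing <= 0):
        raise ValueError(f"voxel spacing must be positive, got {spacing}")
    return spacing, origin


@dataclass
class VolumeImage:
    """3D scalar intensity grid (HU-like) with voxel spacing and origin in mm."""

    intensities: np.ndarray
    voxel_spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("volume must be a 3D grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume contains non-finite intensities")
        self.voxel_spacing, self.origin = _validate_grid(
            self.intensities.shape, self.voxel_spacing, self.origin
        )

    @property
    def shape(self):
        return self.intensities.shape

    def world_coordinates(self, index_points: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to mm world coordinates."""
        return np.asarray(index_points, float) * self.voxel_spacing + self.origin


@dataclass
class BinaryMask:
    """Boolean voxel grid sharing the source volume's spacing/origin."""

    voxels: np.ndarray
    voxel_spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D grid")
        self.voxel_spacing, self.origin = _validate_grid(
            self.voxels.shape, self.voxel_spacing, self.origin
        )

    @property
    def shape(self):
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def touches_boundary(self) -> bool:
        v = self.voxels
        return bool(
            v[0].any() or v[-1].any()
            or v[:, 0].any() or v[:, -1].any()
            or v[:, :, 0].any() or v[:, :, -1].any()
        )


def _affine(spacing, origin) -> np.ndarray:
    A = np.diag(np.append(spacing, 1.0))
    A[:3, 3] = origin
    return A


def write_volume(volume: VolumeImage | BinaryMask, path) -> None:
    """Write a volume or mask as NIfTI (.nii / .nii.gz)."""
    data = volume.voxels.astype(np.uint8) if isinstance(volume, BinaryMask) else volume.intensities
    img = nib.Nifti1Image(np.asarray(data), _affine(volume.voxel_spacing, volume.origin))
    nib.save(img, str(path))


def read_volume(path, as_mask: bool = False) -> VolumeImage | BinaryMask:
    """Read a NIfTI volume; spacing from the affine diagonal, origin from its offset."""
    img = nib.load(str(path))
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    data = np.asarray(img.dataobj)
    if as_mask:
        return BinaryMask(voxels=data > 0, voxel_spacing=spacing, origin=origin)
    return VolumeImage(intensities=data.astype(float), voxel_spacing=spacing, origin=origin)
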