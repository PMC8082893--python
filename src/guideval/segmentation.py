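"""Volume segmentation and surface-model generation.

Mirrors the imaging stage of the guide-validation workflow: intensity
thresholding of a (synthetic) CT volume — either a fixed HU window or
Otsu's automatic threshold — followed by marching-cubes isosurface
extraction and Taubin smoothing to a triangle surface model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volume import BinaryMask, VolumeImage

__all__ = [
    "ThresholdResult",
    "otsu_threshold",
    "threshold_segment",
    "extract_surface",
    "taubin_smooth",
]

#: Default HU window lower bound for bone; the classic adult-bone preset.
DEFAULT_BONE_LOWER_HU = 226.0


@dataclass(frozen=True)
class ThresholdResult:
    """Otsu threshold with its objective value and the histogram it used."""

    threshold: float
    between_class_variance: float
    bin_edges: np.ndarray
    counts: np.ndarray


def otsu_from_histogram(counts: np.ndarray, bin_edges: np.ndarray) -> tuple[float, float]:
    """Otsu's threshold on a precomputed histogram.

    Maximizes the between-class variance ``w0*w1*(mu0-mu1)^2`` over all
    bin boundaries; ties broken toward the lower threshold. Returns
    ``(threshold, between_class_variance)`` with the threshold at the bin
    edge separating the two classes.
    """
    counts = np.asarray(counts, float)
    centers = 0.5 * (np.asarray(bin_edges, float)[:-1] + np.asarray(bin_edges, float)[1:])
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m1 = (counts * centers).sum() - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        bcv = w0 * w1 * (m0 / w0 - m1 / w1) ** 2 / total**2
    bcv = np.where((w0 > 0) & (w1 > 0), bcv, -np.inf)
    if not np.isfinite(bcv).any():
        raise ValueError("degenerate histogram: all mass in one bin")
    best = int(np.argmax(bcv))  # argmax returns the first (lowest) maximizer
    return float(bin_edges[best + 1]), float(bcv[best])


def otsu_threshold(volume: VolumeImage, n_bins: int = 256) -> ThresholdResult:
    """Automatic threshold maximizing between-class intensity variance.

    Raises on a constant volume, where no threshold separates anything.
    """
    data = volume.intensities.ravel()
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("constant volume: Otsu threshold undefined")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    thr, bcv = otsu_from_histogram(counts, edges)
    return ThresholdResult(
        threshold=thr, between_class_variance=bcv, bin_edges=edges, counts=counts
    )


def threshold_segment(
    volume: VolumeImage,
    lower: float = DEFAULT_BONE_LOWER_HU,
    upper: float = np.inf,
    keep_largest: bool = True,
) -> BinaryMask:
    """Window threshold ``lower <= I <= upper``; optionally keep only the
    largest 26-connected component (removes disconnected false positives
    such as calcified-tendon blobs)."""
    if lower > upper:
        raise ValueError(f"lower ({lower}) must not exceed upper ({upper})")
    voxels = (volume.intensities >= lower) & (volume.intensities <= upper)
    if not voxels.any():
        warnings.warn("threshold window selects no voxels; returning empty mask")
    elif keep_largest:
        labels, n = ndimage.label(voxels, structure=np.ones((3, 3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(voxels, labels, index=np.arange(1, n + 1))
            voxels = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(
        voxels=voxels, voxel_spacing=volume.voxel_spacing, origin=volume.origin
    )


def taubin_smooth(
    mesh: trimesh.Trimesh, factor: float = 0.3, iterations: int = 2
) -> trimesh.Trimesh:
    """Taubin low-pass smoothing: per iteration one shrink step (lambda =
    ``factor``) and one inflate step (mu = -1.02 * lambda), preserving
    volume far better than plain Laplacian smoothing."""
    out = mesh.copy()
    if iterations == 0 or factor == 0:
        return out
    lap = trimesh.smoothing.laplacian_calculation(out)
    verts = out.vertices.view(np.ndarray).copy()
    lam, mu = factor, -1.02 * factor
    for _ in range(iterations):
        verts += lam * (lap.dot(verts) - verts)
        verts += mu * (lap.dot(verts) - verts)
    out.vertices = verts
    return out


def extract_surface(
    mask: BinaryMask,
    smoothing_factor: float = 0.3,
    smoothing_iterations: int = 2,
) -> trimesh.Trimesh:
    """Marching-cubes isosurface (level 0.5) of a binary mask, in mm
    coordinates, followed by Taubin smoothing.

    Watertight whenever the mask does not touch the grid boundary; if it
    does, a warning is emitted and the surface may be open there.
    """
    if not mask.voxels.any():
        raise ValueError("cannot extract a surface from an empty mask")
    if mask.touches_boundary():
        warnings.warn("mask touches the grid boundary; extracted surface may be open")
    verts, faces, _, _ = measure.marching_cubes(
        mask.voxels.astype(np.uint8), level=0.5, spacing=tuple(mask.voxel_spacing)
    )
    verts = verts + mask.origin
    surf = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # marching-cubes winding can come out material-inward; flip so normals
    # point out of the segmented material (total signed volume positive)
    if surf.is_watertight and surf.volume < 0:
        surf.invert()
    return taubin_smooth(surf, factor=smoothing_factor, iterations=smoothing_iterations)
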