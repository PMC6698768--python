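"""Volume and ROI handling: NIfTI I/O, spherical ROIs, analysis-plane
selection, and gray-level quantization.

Feature extraction works on a :class:`QuantizedROI`: the ROI voxel sample
with HU values clipped to the 12-bit CT window, mapped to equal-width bin
levels over the sample range (20 bins by default), together with the 2-D
analysis plane — the slice, among all axial/coronal/sagittal slices, with the
largest in-plane mask diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.spatial.distance import pdist

from .phantom import VolumeImage

#: 12-bit CT window applied before binning.
HU_WINDOW = (-1024.0, 3071.0)
#: Voxels below this HU are treated as air bubbles and excluded from ROIs.
AIR_EXCLUSION_HU = -200.0
DEFAULT_N_BINS = 20

PLANES = ("axial", "coronal", "sagittal")  # slice axes z, y, x


def write_nifti(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with spacing and origin in the affine.

    Data are stored in (x, y, z) axis order as NIfTI convention expects.
    """
    path = Path(path)
    sz, sy, sx = volume.spacing
    oz, oy, ox = volume.origin
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    data = np.ascontiguousarray(np.transpose(volume.values, (2, 1, 0)))
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, path)
    return path


def read_nifti(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 volume into (z, y, x) axis order."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
    return VolumeImage(
        np.transpose(data, (2, 1, 0)).copy(),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin=origin,
    )


@dataclass
class ROIMask:
    """A binary region-of-interest mask aligned to a volume grid."""

    label: str
    center: tuple[float, float, float]
    radius: float
    grid: np.ndarray  # bool, same shape as the volume

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


def make_sphere_roi(
    volume: VolumeImage,
    center: tuple[float, float, float],
    radius: float,
    label: str = "roi",
) -> ROIMask:
    """Spherical ROI: voxels whose centres lie within ``radius`` of ``center``.

    ``center`` is (z, y, x) in mm.  Raises if no voxel centre falls inside the
    sphere.
    """
    d2 = np.zeros((1, 1, 1))
    for ax in range(3):
        c = volume.axis_centers(ax) - center[ax]
        shape = [1, 1, 1]
        shape[ax] = c.size
        d2 = d2 + (c**2).reshape(shape)
    grid = d2 <= radius**2
    if not grid.any():
        raise ValueError(
            f"sphere ROI {label!r} at {center} (r={radius} mm) contains no voxel centres"
        )
    return ROIMask(label=label, center=tuple(center), radius=float(radius), grid=grid)


def _slice_diameter(points_mm: np.ndarray) -> float:
    """Largest pairwise distance between voxel centres, in mm."""
    if len(points_mm) < 2:
        return 0.0
    return float(pdist(points_mm).max())


def select_2d_plane(mask: ROIMask, spacing: tuple[float, float, float]) -> tuple[str, int]:
    """Orientation and slice index with the largest in-plane mask diameter.

    All three orientations (axial = z slices, coronal = y, sagittal = x) are
    scanned; ties break in that order, then toward the lowest slice index.
    """
    idx = np.argwhere(mask.grid)
    if idx.size == 0:
        raise ValueError("empty mask")
    best: tuple[float, int, int] | None = None  # (-diam, plane_rank, slice)
    result = ("axial", 0)
    for rank, axis in enumerate(range(3)):
        in_plane_axes = [a for a in range(3) if a != axis]
        for s in np.unique(idx[:, axis]):
            pts = idx[idx[:, axis] == s][:, in_plane_axes].astype(float)
            pts *= np.array([spacing[a] for a in in_plane_axes])
            key = (-_slice_diameter(pts), rank, int(s))
            if best is None or key < best:
                best = key
                result = (PLANES[rank], int(s))
    return result


def quantize_values(values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Equal-width bin levels in 1..n_bins over [min, max] of the sample.

    The maximum maps to bin ``n_bins``; a constant sample maps to bin 1.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty sample")
    if np.isnan(values).any():
        raise ValueError("NaN in gray-level sample")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    width = (hi - lo) / n_bins
    levels = np.floor((values - lo) / width).astype(np.int64) + 1
    return np.clip(levels, 1, n_bins)


@dataclass
class QuantizedROI:
    """ROI voxel sample ready for texture analysis.

    ``indices``/``hu``/``levels`` are the retained ROI voxels (after air
    exclusion), their clipped HU values and bin levels.  ``grid`` is the bin
    levels on the mask bounding box with 0 marking out-of-mask voxels;
    ``plane_slice`` is the 2-D bin-level grid of the selected analysis plane.
    """

    indices: np.ndarray  # (N, 3) int, volume coordinates
    hu: np.ndarray  # (N,) float
    levels: np.ndarray  # (N,) int in 1..n_bins
    n_bins: int
    spacing: tuple[float, float, float]
    plane: str
    plane_index: int
    plane_slice: np.ndarray  # 2-D int grid, 0 outside mask
    grid: np.ndarray  # 3-D int grid over mask bounding box, 0 outside mask

    @property
    def n_voxels(self) -> int:
        return len(self.hu)


def extract_roi(
    volume: VolumeImage,
    mask: ROIMask,
    n_bins: int = DEFAULT_N_BINS,
    *,
    exclude_air_below: float | None = AIR_EXCLUSION_HU,
    hu_window: tuple[float, float] = HU_WINDOW,
    min_voxels: int = 32,
) -> QuantizedROI:
    """Extract and quantize the ROI voxel sample from a volume.

    Air-bubble voxels (HU below ``exclude_air_below``) are dropped, remaining
    HU values are clipped to the 12-bit window, and equal-width bin levels are
    assigned over the sample range.  The analysis plane is chosen on the
    retained mask.
    """
    if volume.values.shape != mask.grid.shape:
        raise ValueError("mask grid does not match volume shape")
    grid = mask.grid
    if exclude_air_below is not None:
        grid = grid & (volume.values >= exclude_air_below)
    n = int(grid.sum())
    if n < min_voxels:
        raise ValueError(
            f"ROI {mask.label!r} has {n} usable voxels; at least {min_voxels} "
            "are required for feature extraction"
        )
    kept = ROIMask(mask.label, mask.center, mask.radius, grid)
    plane, plane_index = select_2d_plane(kept, volume.spacing)

    indices = np.argwhere(grid)
    hu = np.clip(volume.values[grid], *hu_window)
    levels = quantize_values(hu, n_bins)

    lo = indices.min(axis=0)
    hi = indices.max(axis=0) + 1
    level_grid = np.zeros(tuple(hi - lo), dtype=np.int64)
    level_grid[tuple((indices - lo).T)] = levels

    axis = PLANES.index(plane)
    sl = [slice(None)] * 3
    sl[axis] = plane_index - lo[axis]
    plane_grid = level_grid[tuple(sl)]

    return QuantizedROI(
        indices=indices,
        hu=hu,
        levels=levels,
        n_bins=n_bins,
        spacing=volume.spacing,
        plane=plane,
        plane_index=int(plane_index),
        plane_slice=plane_grid,
        grid=level_grid,
    )
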