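from __future__ import annotations

import numpy as np
import pytest

from phantex import PhantomSpec, VolumeImage, build_phantom, extract_roi, make_sphere_roi
from phantex.volume_io import QuantizedROI, select_2d_plane, quantize_values
from phantex.volume_io import ROIMask


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(supersample_factor=2)


@pytest.fixture(scope="session")
def truth_volume(default_spec) -> VolumeImage:
    return build_phantom(default_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def quantized_from_levels(levels: np.ndarray, n_bins: int = 20) -> QuantizedROI:
    """Build a QuantizedROI directly from a 3-D grid of bin levels (0 =
    outside mask), routing plane selection through the package machinery."""
    levels = np.asarray(levels)
    if levels.ndim == 2:
        levels = levels[None, :, :]
    mask = levels > 0
    indices = np.argwhere(mask)
    spacing = (1.0, 1.0, 1.0)
    plane, plane_index = select_2d_plane(
        ROIMask("test", (0.0, 0.0, 0.0), 1.0, mask), spacing
    )
    axis = ("axial", "coronal", "sagittal").index(plane)
    sl = [slice(None)] * 3
    sl[axis] = plane_index
    return QuantizedROI(
        indices=indices,
        hu=levels[mask].astype(float),
        levels=levels[mask].astype(np.int64),
        n_bins=n_bins,
        spacing=spacing,
        plane=plane,
        plane_index=plane_index,
        plane_slice=levels[tuple(sl)],
        grid=levels,
    )


def volume_roi(values: np.ndarray, radius: float | None = None, n_bins: int = 20,
               spacing=(1.0, 1.0, 1.0)) -> QuantizedROI:
    """Quantized spherical ROI covering the centre of a synthetic volume."""
    vol = VolumeImage(np.asarray(values, dtype=float), spacing=spacing)
    center = tuple((np.array(values.shape) - 1) / 2 * np.array(spacing))
    if radius is None:
        radius = float(max(np.array(values.shape) * np.array(spacing)))  # cover all
    mask = make_sphere_roi(vol, center, radius, "test")
    return extract_roi(vol, mask, n_bins=n_bins, exclude_air_below=None, min_voxels=1)
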