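"""Digital CT texture phantom and virtual-scanner acquisition simulation.

The phantom is a short cylinder of soft-tissue-density background material
containing square texture-pattern regions.  Each pattern is a deterministic
periodic binary lattice of insert material occupying a prescribed volume
fraction (the *fill fraction*), emulating 3-D-printed texture inserts cast
into a urethane background.  Acquisitions are simulated parametrically:
partial-volume averaging onto the reconstruction grid, tube-voltage-dependent
contrast scaling, tube-current-dependent Gaussian noise, edge-preserving
(bilateral) reconstruction filtering, and a scanner HU offset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from skimage.restoration import denoise_bilateral

AIR_HU = -1000.0

#: Varied-parameter families enumerated in a one-factor-at-a-time study.
PARAMETER_FAMILIES = ("slice_thickness", "fov", "filter", "kvp", "ma")


@dataclass(frozen=True)
class PatternRegion:
    """Axis-aligned cubic texture region inside the phantom.

    center : (z, y, x) position of the region centre in mm.
    extent : side length of the cube in mm.
    fill_fraction : volume fraction occupied by insert material, in [0, 1].
    """

    center: tuple[float, float, float]
    extent: float
    fill_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fill_fraction <= 1.0:
            raise ValueError(
                f"fill_fraction must be in [0, 1], got {self.fill_fraction}"
            )
        if self.extent <= 0:
            raise ValueError("extent must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and materials of the digital texture phantom.

    The cylinder axis is z; coordinates are (z, y, x) in mm with the origin at
    the phantom centre.  ``background_hu`` is the homogeneous cast material,
    ``insert_hu`` the lattice material; outside the cylinder is air.
    The ground-truth grid is sampled at ``lattice_period / supersample_factor``
    mm so every lattice cell holds ``supersample_factor**3`` voxels.
    """

    cylinder_diameter: float = 150.0
    cylinder_length: float = 60.0
    pattern_regions: tuple[PatternRegion, ...] = (
        PatternRegion((0.0, 38.0, 0.0), 50.0, 0.10),
        PatternRegion((0.0, -20.0, -34.0), 50.0, 0.20),
        PatternRegion((0.0, -20.0, 34.0), 50.0, 0.40),
    )
    background_hu: float = 40.0
    insert_hu: float = -40.0
    lattice_period: float = 2.0
    supersample_factor: int = 4

    def __post_init__(self) -> None:
        if self.supersample_factor < 1 or int(self.supersample_factor) != self.supersample_factor:
            raise ValueError("supersample_factor must be a positive integer")
        if self.cylinder_diameter <= 0 or self.cylinder_length <= 0:
            raise ValueError("cylinder dimensions must be positive")
        for region in self.pattern_regions:
            self._check_inside(region)

    def _check_inside(self, region: PatternRegion) -> None:
        cz, cy, cx = region.center
        h = region.extent / 2.0
        radius = self.cylinder_diameter / 2.0
        for sy, sx in itertools.product((-1, 1), repeat=2):
            if np.hypot(cy + sy * h, cx + sx * h) >= radius:
                raise ValueError(
                    f"pattern region at {region.center} extends outside the "
                    f"cylinder of radius {radius} mm"
                )
        if abs(cz) + h >= self.cylinder_length / 2.0:
            raise ValueError(
                f"pattern region at {region.center} extends outside the "
                f"cylinder length {self.cylinder_length} mm"
            )

    @property
    def truth_voxel_mm(self) -> float:
        return self.lattice_period / self.supersample_factor


@dataclass(frozen=True)
class AcquisitionSetting:
    """One scanner-parameter combination of the acquisition matrix."""

    scanner_id: str
    slice_thickness: float
    fov: float
    kvp: float
    tube_current: float
    filter_level: int = 0
    varied_parameter: str = "baseline"
    repeat_index: int = 0
    seed: int = 0
    setting_id: str = ""

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0 or self.fov <= 0 or self.tube_current <= 0:
            raise ValueError("slice_thickness, fov and tube_current must be positive")
        if self.repeat_index not in (0, 1):
            raise ValueError("repeat_index must be 0 (scan) or 1 (15-min re-scan)")
        if self.filter_level < 0:
            raise ValueError("filter_level must be >= 0")


@dataclass(frozen=True)
class ScannerProfile:
    """Parametric model of one virtual CT scanner.

    ``noise_sigma_ref`` is the background noise s.d. (HU) at ``reference_ma``;
    noise at other tube currents scales as sqrt(reference_ma / mA).
    ``kvp_contrast_scale`` maps each supported tube voltage to a multiplicative
    contrast factor applied to (HU - pivot).  ``filter_levels`` are the
    exposed reconstruction-filter strengths (iterative-reconstruction levels);
    level n applies n passes of a fixed bilateral filter whose HU range
    sigma is ``filter_range_sigma_hu``.
    ``settings_matrix`` holds the per-family value lists varied one at a time.
    """

    scanner_id: str
    hu_offset: float
    noise_sigma_ref: float
    reference_ma: float
    kvp_contrast_scale: dict[float, float]
    filter_levels: tuple[int, ...]
    settings_matrix: dict[str, tuple[float, ...]]
    baseline: dict[str, float] = field(
        default_factory=lambda: {
            "slice_thickness": 3.0,
            "fov": 500.0,
            "kvp": 100.0,
            "ma": 100.0,
            "filter_level": 0,
        }
    )
    matrix_size: int = 512
    filter_range_sigma_hu: float = 60.0


@dataclass
class VolumeImage:
    """A 3-D HU volume with voxel spacing and origin, axis order (z, y, x).

    ``origin`` is the physical coordinate (mm) of the centre of voxel
    (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


def _cell_pattern(fill_fraction: float, factor: int) -> np.ndarray:
    """Binary occupancy pattern of one lattice cell at a given supersampling.

    The ``round(fill * factor**3)`` sub-voxels nearest the cell centre are
    occupied, giving a compact blob whose occupancy matches the requested fill
    fraction to within half a sub-voxel.
    """
    n = factor**3
    k = int(round(fill_fraction * n))
    coords = (np.arange(factor) + 0.5) / factor - 0.5
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    d2 = (zz**2 + yy**2 + xx**2).ravel()
    order = np.lexsort((np.arange(n), d2))
    pattern = np.zeros(n, dtype=bool)
    pattern[order[:k]] = True
    return pattern.reshape((factor, factor, factor))


def _regions_overlap(a: PatternRegion, b: PatternRegion) -> bool:
    ha, hb = a.extent / 2.0, b.extent / 2.0
    return all(abs(ca - cb) < ha + hb for ca, cb in zip(a.center, b.center))


def build_phantom(spec: PhantomSpec) -> VolumeImage:
    """Render the ground-truth phantom on the supersampled lattice grid.

    Returns a volume at ``spec.truth_voxel_mm`` isotropic resolution: air
    outside the cylinder, background material inside, and within each pattern
    region a periodic binary lattice of insert material at the region's fill
    fraction.
    """
    for a, b in itertools.combinations(spec.pattern_regions, 2):
        if _regions_overlap(a, b):
            raise ValueError(
                f"pattern regions at {a.center} and {b.center} overlap; "
                "regions must be disjoint"
            )

    period = spec.lattice_period
    dv = spec.truth_voxel_mm
    factor = spec.supersample_factor
    radius = spec.cylinder_diameter / 2.0

    # Grid extents snapped to whole lattice periods so cells are never cut.
    half_xy = np.ceil((radius + period) / period) * period
    half_z = np.ceil((spec.cylinder_length / 2.0) / period) * period
    n_xy = int(round(2 * half_xy / dv))
    n_z = int(round(2 * half_z / dv))

    z = -half_z + (np.arange(n_z) + 0.5) * dv
    y = -half_xy + (np.arange(n_xy) + 0.5) * dv
    x = -half_xy + (np.arange(n_xy) + 0.5) * dv

    vol = np.full((n_z, n_xy, n_xy), AIR_HU, dtype=np.float64)
    in_cyl = (y[:, None] ** 2 + x[None, :] ** 2) <= radius**2
    in_z = np.abs(z) <= spec.cylinder_length / 2.0
    vol[in_z[:, None, None] & in_cyl[None, :, :]] = spec.background_hu

    axes = (z, y, x)
    for region in spec.pattern_regions:
        pattern = _cell_pattern(region.fill_fraction, factor)
        sel = []
        for ax_coords, c in zip(axes, region.center):
            half = region.extent / 2.0
            sel.append(np.nonzero((ax_coords >= c - half) & (ax_coords < c + half))[0])
        iz, iy, ix = sel
        # sub-voxel index within the lattice cell, periodic in each axis
        sub = [
            np.floor(np.mod(ax[idx], period) / dv).astype(int) % factor
            for ax, idx in zip(axes, sel)
        ]
        occ = pattern[np.ix_(*sub)]
        block = vol[np.ix_(iz, iy, ix)]
        block[occ] = spec.insert_hu
        vol[np.ix_(iz, iy, ix)] = block

    return VolumeImage(vol, spacing=(dv, dv, dv), origin=(z[0], y[0], x[0]))


# ---------------------------------------------------------------------------
# acquisition simulation


def _target_grid(
    truth: VolumeImage, fov: float, slice_thickness: float, matrix_size: int
) -> tuple[tuple[float, float, float], tuple[float, float, float], tuple[int, int, int]]:
    """Spacing, origin and shape of the reconstruction grid centred on the
    truth volume."""
    pixel = fov / matrix_size
    zc = truth.axis_centers(0)
    z_lo = zc[0] - truth.spacing[0] / 2.0
    z_hi = zc[-1] + truth.spacing[0] / 2.0
    n_z = max(1, int(np.floor((z_hi - z_lo) / slice_thickness + 1e-9)))
    z_mid = 0.5 * (z_lo + z_hi)
    z0 = z_mid - n_z * slice_thickness / 2.0 + slice_thickness / 2.0
    y0 = x0 = -fov / 2.0 + pixel / 2.0
    return (
        (slice_thickness, pixel, pixel),
        (z0, y0, x0),
        (n_z, matrix_size, matrix_size),
    )


def partial_volume_average(
    truth: VolumeImage, fov: float, slice_thickness: float, matrix_size: int
) -> VolumeImage:
    """Average the truth volume into the reconstruction grid.

    Each target voxel takes the mean of the truth voxels whose centres fall
    inside it; target voxels receiving no truth voxel are air.  Requires the
    truth resolution to be at least as fine as the target resolution.
    """
    spacing, origin, shape = _target_grid(truth, fov, slice_thickness, matrix_size)
    for ax in range(3):
        if truth.spacing[ax] > spacing[ax] + 1e-9:
            raise ValueError(
                f"truth spacing {truth.spacing[ax]} mm exceeds target spacing "
                f"{spacing[ax]} mm on axis {ax}; supersample the phantom or "
                "coarsen the reconstruction grid"
            )
        extent = truth.values.shape[ax] * truth.spacing[ax]
        if spacing[ax] > extent:
            raise ValueError(
                f"target voxel ({spacing[ax]} mm on axis {ax}) is larger than "
                f"the phantom extent ({extent} mm)"
            )

    idx = []
    for ax in range(3):
        c = truth.axis_centers(ax)
        i = np.floor((c - (origin[ax] - spacing[ax] / 2.0)) / spacing[ax]).astype(int)
        i[(i < 0) | (i >= shape[ax])] = -1
        idx.append(i)
    iz, iy, ix = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij", sparse=True)
    valid = (iz >= 0) & (iy >= 0) & (ix >= 0)
    flat = (iz * shape[1] + iy) * shape[2] + ix
    flat = np.where(valid, flat, 0).ravel()
    w = valid.ravel().astype(np.float64)
    n_flat = shape[0] * shape[1] * shape[2]
    sums = np.bincount(flat, weights=truth.values.ravel() * w, minlength=n_flat)
    counts = np.bincount(flat, weights=w, minlength=n_flat)
    if not counts.any():
        raise ValueError("target grid does not intersect the phantom volume")
    out = np.full(n_flat, AIR_HU, dtype=np.float64)
    nonzero = counts > 0
    out[nonzero] = sums[nonzero] / counts[nonzero]
    return VolumeImage(out.reshape(shape), spacing=spacing, origin=origin)


def _bilateral_filter(values: np.ndarray, level: int, range_sigma: float) -> np.ndarray:
    """Slice-wise edge-preserving smoothing at an iterative strength.

    Each level applies one more pass of a fixed mild bilateral filter
    (spatial sigma 0.8 voxel, window 5, the profile's HU range sigma), so
    noise suppression grows strictly with level while strong edges are
    preserved far longer than under linear smoothing.
    """
    lo = float(values.min())
    out = values - lo
    for k in range(values.shape[0]):
        plane = out[k]
        for _ in range(level):
            plane = denoise_bilateral(
                plane, sigma_color=range_sigma, sigma_spatial=0.8,
                win_size=5, mode="edge",
            )
        out[k] = plane
    return out + lo


def simulate_acquisition(
    truth: VolumeImage,
    setting: AcquisitionSetting,
    profile: ScannerProfile,
    *,
    contrast_pivot_hu: float = 0.0,
    averaged: VolumeImage | None = None,
) -> VolumeImage:
    """Simulate one CT acquisition of the truth volume.

    Pipeline: partial-volume averaging onto the ``matrix_size``-square grid at
    pixel size fov/matrix and the setting's slice thickness; contrast scaling
    of (HU - pivot) by the profile's kVp factor; additive zero-mean Gaussian
    noise with sigma = noise_sigma_ref * sqrt(reference_ma / mA), seeded by
    ``setting.seed``; bilateral filtering at ``setting.filter_level`` (0 =
    none); addition of the scanner HU offset.

    ``averaged`` may supply a precomputed partial-volume average on the same
    geometry (an optimisation for studies that reuse one geometry across many
    noise settings).
    """
    if setting.kvp not in profile.kvp_contrast_scale:
        raise ValueError(
            f"kVp {setting.kvp} not supported by scanner {profile.scanner_id}; "
            f"supported: {sorted(profile.kvp_contrast_scale)}"
        )
    if averaged is None:
        averaged = partial_volume_average(
            truth, setting.fov, setting.slice_thickness, profile.matrix_size
        )
    out = averaged.values.copy()

    cfactor = profile.kvp_contrast_scale[setting.kvp]
    out = contrast_pivot_hu + (out - contrast_pivot_hu) * cfactor

    sigma = profile.noise_sigma_ref * np.sqrt(profile.reference_ma / setting.tube_current)
    if sigma > 0:
        rng = np.random.default_rng(setting.seed)
        out = out + rng.normal(0.0, sigma, size=out.shape)

    if setting.filter_level > 0:
        out = _bilateral_filter(out, setting.filter_level, profile.filter_range_sigma_hu)

    out = out + profile.hu_offset
    return VolumeImage(out, spacing=averaged.spacing, origin=averaged.origin)


def test_retest_pair(
    truth: VolumeImage,
    setting: AcquisitionSetting,
    profile: ScannerProfile,
    *,
    retest_seed: int | None = None,
    contrast_pivot_hu: float = 0.0,
) -> tuple[VolumeImage, VolumeImage]:
    """Simulate a scan and its 15-min re-scan: identical parameters,
    independent noise realisations."""
    if retest_seed is None:
        retest_seed = int(np.random.SeedSequence([setting.seed, 1]).generate_state(1)[0] % 2**31)
    first = simulate_acquisition(truth, setting, profile, contrast_pivot_hu=contrast_pivot_hu)
    second_setting = replace(setting, seed=retest_seed, repeat_index=1)
    second = simulate_acquisition(
        truth, second_setting, profile, contrast_pivot_hu=contrast_pivot_hu
    )
    return first, second


# ---------------------------------------------------------------------------
# study enumeration


def default_profiles() -> tuple[ScannerProfile, ScannerProfile]:
    """The two shipped virtual scanners.

    Scanner A emulates a 6-level iterative-reconstruction machine, scanner B a
    2-level (mild/strong) machine with higher reference noise and a small HU
    offset, so that the two differ in both noise texture and calibration.
    Contrast factors follow a linear energy dependence: 1.0 at 100 kVp,
    -5% per 20 kVp increase.
    """

    def kvp_scale(kvps: Iterable[float]) -> dict[float, float]:
        return {k: 1.0 - 0.05 * (k - 100.0) / 20.0 for k in kvps}

    a = ScannerProfile(
        scanner_id="A",
        hu_offset=0.0,
        noise_sigma_ref=12.0,
        reference_ma=100.0,
        kvp_contrast_scale=kvp_scale((80.0, 100.0, 140.0)),
        filter_levels=(1, 2, 3, 4, 5, 6),
        settings_matrix={
            "slice_thickness": (1.0, 2.0, 3.0, 4.0, 5.0),
            "fov": (125.0, 500.0),
            "kvp": (80.0, 100.0, 140.0),
            "ma": (40.0, 60.0, 80.0, 100.0),
        },
    )
    b = ScannerProfile(
        scanner_id="B",
        hu_offset=4.0,
        noise_sigma_ref=18.0,
        reference_ma=100.0,
        kvp_contrast_scale=kvp_scale((100.0, 135.0)),
        filter_levels=(2, 5),
        settings_matrix={
            "slice_thickness": (1.0, 2.0, 3.0, 4.0, 5.0),
            "fov": (125.0, 500.0),
            "kvp": (100.0, 135.0),
            "ma": (40.0, 60.0, 80.0, 100.0),
        },
    )
    return a, b


def enumerate_settings(profile: ScannerProfile) -> list[AcquisitionSetting]:
    """One-factor-at-a-time acquisition settings for one scanner.

    One baseline setting plus one setting per listed value of each parameter
    family (every listed value yields its own setting, including a value equal
    to the baseline's).  Seeds are zero; the study generator assigns them.
    """
    base = profile.baseline
    settings: list[AcquisitionSetting] = []

    def make(varied: str, setting_id: str, **overrides: float) -> AcquisitionSetting:
        params = dict(base)
        params.update(overrides)
        return AcquisitionSetting(
            scanner_id=profile.scanner_id,
            slice_thickness=params["slice_thickness"],
            fov=params["fov"],
            kvp=params["kvp"],
            tube_current=params["ma"],
            filter_level=int(params["filter_level"]),
            varied_parameter=varied,
            setting_id=setting_id,
        )

    settings.append(make("baseline", f"{profile.scanner_id}_baseline"))
    for value in profile.settings_matrix.get("slice_thickness", ()):
        settings.append(
            make("slice_thickness", f"{profile.scanner_id}_slice_{value:g}mm",
                 slice_thickness=value)
        )
    for value in profile.settings_matrix.get("fov", ()):
        settings.append(make("fov", f"{profile.scanner_id}_fov_{value:g}mm", fov=value))
    for level in profile.filter_levels:
        settings.append(
            make("filter", f"{profile.scanner_id}_filter_{level}", filter_level=level)
        )
    for value in profile.settings_matrix.get("kvp", ()):
        settings.append(make("kvp", f"{profile.scanner_id}_kvp_{value:g}", kvp=value))
    for value in profile.settings_matrix.get("ma", ()):
        settings.append(make("ma", f"{profile.scanner_id}_ma_{value:g}", ma=value))
    return settings


def derive_seed(master_seed: int, scanner_id: str, setting_index: int, repeat_index: int) -> int:
    """Deterministic per-volume noise seed."""
    key = [master_seed, sum(ord(c) for c in scanner_id), setting_index, repeat_index]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % 2**31)


def generate_study(
    spec: PhantomSpec,
    profiles: Sequence[ScannerProfile],
    master_seed: int,
    *,
    truth: VolumeImage | None = None,
) -> Iterator[tuple[AcquisitionSetting, VolumeImage]]:
    """Simulate the full two-scanner one-factor-at-a-time study.

    Yields every (setting, volume) pair: for each scanner, each enumerated
    setting is acquired twice (repeat 0 and the 15-min re-scan, repeat 1)
    with independent, deterministically derived noise seeds.  Partial-volume
    averages are cached per reconstruction geometry, which acquisitions of
    the same slice thickness and FOV share.
    """
    if truth is None:
        truth = build_phantom(spec)
    for profile in profiles:
        avg_cache: dict[tuple[float, float], VolumeImage] = {}
        for s_idx, setting in enumerate(enumerate_settings(profile)):
            geom = (setting.slice_thickness, setting.fov)
            if geom not in avg_cache:
                avg_cache[geom] = partial_volume_average(
                    truth, setting.fov, setting.slice_thickness, profile.matrix_size
                )
            for repeat in (0, 1):
                seed = derive_seed(master_seed, profile.scanner_id, s_idx, repeat)
                acq = replace(setting, repeat_index=repeat, seed=seed)
                vol = simulate_acquisition(
                    truth,
                    acq,
                    profile,
                    contrast_pivot_hu=spec.background_hu,
                    averaged=avg_cache[geom],
                )
                yield acq, vol
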