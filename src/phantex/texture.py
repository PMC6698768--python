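"""The 235-feature texture panel.

Eight feature families computed from a :class:`~phantex.volume_io.QuantizedROI`:

====================  =====  ========================================
family                count  definition
====================  =====  ========================================
histogram                13  first-order statistics of the ROI HU sample
glcm_2d                  60  15 co-occurrence statistics x 4 in-plane
                             directions on the analysis plane
gldm_2d                  20  5 gray-level-difference statistics x 4
                             in-plane directions
glcm_3d                  60  15 co-occurrence statistics aggregated
                             (mean/range/min/max) over 13 3-D directions
gldm_3d                  20  5 difference statistics, same aggregations
glrlm_2d                 33  11 run-length statistics x mean/min/max
                             over 4 in-plane directions
glrlm_3d                 11  11 run-length statistics, mean over the 13
                             3-D directions
fft                      18  9 spectral statistics of magnitude and of
                             phase, over the 10-90% Nyquist annulus of a
                             512-point 2-D DFT of the analysis plane
====================  =====  ========================================

Co-occurrence, difference and run-length families all operate on the 20-bin
quantized gray levels at an inter-voxel distance of 1.  All entropies use
log base 2 with 0*log(0) = 0.  Features whose definition degenerates on the
given sample (e.g. correlation of a constant image) are reported as 0 and
flagged rather than aborting the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .volume_io import QuantizedROI

# (row, col) offsets of the four in-plane directions, by angle.
DIRECTIONS_2D: dict[str, tuple[int, int]] = {
    "0": (0, 1),
    "45": (-1, 1),
    "90": (-1, 0),
    "135": (-1, -1),
}

# The 13 unique 3-D directions (one of each +/- pair), (z, y, x) offsets.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLCM_STAT_NAMES = (
    "energy", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
    "autocorrelation", "max_probability",
)
GLDM_STAT_NAMES = ("contrast", "asm", "entropy", "mean", "idm")
GLRLM_STAT_NAMES = (
    "sre", "lre", "gln", "rln", "rp",
    "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
)
AGGREGATIONS = ("mean", "range", "min", "max")
FFT_STAT_NAMES = (
    "mean", "std", "skewness", "kurtosis", "energy", "entropy",
    "max", "radial_centroid", "radial_spread",
)
HISTOGRAM_NAMES = (
    "mean", "variance", "skewness", "kurtosis", "median", "min", "max",
    "range", "p10", "p90", "mad", "energy", "entropy",
)

FFT_FRAME = 512
FFT_BAND = (0.10, 0.90)  # fraction of the Nyquist frequency
PHASE_HIST_BINS = 64


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy in bits; zero-probability terms contribute nothing."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# histogram family


def histogram_features(roi: QuantizedROI) -> tuple[dict[str, float], set[str]]:
    """13 first-order statistics of the raw HU sample within the ROI.

    Energy and entropy are computed on the 20-bin gray-level probabilities;
    everything else on the HU values.  A constant sample yields variance 0
    with skewness and kurtosis defined as 0 (flagged).
    """
    hu = roi.hu
    if hu.size < 2:
        raise ValueError("histogram features need at least 2 voxels")
    flags: set[str] = set()
    constant = float(hu.max()) == float(hu.min())
    if constant:
        skew = kurt = 0.0
        flags.update({"hist_skewness", "hist_kurtosis"})
    else:
        skew = float(sps.skew(hu))
        kurt = float(sps.kurtosis(hu, fisher=False))
    counts = np.bincount(roi.levels, minlength=roi.n_bins + 1)[1:]
    p = counts / counts.sum()
    values = {
        "hist_mean": float(hu.mean()),
        "hist_variance": float(hu.var()),
        "hist_skewness": skew,
        "hist_kurtosis": kurt,
        "hist_median": float(np.median(hu)),
        "hist_min": float(hu.min()),
        "hist_max": float(hu.max()),
        "hist_range": float(hu.max() - hu.min()),
        "hist_p10": float(np.percentile(hu, 10)),
        "hist_p90": float(np.percentile(hu, 90)),
        "hist_mad": float(np.abs(hu - hu.mean()).mean()),
        "hist_energy": float((p**2).sum()),
        "hist_entropy": _entropy2(p),
    }
    return values, flags


# ---------------------------------------------------------------------------
# co-occurrence (GLCM) and gray-level difference (GLDM)


@dataclass
class CoocMatrix:
    """Symmetrized, normalized gray-level co-occurrence matrix."""

    probabilities: np.ndarray  # (n_bins, n_bins)
    direction: tuple[int, ...]
    distance: int = 1


@dataclass
class DiffHistogram:
    """Probabilities of absolute gray-level difference k = 0..n_bins-1."""

    probabilities: np.ndarray
    direction: tuple[int, ...]


def _offset_pairs(grid: np.ndarray, offset: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Paired bin levels (a, b) at the given offset; 0 marks out-of-mask."""
    src = [slice(None)] * grid.ndim
    dst = [slice(None)] * grid.ndim
    for ax, d in enumerate(offset):
        n = grid.shape[ax]
        if abs(d) >= n and d != 0:
            return np.empty(0, int), np.empty(0, int)
        if d >= 0:
            src[ax] = slice(0, n - d)
            dst[ax] = slice(d, n)
        else:
            src[ax] = slice(-d, n)
            dst[ax] = slice(0, n + d)
    a = grid[tuple(src)].ravel()
    b = grid[tuple(dst)].ravel()
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


def glcm(grid: np.ndarray, offset: tuple[int, ...], n_bins: int) -> CoocMatrix:
    """Co-occurrence matrix of bin levels at unit distance along ``offset``.

    Counts are symmetrized (both orderings of each pair) and normalized to
    probabilities.  Raises if the direction yields no valid in-mask pair.
    """
    a, b = _offset_pairs(grid, offset)
    if a.size == 0:
        raise ValueError(f"no valid voxel pairs in direction {offset}")
    counts = np.zeros((n_bins, n_bins), dtype=np.float64)
    np.add.at(counts, (a - 1, b - 1), 1.0)
    counts = counts + counts.T
    return CoocMatrix(counts / counts.sum(), tuple(offset))


def gldm(grid: np.ndarray, offset: tuple[int, ...], n_bins: int) -> DiffHistogram:
    """Absolute gray-level difference distribution at unit distance."""
    a, b = _offset_pairs(grid, offset)
    if a.size == 0:
        raise ValueError(f"no valid voxel pairs in direction {offset}")
    k = np.abs(a - b)
    counts = np.bincount(k, minlength=n_bins).astype(np.float64)[:n_bins]
    return DiffHistogram(counts / counts.sum(), tuple(offset))


def glcm_stats(m: CoocMatrix) -> tuple[dict[str, float], set[str]]:
    """The 15 co-occurrence statistics: the Haralick set plus autocorrelation
    and maximum probability.

    With a zero-variance marginal (constant image), correlation and both
    information measures of correlation are defined as 0 and flagged.
    """
    p = m.probabilities
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    var_x = float(((i - mu) ** 2 * px).sum())

    # diagonal-band distributions
    p_sum = np.zeros(2 * n + 1)
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2 * n + 1)
    k_diff = np.arange(n)

    flags: set[str] = set()
    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        log_pxpy = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-(pxpy * log_pxpy).sum())

    if var_x > 0:
        correlation = float((((ii - mu) * (jj - mu) * p).sum()) / var_x)
    else:
        correlation = 0.0
        flags.add("correlation")
    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
        flags.add("imc1")
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    sum_average = float((k_sum * p_sum).sum())
    values = {
        "energy": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": correlation,
        "variance": float(((ii - mu) ** 2 * p).sum()),
        "idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "sum_average": sum_average,
        "sum_variance": float(((k_sum - sum_average) ** 2 * p_sum).sum()),
        "sum_entropy": _entropy2(p_sum),
        "entropy": hxy,
        "difference_variance": float(
            ((k_diff - (k_diff * p_diff).sum()) ** 2 * p_diff).sum()
        ),
        "difference_entropy": _entropy2(p_diff),
        "imc1": float(imc1),
        "imc2": imc2,
        "autocorrelation": float((ii * jj * p).sum()),
        "max_probability": float(p.max()),
    }
    return values, flags


def gldm_stats(h: DiffHistogram) -> dict[str, float]:
    """The 5 gray-level-difference statistics."""
    p = h.probabilities
    k = np.arange(p.size)
    return {
        "contrast": float((k**2 * p).sum()),
        "asm": float((p**2).sum()),
        "entropy": _entropy2(p),
        "mean": float((k * p).sum()),
        "idm": float((p / (1.0 + k**2)).sum()),
    }


def second_order_block(
    roi: QuantizedROI, mode: str
) -> tuple[dict[str, float], set[str]]:
    """80 second-order features for one mode.

    2D: 15 GLCM + 5 GLDM statistics per in-plane direction (4 directions).
    3D: the same statistics aggregated as mean/range/min/max over the 13
    unique 3-D directions.  Directions with no valid voxel pair (ROI thinner
    than 2 voxels along them) are skipped from the aggregation and flagged.
    """
    values: dict[str, float] = {}
    flags: set[str] = set()
    if mode == "2D":
        grid = roi.plane_slice
        for ang, off in DIRECTIONS_2D.items():
            prefix = f"glcm_2d_{ang}"
            try:
                stats, f = glcm_stats(glcm(grid, off, roi.n_bins))
                values.update({f"{prefix}_{k}": v for k, v in stats.items()})
                flags.update(f"{prefix}_{k}" for k in f)
            except ValueError:
                values.update({f"{prefix}_{k}": 0.0 for k in GLCM_STAT_NAMES})
                flags.update(f"{prefix}_{k}" for k in GLCM_STAT_NAMES)
        for ang, off in DIRECTIONS_2D.items():
            prefix = f"gldm_2d_{ang}"
            try:
                stats = gldm_stats(gldm(grid, off, roi.n_bins))
                values.update({f"{prefix}_{k}": v for k, v in stats.items()})
            except ValueError:
                values.update({f"{prefix}_{k}": 0.0 for k in GLDM_STAT_NAMES})
                flags.update(f"{prefix}_{k}" for k in GLDM_STAT_NAMES)
        return values, flags

    if mode != "3D":
        raise ValueError(f"mode must be '2D' or '3D', got {mode!r}")

    grid = roi.grid
    glcm_per_dir: list[dict[str, float]] = []
    gldm_per_dir: list[dict[str, float]] = []
    skipped = 0
    for off in DIRECTIONS_3D:
        try:
            stats, f = glcm_stats(glcm(grid, off, roi.n_bins))
            glcm_per_dir.append(stats)
            flags.update(f"glcm_3d_{k}" for k in f)
            gldm_per_dir.append(gldm_stats(gldm(grid, off, roi.n_bins)))
        except ValueError:
            skipped += 1
    if not glcm_per_dir:
        raise ValueError("no 3-D direction yields a valid voxel pair")
    if skipped:
        flags.add("glcm_3d_directions_skipped")

    def aggregate(per_dir: list[dict[str, float]], stat_names, family: str) -> None:
        for agg in AGGREGATIONS:
            for k in stat_names:
                arr = np.array([d[k] for d in per_dir])
                if agg == "mean":
                    v = arr.mean()
                elif agg == "range":
                    v = arr.max() - arr.min()
                elif agg == "min":
                    v = arr.min()
                else:
                    v = arr.max()
                values[f"{family}_{agg}_{k}"] = float(v)

    aggregate(glcm_per_dir, GLCM_STAT_NAMES, "glcm_3d")
    aggregate(gldm_per_dir, GLDM_STAT_NAMES, "gldm_3d")
    # propagate per-direction degeneracy flags onto the aggregated names
    base_flags = {f for f in flags if f.startswith("glcm_3d_") and not f.endswith("skipped")}
    for f in base_flags:
        stat = f[len("glcm_3d_"):]
        flags.update(f"glcm_3d_{agg}_{stat}" for agg in AGGREGATIONS)
        flags.discard(f)
    return values, flags


# ---------------------------------------------------------------------------
# run-length (GLRLM)


@dataclass
class RunLengthMatrix:
    """Run counts indexed by (gray level 1..n_bins, run length 1..L_max)."""

    counts: np.ndarray
    direction: tuple[int, ...]
    n_voxels_scanned: int


def _canonical(offset: tuple[int, ...]) -> tuple[int, ...]:
    """Flip the offset so its first nonzero component is positive (runs are
    direction-symmetric)."""
    for d in offset:
        if d != 0:
            return offset if d > 0 else tuple(-c for c in offset)
    raise ValueError("zero offset")


def glrlm(grid: np.ndarray, offset: tuple[int, ...], n_bins: int) -> RunLengthMatrix:
    """Run-length matrix: maximal runs of equal nonzero bin level along
    ``offset``-directed lines; out-of-mask voxels (level 0) break runs."""
    off = np.array(_canonical(offset))
    idx = np.indices(grid.shape).reshape(grid.ndim, -1).T
    # step count along the line from the first varied axis (step size 1 there)
    a0 = int(np.nonzero(off)[0][0])
    t = idx[:, a0]
    line = idx - np.outer(t, off)  # line anchor: constant along each line
    order = np.lexsort((t, *line.T[::-1]))
    v = grid.ravel()[np.ravel_multi_index(idx[order].T, grid.shape)]
    line_sorted = line[order]
    new_line = np.any(np.diff(line_sorted, axis=0) != 0, axis=1)
    new_run = np.empty(v.size, dtype=bool)
    new_run[0] = True
    new_run[1:] = new_line | (np.diff(v) != 0)
    run_id = np.cumsum(new_run) - 1
    run_level = v[new_run]
    run_length = np.bincount(run_id)
    keep = run_level > 0
    l_max = max(grid.shape)
    counts = np.zeros((n_bins, l_max), dtype=np.float64)
    np.add.at(counts, (run_level[keep] - 1, run_length[keep] - 1), 1.0)
    return RunLengthMatrix(counts, tuple(offset), int((v > 0).sum()))


def glrlm_stats(m: RunLengthMatrix) -> dict[str, float]:
    """The 11 run-length statistics (Galloway / Chu extensions)."""
    r = m.counts
    n_runs = r.sum()
    if n_runs == 0:
        return {k: 0.0 for k in GLRLM_STAT_NAMES}
    i = np.arange(1, r.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, r.shape[1] + 1)[None, :].astype(float)
    return {
        "sre": float((r / j**2).sum() / n_runs),
        "lre": float((r * j**2).sum() / n_runs),
        "gln": float((r.sum(axis=1) ** 2).sum() / n_runs),
        "rln": float((r.sum(axis=0) ** 2).sum() / n_runs),
        "rp": float(n_runs / m.n_voxels_scanned),
        "lgre": float((r / i**2).sum() / n_runs),
        "hgre": float((r * i**2).sum() / n_runs),
        "srlge": float((r / (i**2 * j**2)).sum() / n_runs),
        "srhge": float((r * i**2 / j**2).sum() / n_runs),
        "lrlge": float((r * j**2 / i**2).sum() / n_runs),
        "lrhge": float((r * i**2 * j**2).sum() / n_runs),
    }


def glrlm_block(roi: QuantizedROI) -> tuple[dict[str, float], set[str]]:
    """44 run-length features: 11 statistics x mean/min/max over the 4
    in-plane directions (33, 2D) plus 11 statistics averaged over the 13
    3-D directions (11, 3D)."""
    values: dict[str, float] = {}
    flags: set[str] = set()

    per_dir_2d = [
        glrlm_stats(glrlm(roi.plane_slice, off, roi.n_bins))
        for off in DIRECTIONS_2D.values()
    ]
    for agg in ("mean", "min", "max"):
        for k in GLRLM_STAT_NAMES:
            arr = np.array([d[k] for d in per_dir_2d])
            values[f"glrlm_2d_{agg}_{k}"] = float(getattr(arr, agg)())

    per_dir_3d = [glrlm_stats(glrlm(roi.grid, off, roi.n_bins)) for off in DIRECTIONS_3D]
    for k in GLRLM_STAT_NAMES:
        values[f"glrlm_3d_mean_{k}"] = float(np.mean([d[k] for d in per_dir_3d]))
    return values, flags


# ---------------------------------------------------------------------------
# spectral (FFT) family


@dataclass
class SpectrumSample:
    """In-band sample of the 2-D DFT of the analysis plane.

    The band is the radial-frequency annulus spanning 10-90% of the Nyquist
    frequency, which excludes the DC component and the highest-frequency
    corner noise.
    """

    magnitude: np.ndarray  # in-band |F|
    phase: np.ndarray  # in-band arg(F), in (-pi, pi]
    radial_freq: np.ndarray  # cycles/sample of each in-band coefficient


def embed_frame(plane: np.ndarray, size: int = FFT_FRAME) -> np.ndarray:
    """Centre the plane in a ``size``-square zero frame (crop centrally if
    larger)."""
    frame = np.zeros((size, size), dtype=np.float64)
    r, c = plane.shape
    if r > size:
        lo = (r - size) // 2
        plane = plane[lo:lo + size, :]
        r = size
    if c > size:
        lo = (c - size) // 2
        plane = plane[:, lo:lo + size]
        c = size
    r0 = (size - r) // 2
    c0 = (size - c) // 2
    frame[r0:r0 + r, c0:c0 + c] = plane
    return frame


def spectrum_sample(plane: np.ndarray, size: int = FFT_FRAME) -> SpectrumSample:
    """512-point 2-D DFT of the plane, band-limited to the 10-90% Nyquist
    annulus.

    The in-mask pixels (nonzero bin levels) are demeaned before zero-padding
    so the spectrum reflects the texture rather than the ROI's mean level and
    silhouette; a constant plane therefore transforms to an identically zero
    spectrum.
    """
    plane = np.asarray(plane, dtype=np.float64)
    support = plane != 0
    if support.any():
        plane = np.where(support, plane - plane[support].mean(), 0.0)
    frame = embed_frame(plane, size)
    spec = np.fft.fft2(frame)
    f = np.fft.fftfreq(size)
    radial = np.hypot(f[:, None], f[None, :])
    nyq = 0.5
    band = (radial >= FFT_BAND[0] * nyq) & (radial <= FFT_BAND[1] * nyq)
    return SpectrumSample(
        magnitude=np.abs(spec[band]),
        phase=np.angle(spec[band]),
        radial_freq=radial[band],
    )


def fft_features(s: SpectrumSample) -> tuple[dict[str, float], set[str]]:
    """18 spectral features: 9 statistics of the magnitude and of the phase.

    Magnitude entropy/energy use p_i = |F_i| / sum |F_j|; the radial spectral
    centroid and spread are magnitude-weighted moments of radial frequency.
    Phase entropy/energy use a 64-bin histogram over (-pi, pi]; phase radial
    moments weight by |phase|.  A constant plane has (numerically) zero
    in-band magnitude: its magnitude statistics are reported as 0 and flagged.
    """
    values: dict[str, float] = {}
    flags: set[str] = set()

    mag = s.magnitude
    total = mag.sum()
    degenerate = not np.isfinite(total) or total <= mag.size * 1e-9
    if degenerate:
        for k in FFT_STAT_NAMES:
            values[f"fft_mag_{k}"] = 0.0
            flags.add(f"fft_mag_{k}")
    else:
        p = mag / total
        centroid = float((s.radial_freq * p).sum())
        values.update({
            "fft_mag_mean": float(mag.mean()),
            "fft_mag_std": float(mag.std()),
            "fft_mag_skewness": float(sps.skew(mag)),
            "fft_mag_kurtosis": float(sps.kurtosis(mag, fisher=False)),
            "fft_mag_energy": float((p**2).sum()),
            "fft_mag_entropy": _entropy2(p),
            "fft_mag_max": float(mag.max()),
            "fft_mag_radial_centroid": centroid,
            "fft_mag_radial_spread": float(
                np.sqrt(((s.radial_freq - centroid) ** 2 * p).sum())
            ),
        })

    ph = s.phase
    hist, _ = np.histogram(ph, bins=PHASE_HIST_BINS, range=(-np.pi, np.pi))
    q = hist / hist.sum()
    ph_abs = np.abs(ph)
    ph_total = ph_abs.sum()
    if ph.std() == 0:
        ph_skew = ph_kurt = 0.0
        flags.update({"fft_phase_skewness", "fft_phase_kurtosis"})
    else:
        ph_skew = float(sps.skew(ph))
        ph_kurt = float(sps.kurtosis(ph, fisher=False))
    if ph_total > 0:
        w = ph_abs / ph_total
        ph_centroid = float((s.radial_freq * w).sum())
        ph_spread = float(np.sqrt(((s.radial_freq - ph_centroid) ** 2 * w).sum()))
    else:
        ph_centroid = ph_spread = 0.0
        flags.update({"fft_phase_radial_centroid", "fft_phase_radial_spread"})
    values.update({
        "fft_phase_mean": float(ph.mean()),
        "fft_phase_std": float(ph.std()),
        "fft_phase_skewness": ph_skew,
        "fft_phase_kurtosis": ph_kurt,
        "fft_phase_energy": float((q**2).sum()),
        "fft_phase_entropy": _entropy2(q),
        "fft_phase_max": float(ph.max()),
        "fft_phase_radial_centroid": ph_centroid,
        "fft_phase_radial_spread": ph_spread,
    })
    return values, flags


# ---------------------------------------------------------------------------
# the panel


@dataclass
class FeatureVector:
    """Ordered 235-entry feature map with degeneracy flags.

    The block layout is fixed: histogram 1-13, 2-D second order 14-93,
    3-D second order 94-173, 2-D run length 174-206, 3-D run length 207-217,
    spectral 218-235.
    """

    names: tuple[str, ...]
    values: np.ndarray
    flags: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.names, self.values)}


def feature_names() -> tuple[str, ...]:
    """Canonical ordering of the 235 feature names."""
    names: list[str] = [f"hist_{k}" for k in HISTOGRAM_NAMES]
    for ang in DIRECTIONS_2D:
        names += [f"glcm_2d_{ang}_{k}" for k in GLCM_STAT_NAMES]
    for ang in DIRECTIONS_2D:
        names += [f"gldm_2d_{ang}_{k}" for k in GLDM_STAT_NAMES]
    for agg in AGGREGATIONS:
        names += [f"glcm_3d_{agg}_{k}" for k in GLCM_STAT_NAMES]
    for agg in AGGREGATIONS:
        names += [f"gldm_3d_{agg}_{k}" for k in GLDM_STAT_NAMES]
    for agg in ("mean", "min", "max"):
        names += [f"glrlm_2d_{agg}_{k}" for k in GLRLM_STAT_NAMES]
    names += [f"glrlm_3d_mean_{k}" for k in GLRLM_STAT_NAMES]
    names += [f"fft_mag_{k}" for k in FFT_STAT_NAMES]
    names += [f"fft_phase_{k}" for k in FFT_STAT_NAMES]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = feature_names()


def feature_family(name: str) -> str:
    """The family (one of the eight subgroups) a feature belongs to."""
    for fam in ("hist", "glcm_2d", "gldm_2d", "glcm_3d", "gldm_3d",
                "glrlm_2d", "glrlm_3d", "fft"):
        if name.startswith(fam + "_"):
            return "histogram" if fam == "hist" else fam
    raise ValueError(f"unknown feature {name!r}")


FEATURE_FAMILIES: tuple[str, ...] = tuple(feature_family(n) for n in FEATURE_NAMES)

#: Families whose features are second-order (spatial co-occurrence based).
SECOND_ORDER_FAMILIES = ("glcm_2d", "gldm_2d", "glcm_3d", "gldm_3d",
                         "glrlm_2d", "glrlm_3d")


def extract_panel(roi: QuantizedROI) -> FeatureVector:
    """Compute the full 235-feature panel on one quantized ROI."""
    values: dict[str, float] = {}
    flags: set[str] = set()
    for part, f in (
        histogram_features(roi),
        second_order_block(roi, "2D"),
        second_order_block(roi, "3D"),
        glrlm_block(roi),
        fft_features(spectrum_sample(roi.plane_slice)),
    ):
        values.update(part)
        flags.update(f)
    arr = np.array([values[k] for k in FEATURE_NAMES], dtype=np.float64)
    if not np.isfinite(arr).all():
        bad = [k for k, v in zip(FEATURE_NAMES, arr) if not np.isfinite(v)]
        raise ValueError(f"non-finite feature values: {bad}")
    kept_flags = (flags & set(FEATURE_NAMES)) | {f for f in flags if f.endswith("skipped")}
    return FeatureVector(FEATURE_NAMES, arr, frozenset(kept_flags))
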