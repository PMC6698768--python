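# Methods

This note documents the models, conventions and design choices behind
`phantex`: the digital texture phantom, the virtual-scanner acquisition
model, the 235-feature texture panel, and the percent-absolute-difference
(PAD) reliability framework.

## 1. The digital texture phantom

The phantom is a short cylinder (default diameter 150 mm, length 60 mm) of
homogeneous background material at 40 HU — a urethane-like soft-tissue
density — surrounded by air at −1000 HU. Three axis-parallel cubic pattern
regions (side 50 mm) sit fully inside the cylinder; each contains a
periodic binary lattice of insert material at −40 HU (−80 HU relative
contrast, an ABS-plastic-like value) occupying a prescribed *fill
fraction*: 10%, 20% and 40% by default, spanning smooth to coarse texture.
Real material densities for 3-D-printed texture inserts are not tabulated
anywhere authoritative; these values were chosen once to put both materials
in the soft-tissue range with a contrast comfortably above the simulated
noise floor, and are configuration keys, not constants.

The lattice has period 2 mm. The ground-truth grid samples each lattice
cell with `supersample_factor`³ voxels (period/factor mm voxel size), and
within each cell the `round(fill · factor³)` sub-voxels nearest the cell
centre are occupied. This makes the realized occupancy exactly
`round(fill·factor³)/factor³` — within half a sub-voxel of the requested
fill, so occupancy converges to the fill fraction as the supersampling
grows (at factor 4 the error is below 0.008) — and makes the pattern
deterministic, periodic, and identical across cells. A consequence used by
the tests: the noise-free mean HU of a region interior is
`bg + fill·(insert − bg)·contrast` to within ~1 HU of partial-volume
blur at the region boundary.

Grid extents snap to whole lattice periods so cells are never truncated;
coordinates are voxel-centre based, axis order (z, y, x), origin at the
phantom centre.

## 2. The virtual scanners

`simulate_acquisition` maps a truth volume to a reconstruction in five
steps, in order:

1. **Partial-volume averaging.** Each target voxel (512×512 in-plane grid
   at pixel size FOV/512 by default, slice thickness from the setting)
   takes the mean of the truth voxels whose centres fall inside it. Target
   voxels receiving no truth voxel are air. The truth grid must be at least
   as fine as the target grid — the simulator refuses to interpolate
   upward, and likewise refuses a target voxel larger than the phantom.
2. **Contrast scaling.** (HU − pivot) is multiplied by the profile's kVp
   factor; the pivot is the phantom background so tube voltage modulates
   the texture contrast, not the background calibration. The shipped
   profiles use a linear energy dependence, factor 1 at 100 kVp and −5%
   per +20 kVp (80→1.05, 135→0.9125, 140→0.90). The slope is a free
   simulator parameter; only its sign and monotonicity matter to the
   qualitative conclusions.
3. **Noise.** Additive zero-mean Gaussian noise with
   σ(mA) = σ_ref·√(mA_ref/mA), the standard photon-statistics scaling.
   σ_ref is 12 HU (scanner A) and 18 HU (scanner B) at 100 mA, chosen in
   the range of abdominal-protocol noise and deliberately different so the
   two scanners are not interchangeable. Noise is stationary and white: no
   streaks, scatter, beam hardening or correlated reconstruction noise.
4. **Reconstruction filtering.** Iterative-reconstruction strength *n* is
   emulated by *n* passes of a fixed slice-wise bilateral filter (range
   sigma 60 HU, spatial sigma 0.8 voxel, 5×5 window, edge-replicated
   borders). Iterating a fixed mild filter — rather than widening a single
   filter's range sigma — was chosen because it gives strictly monotone
   noise suppression across levels while still preserving strong edges,
   which matches the intended behaviour of vendor iterative-reconstruction
   level knobs; widening only the range sigma of a single bilateral pass
   turns out not to reduce noise monotonically. Scanner A exposes levels
   1–6; scanner B levels 2 ("mild") and 5 ("strong").
5. **Calibration offset.** A constant HU offset per scanner (0 for A,
   +4 for B), reflecting the inter-scanner Hounsfield-unit variation seen
   between real machines.

**Study enumeration.** Each scanner acquires one baseline scan (slice
3 mm, FOV 500 mm, 100 kVp, 100 mA, no filter — baseline values are
configuration keys, since no canonical baseline exists) plus one scan per
listed value of each parameter family, one factor at a time. Every listed
value yields its own setting, including values equal to the baseline's, so
the default matrix gives 1 + (5+2+6+3+4) = 21 settings on scanner A and
1 + (5+2+2+2+4) = 16 on scanner B. Every setting is acquired twice —
test plus re-test — with independent noise seeds. Per-volume seeds derive
deterministically from (master seed, scanner, setting index, repeat) via
`numpy.random.SeedSequence` and are recorded in the study manifest, making
every study bit-reproducible.

## 3. ROIs and quantization

ROIs are parametric spheres (default: radius 20 mm centred on each pattern
region), membership by voxel-centre-in-sphere. Voxels below −200 HU are
dropped from the sample (mirroring the exclusion of air bubbles from
physical phantom ROIs); the remainder is clipped to the 12-bit CT window
[−1024, 3071] and quantized to 20 equal-width bins over the ROI's own
[min, max]. The maximum maps to bin 20; a constant sample maps to bin 1.
Reconciling "20-bin quantization" with "12-bit gray levels": the 12-bit
window is a clip applied before binning, and all matrix-based families
operate on the 20 bin levels. Feature extraction requires at least 32
usable voxels.

The 2-D analysis plane is the slice, over all axial/coronal/sagittal
slices, with the largest in-plane mask diameter (maximum pairwise distance
between voxel centres, in mm). Ties break axial > coronal > sagittal, then
lowest slice index, making the choice deterministic on symmetric masks.

## 4. The 235-feature panel

Eight families in a fixed canonical order (1-based indices):

| block | indices | contents |
|---|---|---|
| histogram | 1–13 | mean, variance, skewness, kurtosis (Pearson), median, min, max, range, p10, p90, mean abs. deviation, energy and entropy of the 20-bin distribution |
| 2-D GLCM | 14–73 | 15 statistics × 4 directions (0°, 45°, 90°, 135°, distance 1) |
| 2-D GLDM | 74–93 | 5 statistics × 4 directions |
| 3-D GLCM | 94–153 | 15 statistics × {mean, range, min, max} over the 13 unique 3-D directions |
| 3-D GLDM | 154–173 | 5 statistics × the same aggregations |
| 2-D GLRLM | 174–206 | 11 statistics × {mean, min, max} over 4 directions |
| 3-D GLRLM | 207–217 | 11 statistics × mean over 13 directions |
| FFT | 218–235 | 9 statistics of magnitude, 9 of phase |

The 15 co-occurrence statistics are the Haralick set (energy, contrast,
correlation, variance, inverse difference moment, sum average, sum
variance, sum entropy, entropy, difference variance, difference entropy,
and both information measures of correlation) plus autocorrelation and
maximum probability; sum variance is centred on the sum average. The GLDM
statistics are contrast, angular second moment, entropy, mean and inverse
difference moment of the absolute-difference distribution. The GLRLM
statistics are SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE,
LRHGE (Galloway plus the Chu gray-level extensions). Co-occurrence
matrices are symmetrized and normalized; inter-voxel distance is fixed at
1 voxel throughout. All entropies are log base 2 with 0·log 0 ≡ 0.

The FFT family embeds the quantized (bin-level) analysis plane — demeaned
over its mask support — in a 512×512 zero frame, takes the 2-D DFT, and
retains the radial-frequency annulus from 10% to 90% of the Nyquist
frequency, which excludes both DC/silhouette leakage and corner noise.
Using bin levels rather than raw HU keeps the spectrum comparable across
settings with different calibration. For the magnitude: mean, s.d.,
skewness, kurtosis, energy and entropy of p_i = |F_i|/Σ|F_j|, maximum,
and the magnitude-weighted radial spectral centroid and spread. For the
phase: the same moment statistics over the phase values, energy and
entropy of a 64-bin histogram on (−π, π], maximum, and |phase|-weighted
radial moments.

**Degeneracy policy.** Statistics whose definition collapses on a given
sample (correlation of a constant image, skewness of a constant sample,
the magnitude statistics of an all-zero in-band spectrum) are reported as
0 and flagged in the feature table's `degenerate_flag` column rather than
aborting the panel; 3-D directions along which the ROI is thinner than two
voxels are skipped from the aggregations and flagged. The panel always
returns exactly 235 finite values, bitwise reproducibly.

The canonical name/family manifest ships as
`src/phantex/data/feature_names.txt`; a test asserts it cannot change
silently.

## 5. The reliability framework

PAD = |test − baseline| / |baseline|, with a zero-baseline guard: 0/0 → 0
(a feature identically zero under both conditions carries no instability
signal) and x/0 → ∞, flagged and never reliable. PAD is computed per ROI
and never pooled across ROIs; tallies are reported pooled and per ROI.

Two thresholds coexist by design: the **tally cutoff 0.15** defines the
percent-repeatable/percent-robust summaries, and the **reliable band
0.05** defines the reliable set — a feature is reliable exactly when its
maximum PAD over all repeatability and robustness records is ≤ 0.05 on
both scanners. "Reproducibility" is operationalized as that cross-scanner
conjunction; no correlation-based index (ICC/CCC) is computed, since with
three ROIs only the signal difference is meaningful.

The filter-level contrast reports, per scanner and level, the mean PAD of
the filter-family robustness records, a paired sign test against zero
change (distribution-free; the choice of test is free since PADs are far
from zero whenever filtering is active), and a Kendall-tau trend across
levels. Heatmaps (features × settings, PAD averaged over ROIs) are written
as unclipped CSV plus a PNG clipped to [0, 0.20] on a blue-to-red scale
with the 5% band marked.

## 6. What the simulator does and does not emulate

The generator reproduces the *structure* of a two-scanner phantom
reliability study — geometry, partial volume, noise-versus-exposure,
energy-dependent contrast, nonlinear edge-preserving filtering, scanner
calibration offsets, test-retest repeats — under a fully controlled,
seeded noise model. It does **not** model sinogram-domain reconstruction,
beam hardening, scatter, motion, detector correlations or DICOM
semantics. Consequently, passing tests demonstrate that the *pipeline*
(panel + framework) behaves correctly and that the qualitative stability
ranking (FFT-based spectral features, especially magnitude and phase
entropy, more stable than co-occurrence/run-length families under noise
and filter variation) emerges under a realistic parametric noise model.
Percent tallies measured on physical scanners depend on scanner hardware
and are expected to differ numerically from simulated ones.

## 7. Problem sizes and numerical conventions

The library default is the full 512×512 reconstruction grid with 4×
phantom supersampling (0.5 mm truth voxels). The test suite and the
acceptance script run the same code on a 64×64 grid with 2× supersampling
(1 mm truth voxels) and, where noted, the `fast_config` profile that trims
the filter-level and tube-current lists to their first and last values —
sizes chosen so a complete two-scanner study simulates and extracts in
about ten seconds while every structural count (21/16 settings, 235
features, 1175/470 family comparisons) is grid-independent. Stochastic
properties (noise scaling, invariant-feature recovery, filter trend, the
FFT-versus-second-order stability ranking) are asserted over ten seeded
replicate studies; the filter trend is evaluated on the replicate-averaged
mean PAD per level, since the per-study mean of second-order PADs is
itself noisy.

Other conventions: voxel arrays are float64 end to end; NIfTI-1 I/O
(via nibabel) stores (x, y, z) data with spacing and origin in the affine
and round-trips exactly; percentiles use NumPy's linear interpolation;
kurtosis is the non-excess (Pearson) form; sample moments are population
(ddof 0) forms.

## 8. Known limitations

- The bilateral-iteration filter model is one of many plausible
  iterative-reconstruction emulations; absolute filter-family PAD levels
  depend on it, though the monotone trend does not.
- Equal-width quantization over the ROI's own range couples every
  matrix-based feature to the sample extremes, which is a genuine source
  of test-retest instability — deliberately retained, as real pipelines
  with per-ROI normalization share it.
- The phase-weighted radial moments of the FFT block are a pragmatic
  construction (there is no standard definition of a "phase spectral
  centroid"); they are deterministic and scale-free but should not be
  interpreted physically.
- With three ROIs and one phantom, reliability verdicts are about the
  simulated acquisition chain, not about biological variability.
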