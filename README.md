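# phantex

Digital CT texture-phantom simulation and radiomic-feature reliability
analysis.

Radiomic (CT texture analysis, CTTA) studies extract hundreds of quantitative
features from CT images, but many of those features are unstable: their
values drift between a scan and a re-scan fifteen minutes later, when a
single acquisition parameter changes, or between two scanners. Feeding
unstable features into predictive models inflates false-discovery risk,
especially in multicenter studies. `phantex` is a testbed for that problem:
it simulates a texture phantom imaged on two configurable virtual CT
scanners under a one-factor-at-a-time acquisition matrix, extracts a fixed
235-feature texture panel, and identifies the features that remain stable —
*repeatable*, *robust*, and *reproducible* — under a percent-absolute-
difference criterion.

It is aimed at radiomics methodologists who want a fully controlled,
deterministic environment in which feature-stability pipelines can be
developed and validated before being pointed at physical-scanner data.

## The model

**Phantom.** A 15 cm short cylinder of soft-tissue-density background
(40 HU) contains three 5×5 cm texture regions. Each region holds a periodic
binary lattice (period 2 mm) of lower-density insert material (−40 HU,
i.e. −80 HU relative contrast) occupying a prescribed volume fraction — 10%,
20% and 40% fill — spanning smooth to coarse texture. Outside the cylinder
is air (−1000 HU).

**Acquisition.** Each virtual scanner maps the ground-truth volume to a
reconstruction through: partial-volume averaging onto a 512×512 grid at
pixel size FOV/512 and the chosen slice thickness; tube-voltage-dependent
contrast scaling; additive Gaussian noise with

&nbsp;&nbsp;&nbsp;&nbsp;σ(mA) = σ_ref · √(mA_ref / mA);

*n* passes of an edge-preserving bilateral filter for iterative-
reconstruction level *n*; and a scanner HU offset. Scanner A exposes six
filter levels and three tube voltages, scanner B two of each, with
different reference noise and calibration offset. One-factor-at-a-time
variation over {slice thickness 1–5 mm, FOV 125/500 mm, filter level,
kVp, mA 40–100} plus a baseline yields 21 settings on scanner A and 16 on
scanner B, each acquired twice (test plus 15-minute re-test) with
independent noise.

**Feature panel.** From each of three spherical ROIs, gray levels are
clipped to the 12-bit CT window and quantized to 20 equal-width bins; 2-D
families use the axial/coronal/sagittal slice with the largest in-plane
diameter. The panel is fixed at 235 features in eight families: 13
first-order histogram statistics; 15 gray-level co-occurrence (GLCM)
statistics × 4 in-plane directions plus 5 gray-level difference (GLDM)
statistics × 4 directions in 2-D (80); the same statistics aggregated
mean/range/min/max over the 13 unique 3-D directions (80); 11 run-length
(GLRLM) statistics × mean/min/max over in-plane directions (33) and
direction-averaged in 3-D (11); and 9 spectral statistics each of the
magnitude and phase of a 512-point 2-D FFT restricted to the 10–90% Nyquist
annulus (18).

**Reliability.** For feature value x against reference x₀ the instability
measure is the percent absolute difference

&nbsp;&nbsp;&nbsp;&nbsp;PAD = |x − x₀| / |x₀|.

Repeatability compares each setting's re-scan to its first scan; robustness
compares each varied setting to the baseline scan, grouped by the varied
parameter. Percent-stable tallies use a PAD cutoff of 0.15; a feature is
**reliable** when every one of its repeatability and robustness PADs stays
within the 5% band on *both* scanners (the cross-scanner reproducibility
conjunction). Heatmaps of PAD (clipped at 20% for display) are exported per
scanner and comparison kind.

## Worked example

```python
from phantex import fast_config, run_study, assess

cfg = fast_config(master_seed=7)           # reduced 64x64 grid profile
manifest, features = run_study(cfg)        # simulate + extract in memory
report = assess(features, manifest, cfg, out_dir="demo_reports")

pooled = report.family_tallies.query("parameter_family == 'all' and roi_label == 'all'")
for _, r in pooled.iterrows():
    print(f"scanner {r.scanner_id:>2} {r.comparison_kind:<13} "
          f"{100*r.fraction:5.1f}% of {r.n_comparisons} comparisons within 15%")
print(f"reliable features ({len(report.reliable_features)}):",
      ", ".join(report.reliable_features))
```

prints

```
scanner  A repeatability  62.4% of 10575 comparisons within 15%
scanner  A robustness     52.1% of 9870 comparisons within 15%
scanner  B repeatability  60.8% of 9870 comparisons within 15%
scanner  B robustness     53.7% of 9165 comparisons within 15%
reliable features (6): glrlm_3d_mean_sre, fft_mag_entropy, fft_phase_entropy, fft_phase_max, fft_phase_radial_centroid, fft_phase_radial_spread
```

Roughly half of all feature comparisons move by more than 15% under
realistic noise on this reduced grid, and the handful of features that
survive the 5% reliability band on both scanners is dominated by the FFT
block — in particular the entropy of the FFT magnitude and phase — while
the co-occurrence and run-length families are far more sensitive to noise,
filtering and geometry changes. `demo_reports/` receives the comparison
records, the per-feature verdict table, per-family tallies, the
filter-level contrast and the PAD heatmaps.

The same pipeline is available from the shell:

```bash
phantex run-all --fast --seed 7 --out demo_study      # simulate, extract, assess
phantex simulate --config my_config.yaml --out study  # stage by stage
phantex extract study && phantex assess study
```

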