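master_seed: 0
output_dir: study_out
phantom:
  cylinder_diameter: 150.0
  cylinder_length: 60.0
  pattern_regions:
  - center:
    - 0.0
    - 38.0
    - 0.0
    extent: 50.0
    fill_fraction: 0.1
  - center:
    - 0.0
    - -20.0
    - -34.0
    extent: 50.0
    fill_fraction: 0.2
  - center:
    - 0.0
    - -20.0
    - 34.0
    extent: 50.0
    fill_fraction: 0.4
  background_hu: 40.0
  insert_hu: -40.0
  lattice_period: 2.0
  supersample_factor: 4
scanners:
- scanner_id: A
  hu_offset: 0.0
  noise_sigma_ref: 12.0
  reference_ma: 100.0
  kvp_contrast_scale:
    80.0: 1.05
    100.0: 1.0
    140.0: 0.9
  filter_levels:
  - 1
  - 2
  - 3
  - 4
  - 5
  - 6
  settings_matrix:
    slice_thickness:
    - 1.0
    - 2.0
    - 3.0
    - 4.0
    - 5.0
    fov:
    - 125.0
    - 500.0
    kvp:
    - 80.0
    - 100.0
    - 140.0
    ma:
    - 40.0
    - 60.0
    - 80.0
    - 100.0
  baseline:
    slice_thickness: 3.0
    fov: 500.0
    kvp: 100.0
    ma: 100.0
    filter_level: 0
  matrix_size: 512
  filter_range_sigma_hu: 60.0
- scanner_id: B
  hu_offset: 4.0
  noise_sigma_ref: 18.0
  reference_ma: 100.0
  kvp_contrast_scale:
    100.0: 1.0
    135.0: 0.9125
  filter_levels:
  - 2
  - 5
  settings_matrix:
    slice_thickness:
    - 1.0
    - 2.0
    - 3.0
    - 4.0
    - 5.0
    fov:
    - 125.0
    - 500.0
    kvp:
    - 100.0
    - 135.0
    ma:
    - 40.0
    - 60.0
    - 80.0
    - 100.0
  baseline:
    slice_thickness: 3.0
    fov: 500.0
    kvp: 100.0
    ma: 100.0
    filter_level: 0
  matrix_size: 512
  filter_range_sigma_hu: 60.0
rois:
- label: roi1
  center:
  - 0.0
  - 38.0
  - 0.0
  radius: 20.0
- label: roi2
  center:
  - 0.0
  - -20.0
  - -34.0
  radius: 20.0
- label: roi3
  center:
  - 0.0
  - -20.0
  - 34.0
  radius: 20.0
analysis:
  n_bins: 20
  tally_cutoff: 0.15
  reliable_band: 0.05
  clip_max: 0.2
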