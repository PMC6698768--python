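"""Stage orchestration: simulate a study, extract the feature table, and
run the reliability assessment.

All stages work on plain pandas tables; the file-based variants exchange the
same tables as CSV plus NIfTI-1 volumes, so each stage can be re-run or
replaced independently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from . import reliability as rel
from .config import PipelineConfig
from .phantom import (
    AcquisitionSetting,
    ScannerProfile,
    VolumeImage,
    build_phantom,
    generate_study,
)
from .texture import FEATURE_FAMILIES, FEATURE_NAMES, extract_panel
from .volume_io import extract_roi, make_sphere_roi, read_nifti, write_nifti

MANIFEST_COLUMNS = [
    "scanner_id", "setting_id", "varied_parameter", "slice_thickness", "fov",
    "kvp", "ma", "filter_level", "repeat_index", "seed", "filename",
]
FEATURE_COLUMNS = [
    "scanner_id", "setting_id", "varied_parameter", "repeat_index", "roi_label",
    "feature_index", "feature_name", "family", "value", "degenerate_flag",
]


def _select_scanners(
    config: PipelineConfig, scanner_ids: Sequence[str] | None
) -> tuple[ScannerProfile, ...]:
    if scanner_ids is None:
        return config.scanners
    by_id = {s.scanner_id: s for s in config.scanners}
    unknown = [s for s in scanner_ids if s not in by_id]
    if unknown:
        raise ValueError(f"unknown scanner ids {unknown}; have {sorted(by_id)}")
    return tuple(by_id[s] for s in scanner_ids)


def _manifest_row(setting: AcquisitionSetting, filename: str) -> dict:
    return {
        "scanner_id": setting.scanner_id,
        "setting_id": setting.setting_id,
        "varied_parameter": setting.varied_parameter,
        "slice_thickness": setting.slice_thickness,
        "fov": setting.fov,
        "kvp": setting.kvp,
        "ma": setting.tube_current,
        "filter_level": setting.filter_level,
        "repeat_index": setting.repeat_index,
        "seed": setting.seed,
        "filename": filename,
    }


def study_volumes(
    config: PipelineConfig, scanner_ids: Sequence[str] | None = None
) -> Iterator[tuple[AcquisitionSetting, VolumeImage]]:
    """Simulate every (setting, repeat) volume of the configured study."""
    truth = build_phantom(config.phantom)
    yield from generate_study(
        config.phantom,
        _select_scanners(config, scanner_ids),
        config.master_seed,
        truth=truth,
    )


def simulate_study(
    config: PipelineConfig,
    out_dir: str | Path,
    scanner_ids: Sequence[str] | None = None,
    force: bool = False,
) -> pd.DataFrame:
    """Write all study volumes as NIfTI plus the study manifest CSV.

    Refuses to overwrite a directory already holding a manifest unless
    ``force`` is set.  Returns the manifest table.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} exists; re-run with force to overwrite"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for setting, volume in study_volumes(config, scanner_ids):
        fname = f"{setting.setting_id}_rep{setting.repeat_index}.nii.gz"
        write_nifti(volume, out_dir / fname)
        rows.append(_manifest_row(setting, fname))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    config.dump(out_dir / "resolved_config.yaml")
    return manifest


def features_for_volume(
    setting: AcquisitionSetting, volume: VolumeImage, config: PipelineConfig
) -> list[dict]:
    """Feature-table rows (one per ROI x feature) for one volume."""
    rows = []
    for roi_def in config.rois:
        mask = make_sphere_roi(volume, roi_def.center, roi_def.radius, roi_def.label)
        roi = extract_roi(volume, mask, n_bins=config.analysis.n_bins)
        panel = extract_panel(roi)
        for idx, (name, value) in enumerate(zip(panel.names, panel.values), start=1):
            rows.append({
                "scanner_id": setting.scanner_id,
                "setting_id": setting.setting_id,
                "varied_parameter": setting.varied_parameter,
                "repeat_index": setting.repeat_index,
                "roi_label": roi_def.label,
                "feature_index": idx,
                "feature_name": name,
                "family": _FAMILY_BY_NAME[name],
                "value": float(value),
                "degenerate_flag": name in panel.flags,
            })
    return rows


_FAMILY_BY_NAME = dict(zip(FEATURE_NAMES, FEATURE_FAMILIES))


def extract_study_features(
    config: PipelineConfig,
    volumes: Iterable[tuple[AcquisitionSetting, VolumeImage]] | None = None,
    scanner_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Extract the long-format feature table for a whole study.

    ``volumes`` defaults to simulating the study in memory.
    """
    if volumes is None:
        volumes = study_volumes(config, scanner_ids)
    rows: list[dict] = []
    for setting, volume in volumes:
        rows.extend(features_for_volume(setting, volume, config))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def extract_features_from_dir(
    study_dir: str | Path, config: PipelineConfig
) -> pd.DataFrame:
    """Extract features from a simulated study directory (manifest + NIfTI)."""
    study_dir = Path(study_dir)
    manifest = pd.read_csv(study_dir / "manifest.csv")
    rows: list[dict] = []
    for rec in manifest.to_dict("records"):
        path = study_dir / rec["filename"]
        if not path.exists():
            raise FileNotFoundError(f"volume listed in manifest is missing: {path}")
        volume = read_nifti(path)
        setting = AcquisitionSetting(
            scanner_id=rec["scanner_id"],
            slice_thickness=rec["slice_thickness"],
            fov=rec["fov"],
            kvp=rec["kvp"],
            tube_current=rec["ma"],
            filter_level=int(rec["filter_level"]),
            varied_parameter=rec["varied_parameter"],
            repeat_index=int(rec["repeat_index"]),
            seed=int(rec["seed"]),
            setting_id=rec["setting_id"],
        )
        rows.extend(features_for_volume(setting, volume, config))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def run_study(
    config: PipelineConfig, scanner_ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and extract in memory; returns (manifest, feature table)."""
    manifest_rows = []
    feature_rows: list[dict] = []
    for setting, volume in study_volumes(config, scanner_ids):
        manifest_rows.append(_manifest_row(setting, ""))
        feature_rows.extend(features_for_volume(setting, volume, config))
    return (
        pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS),
        pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS),
    )


def assess(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> rel.ReliabilityReport:
    """Run the reliability assessment and optionally write all reports.

    Produces comparisons.csv (every PAD record), reliability_report.csv
    (per-feature verdicts), family_tallies.csv, filter_contrast.csv and the
    per-scanner heatmaps.
    """
    if features.empty:
        raise ValueError("empty feature table")
    params = config.analysis
    rep_records, rep_tally = rel.repeatability_table(features, params.tally_cutoff)
    rob_records, rob_tally = rel.robustness_table(features, params.tally_cutoff)
    records = pd.concat([rep_records, rob_records], ignore_index=True)
    report = rel.reliable_set(records, params.reliable_band, params.tally_cutoff)
    contrast = rel.filter_effect_contrast(records, manifest)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records.to_csv(out_dir / "comparisons.csv", index=False)
        report.per_feature.to_csv(out_dir / "reliability_report.csv")
        report.family_tallies.to_csv(out_dir / "family_tallies.csv", index=False)
        contrast.to_csv(out_dir / "filter_contrast.csv", index=False)
        rel.heatmap_export(records, out_dir, params.clip_max, params.reliable_band)
    return report
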