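"""Pipeline configuration: phantom geometry, scanner profiles, ROIs and
analysis parameters, serialized as YAML.

The shipped default configuration reproduces the full two-scanner
acquisition matrix (5 slice thicknesses, 2 fields of view, 6-level vs
2-level reconstruction filtering, 3 vs 2 tube voltages, 4 tube currents).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from importlib import resources
from pathlib import Path

import yaml

from .phantom import PatternRegion, PhantomSpec, ScannerProfile, default_profiles


@dataclass(frozen=True)
class SphereROIDef:
    label: str
    center: tuple[float, float, float]  # (z, y, x) mm
    radius: float  # mm


@dataclass(frozen=True)
class AnalysisParams:
    n_bins: int = 20
    tally_cutoff: float = 0.15
    reliable_band: float = 0.05
    clip_max: float = 0.20


@dataclass
class PipelineConfig:
    """Resolved configuration of one simulation-and-analysis run."""

    phantom: PhantomSpec
    scanners: tuple[ScannerProfile, ...]
    rois: tuple[SphereROIDef, ...]
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    master_seed: int = 0
    output_dir: str = "study_out"

    def to_dict(self) -> dict:
        d = {
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
            "phantom": asdict(self.phantom),
            "scanners": [asdict(s) for s in self.scanners],
            "rois": [asdict(r) for r in self.rois],
            "analysis": asdict(self.analysis),
        }
        for r, rd in zip(self.phantom.pattern_regions, d["phantom"]["pattern_regions"]):
            rd["center"] = list(r.center)
        return d

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def _phantom_from_dict(d: dict) -> PhantomSpec:
    regions = tuple(
        PatternRegion(tuple(r["center"]), float(r["extent"]), float(r["fill_fraction"]))
        for r in d.get("pattern_regions", [])
    )
    kwargs = {k: v for k, v in d.items() if k != "pattern_regions"}
    if regions:
        kwargs["pattern_regions"] = regions
    return PhantomSpec(**kwargs)


def _scanner_from_dict(d: dict) -> ScannerProfile:
    d = dict(d)
    d["kvp_contrast_scale"] = {float(k): float(v) for k, v in d["kvp_contrast_scale"].items()}
    d["filter_levels"] = tuple(int(v) for v in d["filter_levels"])
    d["settings_matrix"] = {k: tuple(float(x) for x in v) for k, v in d["settings_matrix"].items()}
    return ScannerProfile(**d)


def config_from_dict(d: dict) -> PipelineConfig:
    return PipelineConfig(
        phantom=_phantom_from_dict(d.get("phantom", {})),
        scanners=tuple(_scanner_from_dict(s) for s in d["scanners"]),
        rois=tuple(
            SphereROIDef(r["label"], tuple(r["center"]), float(r["radius"]))
            for r in d["rois"]
        ),
        analysis=AnalysisParams(**d.get("analysis", {})),
        master_seed=int(d.get("master_seed", 0)),
        output_dir=str(d.get("output_dir", "study_out")),
    )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_config(master_seed: int = 0) -> PipelineConfig:
    """The shipped full-matrix configuration: three spherical ROIs centred on
    the three texture patterns."""
    spec = PhantomSpec()
    rois = tuple(
        SphereROIDef(f"roi{i + 1}", region.center, 20.0)
        for i, region in enumerate(spec.pattern_regions)
    )
    return PipelineConfig(
        phantom=spec,
        scanners=default_profiles(),
        rois=rois,
        master_seed=master_seed,
    )


def fast_config(master_seed: int = 0) -> PipelineConfig:
    """Reduced profile for quick runs: 64x64 reconstruction grid, 2x phantom
    supersampling, and trimmed filter-level and tube-current lists (first and
    last value of each)."""
    cfg = default_config(master_seed)
    cfg = replace(cfg, phantom=replace(cfg.phantom, supersample_factor=2))
    scanners = []
    for s in cfg.scanners:
        matrix = dict(s.settings_matrix)
        matrix["ma"] = (matrix["ma"][0], matrix["ma"][-1])
        scanners.append(
            replace(
                s,
                matrix_size=64,
                filter_levels=(s.filter_levels[0], s.filter_levels[-1]),
                settings_matrix=matrix,
            )
        )
    return replace(cfg, scanners=tuple(scanners))


def noise_free_config(master_seed: int = 0) -> PipelineConfig:
    """A degenerate configuration for full-pipeline determinism checks.

    Noise and filtering are disabled and every parameter family's value list
    collapses to the baseline value, so all acquisitions of a scanner are
    voxel-identical: every PAD is exactly zero and every feature is reliable.
    Uses the reduced reconstruction grid.
    """
    cfg = fast_config(master_seed)
    scanners = []
    for s in cfg.scanners:
        base = s.baseline
        scanners.append(
            replace(
                s,
                noise_sigma_ref=0.0,
                filter_levels=(0,),
                settings_matrix={
                    "slice_thickness": (base["slice_thickness"],),
                    "fov": (base["fov"],),
                    "kvp": (base["kvp"],),
                    "ma": (base["ma"],),
                },
            )
        )
    return replace(cfg, scanners=tuple(scanners))


def shipped_default_path() -> Path:
    """Path of the packaged default configuration file."""
    return Path(resources.files("phantex").joinpath("data/default_config.yaml"))
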