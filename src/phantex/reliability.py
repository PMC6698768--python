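"""Percent-absolute-difference reliability framework.

A feature's instability between two acquisitions is its percent absolute
difference, PAD = |test - baseline| / |baseline|.  Three comparisons are
made per scanner:

* repeatability - each setting's scan vs. its 15-minute re-scan;
* robustness    - the baseline scan vs. each one-factor-varied setting,
  grouped by the varied parameter family;
* reproducibility - consistency of the above across the two scanners,
  operationalized as the conjunction rule of :func:`reliable_set`.

Percent-repeatable / percent-robust tallies use a PAD cutoff of 0.15; a
feature is *reliable* when every one of its repeatability and robustness
PADs on both scanners stays within the 5% band.  Comparisons are computed
per ROI and never pooled across ROIs; tallies are reported both pooled and
per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .texture import FEATURE_NAMES

TALLY_CUTOFF = 0.15
RELIABLE_BAND = 0.05
CLIP_MAX = 0.20
_EPS = 1e-12

RECORD_COLUMNS = [
    "scanner_id", "comparison_kind", "parameter_family", "setting_id",
    "roi_label", "feature_name", "family", "baseline_value", "test_value",
    "pad",
]


def pad(test: float, baseline: float) -> float:
    """Percent absolute difference |test - baseline| / |baseline|.

    Zero-baseline guard: a feature that is (numerically) zero under both
    conditions carries no instability signal and gets PAD 0; a nonzero test
    value against a zero baseline is infinitely unstable (PAD inf).
    """
    if np.isnan(test) or np.isnan(baseline):
        raise ValueError("PAD inputs must not be NaN")
    if abs(baseline) < _EPS:
        return 0.0 if abs(test) < _EPS else np.inf
    return abs(test - baseline) / abs(baseline)


def pad_array(test: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Vectorized :func:`pad`."""
    test = np.asarray(test, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.isnan(test).any() or np.isnan(baseline).any():
        raise ValueError("PAD inputs must not be NaN")
    zero_base = np.abs(baseline) < _EPS
    out = np.empty_like(test)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(test - baseline) / np.abs(baseline)
    out[zero_base] = np.where(np.abs(test[zero_base]) < _EPS, 0.0, np.inf)
    return out


def _require_columns(features: pd.DataFrame) -> None:
    needed = {"scanner_id", "setting_id", "varied_parameter", "repeat_index",
              "roi_label", "feature_name", "family", "value"}
    missing = needed - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")


TALLY_COLUMNS = ["scanner_id", "comparison_kind", "parameter_family",
                 "roi_label", "n_comparisons", "n_within", "fraction"]


def _tally(records: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Fraction of comparisons with PAD <= cutoff.

    Reported at three levels per scanner and comparison kind: pooled over
    everything (family and ROI marked ``all``), per parameter family pooled
    over ROIs, and per family per ROI.
    """
    if records.empty:
        return pd.DataFrame(columns=TALLY_COLUMNS)
    rows = []
    groupings = (
        ["scanner_id", "comparison_kind"],
        ["scanner_id", "comparison_kind", "parameter_family"],
        ["scanner_id", "comparison_kind", "parameter_family", "roi_label"],
    )
    for keys in groupings:
        for key_vals, grp in records.groupby(keys, sort=True):
            row = dict(zip(keys, key_vals))
            row.setdefault("parameter_family", "all")
            row.setdefault("roi_label", "all")
            row["n_comparisons"] = len(grp)
            row["n_within"] = int((grp["pad"] <= cutoff).sum())
            row["fraction"] = row["n_within"] / row["n_comparisons"]
            rows.append(row)
    return pd.DataFrame(rows)[TALLY_COLUMNS]


def repeatability_table(
    features: pd.DataFrame, cutoff: float = TALLY_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test-retest comparisons: repeat 0 vs. the 15-min re-scan (repeat 1).

    One record per (scanner, setting, ROI, feature); the tally is the
    fraction of records with PAD <= cutoff per scanner (the per-family rows
    break the same records down by the setting's varied parameter).
    """
    _require_columns(features)
    keys = ["scanner_id", "setting_id", "varied_parameter", "roi_label",
            "feature_name", "family"]
    r0 = features[features["repeat_index"] == 0].set_index(keys)["value"]
    r1 = features[features["repeat_index"] == 1].set_index(keys)["value"]
    only0 = r0.index.difference(r1.index)
    only1 = r1.index.difference(r0.index)
    if len(only0) or len(only1):
        missing = list(only0[:5]) + list(only1[:5])
        raise ValueError(f"unmatched test-retest pairs, e.g. {missing}")
    r1 = r1.reindex(r0.index)
    records = r0.index.to_frame(index=False)
    records["comparison_kind"] = "repeatability"
    records["parameter_family"] = records["varied_parameter"].replace(
        {"baseline": "none"}
    )
    records["baseline_value"] = r0.to_numpy()
    records["test_value"] = r1.to_numpy()
    records["pad"] = pad_array(records["test_value"], records["baseline_value"])
    records = records[RECORD_COLUMNS]
    return records, _tally(records, cutoff)


def robustness_table(
    features: pd.DataFrame, cutoff: float = TALLY_CUTOFF
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-factor-at-a-time comparisons against the baseline scan.

    Uses repeat-0 scans only; every non-baseline setting is compared with the
    scanner's baseline setting per ROI and feature, grouped by the varied
    parameter family.
    """
    _require_columns(features)
    f0 = features[features["repeat_index"] == 0]
    records_parts = []
    for scanner, grp in f0.groupby("scanner_id", sort=True):
        base = grp[grp["varied_parameter"] == "baseline"]
        if base.empty:
            raise ValueError(f"scanner {scanner!r}: no baseline setting in table")
        base_vals = base.set_index(["roi_label", "feature_name"])["value"]
        varied = grp[grp["varied_parameter"] != "baseline"].copy()
        idx = pd.MultiIndex.from_frame(varied[["roi_label", "feature_name"]])
        varied["baseline_value"] = base_vals.reindex(idx).to_numpy()
        if varied["baseline_value"].isna().any():
            raise ValueError(f"scanner {scanner!r}: baseline missing ROI/feature rows")
        varied["comparison_kind"] = "robustness"
        varied["parameter_family"] = varied["varied_parameter"]
        varied["test_value"] = varied["value"]
        varied["pad"] = pad_array(varied["test_value"], varied["baseline_value"])
        records_parts.append(varied[RECORD_COLUMNS])
    records = pd.concat(records_parts, ignore_index=True)
    return records, _tally(records, cutoff)


@dataclass
class ReliabilityReport:
    """Per-feature reliability verdicts and per-family tallies."""

    per_feature: pd.DataFrame  # flags per feature
    family_tallies: pd.DataFrame
    reliable_features: list[str]
    band: float = RELIABLE_BAND
    cutoff: float = TALLY_CUTOFF
    scanners: tuple[str, ...] = field(default_factory=tuple)


def reliable_set(
    records: pd.DataFrame,
    band: float = RELIABLE_BAND,
    cutoff: float = TALLY_CUTOFF,
) -> ReliabilityReport:
    """Identify reliable features from pooled repeatability and robustness
    records of both scanners.

    Per scanner a feature is *repeatable* (resp. *robust*) when all its
    repeatability (robustness) PADs are within the band; it is *reliable*
    exactly when it is repeatable and robust on both scanners — the
    cross-scanner reproducibility conjunction.
    """
    scanners = tuple(sorted(records["scanner_id"].unique()))
    if len(scanners) != 2:
        raise ValueError(f"reliable_set expects records from 2 scanners, got {scanners}")
    per_kind = (
        records.groupby(["feature_name", "scanner_id", "comparison_kind"])["pad"]
        .max()
        .unstack(["scanner_id", "comparison_kind"])
    )
    per_feature = pd.DataFrame(index=per_kind.index)
    for s in scanners:
        rep = per_kind.get((s, "repeatability"))
        rob = per_kind.get((s, "robustness"))
        per_feature[f"max_pad_repeat_{s}"] = rep
        per_feature[f"max_pad_robust_{s}"] = rob
        per_feature[f"repeatable_{s}"] = (rep <= band) if rep is not None else False
        per_feature[f"robust_{s}"] = (rob <= band) if rob is not None else False
    rep_both = np.logical_and.reduce(
        [per_feature[f"repeatable_{s}"] for s in scanners]
    )
    rob_both = np.logical_and.reduce([per_feature[f"robust_{s}"] for s in scanners])
    per_feature["reproducible"] = rep_both & rob_both
    per_feature["reliable"] = per_feature["reproducible"]
    fam = records.drop_duplicates("feature_name").set_index("feature_name")["family"]
    per_feature.insert(0, "family", fam.reindex(per_feature.index))
    per_feature = per_feature.reindex(
        [n for n in FEATURE_NAMES if n in per_feature.index]
        + [n for n in per_feature.index if n not in FEATURE_NAMES]
    )
    reliable = per_feature.index[per_feature["reliable"]].tolist()
    return ReliabilityReport(
        per_feature=per_feature,
        family_tallies=_tally(records, cutoff),
        reliable_features=reliable,
        band=band,
        cutoff=cutoff,
        scanners=scanners,
    )


def filter_effect_contrast(
    records: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Per-filter-level robustness contrast against the unfiltered baseline.

    For each scanner and exposed filter level: the mean PAD across features
    and ROIs, a paired sign-test p-value against zero change (fraction of
    strictly positive PADs under a fair-coin null), and for each scanner a
    rank-correlation (Kendall tau) trend of mean PAD versus level.
    """
    filt = records[
        (records["comparison_kind"] == "robustness")
        & (records["parameter_family"] == "filter")
    ]
    if filt.empty:
        return pd.DataFrame(
            columns=["scanner_id", "filter_level", "n", "mean_pad",
                     "sign_test_p", "trend_tau", "trend_p"]
        )
    levels = manifest.drop_duplicates("setting_id").set_index("setting_id")["filter_level"]
    filt = filt.assign(filter_level=levels.reindex(filt["setting_id"]).to_numpy())
    rows = []
    for (scanner, level), grp in filt.groupby(["scanner_id", "filter_level"]):
        finite = grp["pad"].replace(np.inf, np.nan).dropna()
        n_pos = int((grp["pad"] > 0).sum())
        p = sps.binomtest(n_pos, len(grp), 0.5, alternative="greater").pvalue
        rows.append({
            "scanner_id": scanner,
            "filter_level": int(level),
            "n": len(grp),
            "mean_pad": float(finite.mean()) if len(finite) else np.nan,
            "sign_test_p": float(p),
        })
    out = pd.DataFrame(rows).sort_values(["scanner_id", "filter_level"])
    for scanner, grp in out.groupby("scanner_id"):
        if len(grp) >= 2 and grp["mean_pad"].notna().all():
            tau, p = sps.kendalltau(grp["filter_level"], grp["mean_pad"])
        else:
            tau, p = np.nan, np.nan
        out.loc[out["scanner_id"] == scanner, "trend_tau"] = tau
        out.loc[out["scanner_id"] == scanner, "trend_p"] = p
    return out.reset_index(drop=True)


def heatmap_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Feature-by-setting PAD matrix (mean over ROIs), features in canonical
    order, settings grouped by parameter family."""
    mat = records.pivot_table(
        index="feature_name", columns=["parameter_family", "setting_id"],
        values="pad", aggfunc="mean", sort=True,
    )
    order = [n for n in FEATURE_NAMES if n in mat.index]
    order += [n for n in mat.index if n not in FEATURE_NAMES]
    return mat.reindex(order)


def heatmap_export(
    records: pd.DataFrame,
    out_dir: str | Path,
    clip_max: float = CLIP_MAX,
    band: float = RELIABLE_BAND,
) -> list[Path]:
    """Write one PAD heatmap per (scanner, comparison kind).

    The CSV holds the unclipped matrix; the PNG renders values clipped to
    [0, clip_max] on a blue-to-red scale with the reliable band marked on the
    colorbar.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if records.empty:
        raise ValueError("no comparison records to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (scanner, kind), grp in records.groupby(["scanner_id", "comparison_kind"]):
        mat = heatmap_matrix(grp)
        csv_path = out_dir / f"heatmap_{scanner}_{kind}.csv"
        mat.to_csv(csv_path)
        written.append(csv_path)

        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.25 * mat.shape[1] + 2), 8.0), constrained_layout=True
        )
        img = ax.imshow(
            np.clip(mat.to_numpy(dtype=float), 0.0, clip_max),
            aspect="auto", cmap="coolwarm", vmin=0.0, vmax=clip_max,
            interpolation="nearest",
        )
        ax.set_title(f"{kind} PAD, scanner {scanner}")
        ax.set_xlabel("setting (grouped by varied parameter)")
        ax.set_ylabel("feature (canonical order)")
        ax.set_xticks(range(mat.shape[1]))
        ax.set_xticklabels([c[1] for c in mat.columns], rotation=90, fontsize=5)
        cbar = fig.colorbar(img, ax=ax, label="percent absolute difference")
        cbar.ax.axhline(band, color="k", linewidth=1.5)
        cbar.set_ticks(sorted({0.0, band, 0.10, 0.15, clip_max}))
        png_path = out_dir / f"heatmap_{scanner}_{kind}.png"
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
        written.append(png_path)
    return written
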