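"""End-to-end orchestration: simulate → quantify → stats as reproducible,
configured runs.

``run_quantify`` walks a manifest CSV of multi-page TIFFs, segments each
field of view, measures every surviving droplet and emits one long-format
measurements table plus a QC report.  ``run_stats`` applies the outlier
filter, optional carrier-control normalization and the test battery
appropriate to the design (two arms → paired/nested t; multi-group → ANOVA
with Tukey HSD).  Given a config and seed, every output is deterministic.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import imaging, quantify, stats, synthgen
from .imaging import (
    MicrotissueImage,
    NucleusDetectionParams,
    PreprocessParams,
    SegmentationParams,
    ViabilityParams,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StatsDesign",
    "QuantifyResult",
    "quantify_image",
    "run_quantify",
    "run_stats",
    "run_simulate",
    "recovery_report",
]


def _dataclass_from_dict(cls, data: dict, path: str = ""):
    """Build a (possibly nested) dataclass from a dict, rejecting unknown
    keys so config typos fail loudly."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise KeyError(
            f"unknown config keys {sorted(unknown)} under {path or cls.__name__!r}; "
            f"allowed: {sorted(fields)}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = _NESTED.get((cls, name))
        if target is not None and isinstance(value, dict):
            kwargs[name] = _dataclass_from_dict(target, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Resolved parameters of one quantification run.

    Every parameter has a default; unknown keys in a config file are
    rejected.  The fully resolved config is written next to the outputs.
    """

    manifest: str | None = None
    output_dir: str = "microquant_out"
    pixel_size_um: float = 1.0
    segment_on: list | None = None  # channel names; None = all non-nuclei
    marker_channel: str = "marker"
    nuclei_channel: str = "nuclei"
    live_channel: str = "live"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    nuclei: NucleusDetectionParams = field(default_factory=NucleusDetectionParams)
    viability: ViabilityParams = field(default_factory=ViabilityParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _dataclass_from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_NESTED = {
    (RunConfig, "preprocess"): PreprocessParams,
    (RunConfig, "segmentation"): SegmentationParams,
    (RunConfig, "nuclei"): NucleusDetectionParams,
    (RunConfig, "viability"): ViabilityParams,
}


@dataclass
class StatsDesign:
    """What to test: metrics, grouping factors and the control level."""

    metrics: list = field(default_factory=lambda: ["normalized_intensity_per_cell", "area_um2"])
    group_col: str = "condition"
    control_level: str | None = None
    replicate_col: str | None = None
    patient_col: str | None = None
    remove_outliers: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "StatsDesign":
        return _dataclass_from_dict(cls, data)


@dataclass
class QuantifyResult:
    measurements: pd.DataFrame
    qc: dict


# ---------------------------------------------------------------------------
# per-image measurement
# ---------------------------------------------------------------------------

def quantify_image(image: MicrotissueImage, config: RunConfig | None = None) -> list:
    """Measure every droplet in one field of view.

    Segmentation runs on the preprocessed maximum projection of the
    non-nuclear channels (droplet outlines are visible in the matrix/marker
    stains); intensity quantification always reads the raw marker channel.
    Returns a list of :class:`~microquant.quantify.DropletMeasurement`.
    """
    config = config or RunConfig()
    seg_names = config.segment_on
    if seg_names is None:
        seg_names = [c for c in image.channels if c != config.nuclei_channel]
        if not seg_names:
            seg_names = list(image.channels)
    seg_channel = np.max(
        np.stack([np.asarray(image.channel(c), float) for c in seg_names]), axis=0
    )
    corrected = imaging.preprocess(seg_channel, config.preprocess)
    masks = imaging.segment_droplets(
        corrected, image.pixel_size_um, config.segmentation
    )

    meta = image.metadata
    base_id = str(meta.get("droplet_id", "droplet"))
    marker = image.channels.get(config.marker_channel)
    nuclei = image.channels.get(config.nuclei_channel)
    live = image.channels.get(config.live_channel)

    measurements = []
    for k, mask in enumerate(masks):
        droplet_id = base_id if len(masks) == 1 else f"{base_id}.{k + 1}"
        flags = []
        if len(masks) > 1:
            flags.append("multi_droplet_fov")
        if mask.area_px < 10:
            flags.append("tiny_mask")

        cell_count, centroids = 0, np.empty((0, 2))
        if nuclei is not None:
            cell_count, centroids = imaging.count_nuclei(nuclei, mask, config.nuclei)

        meas = quantify.DropletMeasurement(
            droplet_id=droplet_id,
            condition=str(meta.get("condition", "")),
            dose_uM=float(meta.get("dose_uM", 0.0)),
            timepoint_days=float(meta.get("timepoint_days", 0.0)),
            patient_id=str(meta.get("patient_id", "")),
            replicate=int(meta.get("replicate", 1)),
            area_um2=mask.area_um2,
            equiv_diameter_um=mask.equiv_diameter_um,
            circularity=mask.circularity,
            cell_count=int(cell_count),
            qc_flags=flags,
        )
        if marker is not None:
            meas.mean_intensity = quantify.mean_intensity(marker, mask)
            meas.background_p10 = quantify.background_p10(marker, mask)
            if cell_count >= 1:
                meas.normalized_intensity_per_cell = (
                    quantify.normalized_intensity_per_cell(
                        meas.mean_intensity, meas.background_p10, cell_count
                    )
                )
            else:
                flags.append("zero_cells")
        if live is not None and cell_count >= 1:
            viab = imaging.classify_viability(live, centroids, config.viability)
            meas.live_fraction = viab.live_fraction
            if viab.used_fallback:
                flags.append("viability_fallback_threshold")
        measurements.append(meas)
    return measurements


# ---------------------------------------------------------------------------
# manifest-driven runs
# ---------------------------------------------------------------------------

def _parse_channel_map(spec: str) -> dict:
    """``"nuclei:0;marker:1;live:2"`` → {"nuclei": 0, ...}"""
    out = {}
    for part in str(spec).split(";"):
        name, _, idx = part.partition(":")
        if not idx:
            raise ValueError(f"malformed channel_map entry {part!r}")
        out[name.strip()] = int(idx)
    return out


def load_image(row, manifest_dir: Path, config: RunConfig) -> MicrotissueImage:
    """Load one manifest row into a :class:`MicrotissueImage`."""
    path = Path(row["image_path"])
    if not path.is_absolute():
        path = manifest_dir / path
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    cmap = _parse_channel_map(row.get("channel_map", "marker:0"))
    channels = {name: stack[idx] for name, idx in cmap.items()}
    bit_depth = 8 if stack.dtype == np.uint8 else 16
    return MicrotissueImage(
        channels=channels,
        pixel_size_um=float(row.get("pixel_size_um", config.pixel_size_um)),
        bit_depth=bit_depth,
        metadata={
            k: row[k]
            for k in (
                "droplet_id",
                "condition",
                "dose_uM",
                "timepoint_days",
                "patient_id",
                "replicate",
            )
            if k in row
        },
    )


def run_quantify(
    config: RunConfig,
    images: list | None = None,
    write: bool = True,
) -> QuantifyResult:
    """Measure every droplet referenced by the manifest (or an in-memory
    image list) and write ``measurements.csv``, ``qc.json`` and the
    resolved config snapshot.

    Unreadable images are skipped and reported in the QC block; the run
    continues.  An empty manifest is an error.
    """
    qc: dict = {"images": 0, "droplets": 0, "skipped": [], "flag_counts": {}}
    all_meas = []
    if images is None:
        if config.manifest is None:
            raise ValueError("run_quantify needs a manifest path or images")
        manifest = pd.read_csv(config.manifest)
        if manifest.empty:
            raise ValueError(f"manifest {config.manifest} is empty")
        manifest_dir = Path(config.manifest).parent
        for _, row in manifest.iterrows():
            try:
                image = load_image(row, manifest_dir, config)
            except (OSError, ValueError, KeyError) as exc:
                logger.warning("skipping %s: %s", row.get("image_path"), exc)
                qc["skipped"].append(
                    {"image_path": str(row.get("image_path")), "error": str(exc)}
                )
                continue
            all_meas.extend(quantify_image(image, config))
            qc["images"] += 1
    else:
        for image in images:
            all_meas.extend(quantify_image(image, config))
            qc["images"] += 1

    table = quantify.build_cohort_table(all_meas)
    qc["droplets"] = int(len(table))
    flat = [f for m in all_meas for f in m.qc_flags]
    qc["flag_counts"] = {f: flat.count(f) for f in sorted(set(flat))}

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "measurements.csv", index=False)
        with open(out / "qc.json", "w") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True)
        with open(out / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return QuantifyResult(measurements=table, qc=qc)


# ---------------------------------------------------------------------------
# statistics runs
# ---------------------------------------------------------------------------

def run_stats(measurements: pd.DataFrame, design: StatsDesign) -> dict:
    """Run the outlier filter, optional control normalization and the test
    battery for every requested metric; returns a JSON-serializable report.

    Two groups with a patient factor (>= 2 patients per group) use the
    nested t; two groups with a replicate factor use the paired t on
    per-replicate condition means; two plain groups use an unpaired Student
    t; three or more groups use one-way ANOVA with Tukey HSD.
    """
    report: dict = {"design": dataclasses.asdict(design), "metrics": {}}
    gcol = design.group_col
    if gcol not in measurements.columns:
        raise KeyError(f"group column {gcol!r} not in measurements")
    levels = list(pd.unique(measurements[gcol]))

    for metric in design.metrics:
        if metric not in measurements.columns:
            raise KeyError(f"metric column {metric!r} not in measurements")
        sub = measurements[measurements[metric].notna()].copy()
        block: dict = {"outliers_removed": {}, "groups": {}, "tests": []}

        # 3-SD outlier filter, independently per group, before normalization
        if design.remove_outliers:
            keep_idx = []
            for level, grp in sub.groupby(gcol, sort=False):
                res = stats.remove_outliers(grp[metric].to_numpy())
                removed = grp.index.to_numpy()[res.removed_indices]
                block["outliers_removed"][str(level)] = int(removed.size)
                keep_idx.extend(set(grp.index) - set(removed))
            sub = sub.loc[sorted(keep_idx)]

        value_col = metric
        if design.control_level is not None:
            sub = stats.normalize_to_control(
                sub,
                metric,
                design.control_level,
                group_col=gcol,
                replicate_col=design.replicate_col,
            )
            value_col = f"{metric}_fold"

        for level, grp in sub.groupby(gcol, sort=False):
            vals = grp[value_col].to_numpy()
            summary = {"n": int(vals.size), "mean": float(np.mean(vals))}
            if vals.size >= 2:
                _, lo, hi = stats.mean_ci95(vals)
                summary["ci95"] = [lo, hi]
            block["groups"][str(level)] = summary

        results: list[stats.StatsResult] = []
        present = [lv for lv in levels if (sub[gcol] == lv).any()]
        if len(present) == 2:
            a_lv, b_lv = present
            if (
                design.patient_col is not None
                and design.patient_col in sub.columns
                and sub.groupby(gcol)[design.patient_col].nunique().min() >= 2
            ):
                results.append(
                    stats.nested_t_test(sub, value_col, gcol, design.patient_col)
                )
            elif (
                design.replicate_col is not None
                and sub[design.replicate_col].nunique() >= 2
            ):
                per_rep = (
                    sub.groupby([design.replicate_col, gcol])[value_col]
                    .mean()
                    .unstack(gcol)
                    .dropna()
                )
                results.append(
                    stats.paired_t_test(
                        per_rep[a_lv], per_rep[b_lv], groups=(a_lv, b_lv)
                    )
                )
            else:
                results.append(
                    stats.two_sample_t_test(
                        sub.loc[sub[gcol] == a_lv, value_col],
                        sub.loc[sub[gcol] == b_lv, value_col],
                        groups=(a_lv, b_lv),
                    )
                )
        elif len(present) >= 3:
            groups = {
                str(lv): sub.loc[sub[gcol] == lv, value_col].to_numpy()
                for lv in present
            }
            anova, pairs = stats.anova_tukey(groups)
            results.append(anova)
            results.extend(pairs)
        else:
            logger.warning("metric %s: fewer than 2 groups, no test run", metric)

        block["tests"] = [r.to_dict() for r in results]
        report["metrics"][metric] = block
    return report


def write_stats_report(report: dict, out_dir) -> None:
    """Emit the stats report as JSON plus a flat per-test summary CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    rows = []
    for metric, block in report["metrics"].items():
        for t in block["tests"]:
            rows.append(
                {
                    "metric": metric,
                    "test": t["test_name"],
                    "groups": " vs ".join(map(str, t["groups"])),
                    "n": ",".join(map(str, t["n"])),
                    "statistic": t["statistic"],
                    "df": t["df"],
                    "p_value": t["p_value"],
                    "adjusted": t["adjusted"],
                    "stars": t["stars"],
                }
            )
    pd.DataFrame(rows).to_csv(out / "stats_summary.csv", index=False)


# ---------------------------------------------------------------------------
# simulation + recovery
# ---------------------------------------------------------------------------

def run_simulate(
    config: synthgen.GeneratorConfig,
    design,
    out_dir,
) -> synthgen.Cohort:
    """Thin wrapper over :func:`microquant.synthgen.generate_cohort` that
    always writes images, manifest and ground truth to ``out_dir``."""
    return synthgen.generate_cohort(config, design, out_dir=out_dir)


def recovery_report(measurements: pd.DataFrame, ground_truth: pd.DataFrame) -> dict:
    """Measured-vs-truth error summary per condition.

    Reports mean relative area error, mean absolute cell-count error, the
    live-fraction error, and the per-cell-intensity fold of each condition
    against the first (in both measured and true values).
    """
    merged = measurements.merge(ground_truth, on="droplet_id", suffixes=("", "_gt"))
    if merged.empty:
        raise ValueError("no droplets shared between measurements and ground truth")
    out: dict = {"conditions": {}}
    cond_col = "condition" if "condition" in merged.columns else "condition_gt"
    for level, grp in merged.groupby(cond_col, sort=False):
        entry = {
            "n": int(len(grp)),
            "area_rel_err": float(
                np.mean(
                    (grp["area_um2"] - grp["true_area_um2"]) / grp["true_area_um2"]
                )
            ),
            "count_mae": float(
                np.mean(np.abs(grp["cell_count"] - grp["true_cell_count"]))
            ),
        }
        if grp["live_fraction"].notna().any():
            entry["live_fraction_err"] = float(
                np.nanmean(grp["live_fraction"] - grp["true_live_fraction"])
            )
        entry["mean_normalized_intensity"] = float(
            np.nanmean(grp["normalized_intensity_per_cell"])
        )
        entry["true_mean_normalized_intensity"] = float(
            np.nanmean(grp["true_normalized_intensity"])
        )
        out["conditions"][str(level)] = entry
    conds = list(out["conditions"])
    if len(conds) >= 2:
        ref = out["conditions"][conds[0]]
        out["fold_vs_first"] = {
            c: {
                "measured": out["conditions"][c]["mean_normalized_intensity"]
                / ref["mean_normalized_intensity"],
                "true": out["conditions"][c]["true_mean_normalized_intensity"]
                / ref["true_mean_normalized_intensity"],
            }
            for c in conds[1:]
        }
    return out
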