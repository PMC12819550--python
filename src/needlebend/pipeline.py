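"""End-to-end pipeline: simulate -> reconstruct -> analyze -> report.

Every stage's output is persisted under the output directory and a manifest
records the full configuration, the seed and content hashes of all products,
so any number in the report is regenerable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import serialize
from .geometry import SegmentFrame, analyze_bending, spacing_deviation
from .phantom import CohortConfig, generate_cohort
from .reconstruct import flag_merged, reconstruct_needle
from .stats import bin_table, compare_paths, histogram, path_from_curve, threshold_counts
from .volume import save_nifti

logger = logging.getLogger("needlebend")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline; defaults match the clinical constants

    (600 HU threshold, 30 x 30 mm search window, 2 mm slices, 1 cm line-fit
    extent, 9 mm first-dwell offset, 0.5-unit histogram bins).
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    threshold_hu: float = 600.0
    window_mm: float = 30.0
    weighted_centroid: bool = True
    fit_extent_mm: float = 10.0
    dwell_offset_mm: float = 9.0
    length_edges: tuple[float, ...] = (100.0, 120.0, 140.0, 160.0, 180.0, 200.0, 220.0)
    hist_bin_width: float = 0.5
    deviation_thresholds: tuple[float, ...] = (1.0, 5.0, 10.0)
    seed: int = 0
    write_volumes: bool = True

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        cohort = CohortConfig(**data.pop("cohort", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=cohort, **data)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _hash_file(path: str) -> str:
    with open(path, "rb") as fh:
        return _sha256(fh.read())


def run_pipeline(config: PipelineConfig, out_dir: str | os.PathLike) -> dict:
    """Run all stages on a synthetic cohort and write the report artifacts.

    Returns the manifest dict (also written to ``manifest.json``): config,
    seed, per-stage products and their content hashes.  Merged needles (not
    separable by thresholding) are excluded from the analysis and counted.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    cohort = generate_cohort(config.cohort, config.seed)

    manifest: dict = {"config": config.to_dict(), "seed": config.seed, "hashes": {}, "stages": {}}
    all_metrics = []
    all_spacing = []
    recon_vs_truth = []
    n_merged = 0
    all_paths_flat = []

    for p_idx, (volume, truth, template) in enumerate(cohort):
        tag = f"phantom_{p_idx:03d}"
        manifest["hashes"][f"{tag}/volume"] = _sha256(
            np.ascontiguousarray(volume.voxels).tobytes()
            + np.asarray(volume.spacing).tobytes()
            + volume.origin.tobytes()
        )
        if config.write_volumes:
            save_nifti(volume, os.path.join(out_dir, f"{tag}.nii"))
        truth_file = os.path.join(out_dir, f"{tag}_truth.json")
        serialize.truth_to_json(truth, truth_file)
        manifest["hashes"][f"{tag}/truth"] = _hash_file(truth_file)

        truth_paths = [
            path_from_curve(c, dz=volume.spacing[0], z0=volume.origin[0], needle_id=i)
            for i, c in enumerate(truth.curves)
        ]
        paths = []
        for i, tp in enumerate(truth_paths):
            path = reconstruct_needle(
                volume,
                tp.points[0],
                template,
                nominal_length=truth.specs[i].nominal_length,
                window_mm=config.window_mm,
                threshold_hu=config.threshold_hu,
                weighted=config.weighted_centroid,
                fit_extent_mm=config.fit_extent_mm,
                needle_id=i,
            )
            logger.debug(
                "%s needle %d: %d slices, terminated %s, bridged %s, truncated %s",
                tag, i, len(path.points), path.termination_reason,
                path.bridged_interval, path.truncated,
            )
            paths.append(path)
        flag_merged(paths)
        paths_file = os.path.join(out_dir, f"{tag}_paths.json")
        serialize.paths_to_json(paths, paths_file)
        serialize.paths_to_csv(paths, os.path.join(out_dir, f"{tag}_paths.csv"))
        manifest["hashes"][f"{tag}/paths"] = _hash_file(paths_file)
        all_paths_flat.append((paths, truth_paths, truth))

        frame = None
        if truth.probe_axis is not None:
            frame = SegmentFrame.from_probe(truth.probe_axis)
        usable = [p for p in paths if not p.merged]
        n_merged += len(paths) - len(usable)
        for path in usable:
            all_metrics.append(analyze_bending(path, frame=frame, fit_extent_mm=config.fit_extent_mm))
            tp = truth_paths[path.needle_id]
            detected = _detected_only(path)
            if detected is not None:
                recon_vs_truth.extend(compare_paths(detected, tp).distances)
        by_x = sorted(usable, key=lambda p: p.points[-1, 2])
        for a, c, b in zip(by_x, by_x[1:], by_x[2:]):
            try:
                all_spacing.append(spacing_deviation(c, a, b, offset_mm=config.dwell_offset_mm))
            except ValueError:
                logger.debug("%s: spacing trio around needle %s skipped", tag, c.needle_id)

    metrics_df = serialize.bending_to_dataframe(all_metrics)
    spacing_df = serialize.spacing_to_dataframe(all_spacing)
    metrics_df.to_csv(os.path.join(out_dir, "bending_metrics.csv"), index=False)
    spacing_df.to_csv(os.path.join(out_dir, "spacing_metrics.csv"), index=False)

    table = bin_table(metrics_df, length_edges=config.length_edges)
    table.to_csv(os.path.join(out_dir, "bending_table.csv"), index=False)
    hists = []
    for col, unit in (("db_long", "mm"), ("db_trans", "mm"), ("alpha_deg", "deg")):
        h = histogram(metrics_df[col].to_numpy(), config.hist_bin_width)
        h.insert(0, "metric", col)
        h.insert(1, "unit", unit)
        hists.append(h)
    if len(spacing_df):
        h = histogram(spacing_df["de_trans"].to_numpy(), config.hist_bin_width)
        h.insert(0, "metric", "de_trans")
        h.insert(1, "unit", "mm")
        hists.append(h)
    hist_df = pd.concat(hists, ignore_index=True)
    hist_df.to_csv(os.path.join(out_dir, "histograms.csv"), index=False)
    counts = threshold_counts(metrics_df["db_total"].to_numpy(), config.deviation_thresholds)
    counts.to_csv(os.path.join(out_dir, "threshold_counts.csv"), index=False)

    report_lines = _report_text(metrics_df, spacing_df, recon_vs_truth, n_merged, counts)
    report_file = os.path.join(out_dir, "report.txt")
    with open(report_file, "w") as fh:
        fh.write("\n".join(report_lines) + "\n")

    for name in ("bending_metrics.csv", "spacing_metrics.csv", "bending_table.csv",
                 "histograms.csv", "threshold_counts.csv", "report.txt"):
        manifest["hashes"][name] = _hash_file(os.path.join(out_dir, name))
    manifest["stages"] = {
        "simulate": {"n_phantoms": len(cohort)},
        "reconstruct": {"n_needles": int(sum(len(p) for p, _, _ in all_paths_flat)),
                        "n_merged": n_merged},
        "analyze": {"n_bending": len(all_metrics), "n_spacing": len(all_spacing)},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    logger.info("pipeline complete: %d needles analyzed, %d merged, %d trios",
                len(all_metrics), n_merged, len(all_spacing))
    return manifest


def _detected_only(path):
    """The path restricted to detected (non-bridged) points, if any remain."""
    from .reconstruct import NeedlePath, _inside_bridge

    keep = np.array([not _inside_bridge(path, z) for z in path.points[:, 0]])
    if keep.sum() < 1:
        return None
    return NeedlePath(points=path.points[keep], source=path.source, needle_id=path.needle_id)


def _report_text(metrics_df, spacing_df, recon_vs_truth, n_merged, counts) -> list[str]:
    from .stats import summarize

    lines = ["needlebend cohort report", "=" * 40]
    if recon_vs_truth:
        s = summarize(recon_vs_truth)
        lines.append(
            f"reconstruction vs truth (per-slice, {s.n} points): "
            f"median {s.median:.3f} +- {s.iqr:.3f} mm (range {s.min:.3f}-{s.max:.3f})"
        )
    lines.append(f"needles analyzed: {len(metrics_df)}; merged and excluded: {n_merged}")
    for col, unit in (("db_total", "mm"), ("db_trans", "mm"), ("db_long", "mm"), ("alpha_deg", "deg")):
        s = summarize(metrics_df[col].to_numpy())
        lines.append(f"{col}: median {s.median:.2f} +- {s.iqr:.2f} {unit} "
                     f"(range {s.min:.2f}-{s.max:.2f})")
    for _, row in counts.iterrows():
        lines.append(f"tip deviation > {row['threshold']:g} mm: "
                     f"{int(row['count'])} needles ({int(row['percent'])}%)")
    if len(spacing_df):
        s = summarize(spacing_df["de_trans"].to_numpy())
        lines.append(f"de_trans (spacing, {s.n} trios): median {s.median:.2f} +- {s.iqr:.2f} mm "
                     f"(range {s.min:.2f}-{s.max:.2f})")
    return lines
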