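"""JSON / CSV serialization of paths, truth and metrics.

JSON carries full float precision (Python's repr round-trips IEEE doubles
exactly), so serialized paths re-read identical to machine precision.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .geometry import BendingMetrics, SpacingMetrics
from .phantom import PhantomTruth
from .reconstruct import NeedlePath

__all__ = [
    "paths_to_json",
    "paths_from_json",
    "paths_to_csv",
    "paths_from_csv",
    "truth_to_json",
    "bending_to_dataframe",
    "spacing_to_dataframe",
]


def _path_record(path: NeedlePath) -> dict:
    return {
        "needle_id": path.needle_id,
        "points": path.points.tolist(),
        "nominal_length": path.nominal_length,
        "truncated": bool(path.truncated),
        "bridged_interval": list(path.bridged_interval) if path.bridged_interval else None,
        "source": path.source,
        "merged": bool(path.merged),
        "termination_reason": path.termination_reason,
    }


def _path_from_record(rec: dict) -> NeedlePath:
    return NeedlePath(
        points=np.array(rec["points"], dtype=float),
        nominal_length=rec.get("nominal_length"),
        truncated=rec.get("truncated", False),
        bridged_interval=tuple(rec["bridged_interval"]) if rec.get("bridged_interval") else None,
        source=rec.get("source", "semi_auto"),
        merged=rec.get("merged", False),
        termination_reason=rec.get("termination_reason", ""),
        needle_id=rec.get("needle_id"),
    )


def paths_to_json(paths: list[NeedlePath], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump([_path_record(p) for p in paths], fh, sort_keys=True)


def paths_from_json(path: str | os.PathLike) -> list[NeedlePath]:
    with open(path) as fh:
        return [_path_from_record(rec) for rec in json.load(fh)]


def paths_to_csv(paths: list[NeedlePath], path: str | os.PathLike) -> None:
    """Flat per-point CSV: needle_id, slice_index, z/y/x mm, bridged, source."""
    rows = []
    for p in paths:
        for k, pt in enumerate(p.points):
            bridged = (
                p.bridged_interval is not None
                and p.bridged_interval[0] - 1e-9 <= pt[0] <= p.bridged_interval[1] + 1e-9
            )
            rows.append(
                {
                    "needle_id": p.needle_id,
                    "slice_index": k,
                    "z_mm": pt[0],
                    "y_mm": pt[1],
                    "x_mm": pt[2],
                    "bridged": bridged,
                    "source": p.source,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def paths_from_csv(path: str | os.PathLike) -> list[NeedlePath]:
    """Rebuild paths from the flat CSV (bridged intervals from the flags)."""
    df = pd.read_csv(path, float_precision="round_trip")
    paths = []
    for nid, grp in df.groupby("needle_id", dropna=False, sort=True):
        grp = grp.sort_values("slice_index")
        pts = grp[["z_mm", "y_mm", "x_mm"]].to_numpy(dtype=float)
        bz = grp.loc[grp["bridged"].astype(bool), "z_mm"].to_numpy()
        interval = (float(bz.min()), float(bz.max())) if len(bz) else None
        paths.append(
            NeedlePath(
                points=pts,
                bridged_interval=interval,
                source=str(grp["source"].iloc[0]),
                needle_id=None if pd.isna(nid) else int(nid),
            )
        )
    return paths


def truth_to_json(truth: PhantomTruth, path: str | os.PathLike) -> None:
    payload = {
        "seed": truth.seed,
        "truncation_mm": truth.truncation_mm.tolist(),
        "probe_axis": None if truth.probe_axis is None else truth.probe_axis.tolist(),
        "curves": [c.points.tolist() for c in truth.curves],
        "specs": [
            {
                "nominal_length": s.nominal_length,
                "insertion_point": s.insertion_point.tolist(),
                "entry_direction": s.entry_direction.tolist(),
                "straight_extent": s.straight_extent,
                "arc_angle_deg": s.arc_angle_deg,
                "bend_azimuth_deg": s.bend_azimuth_deg,
                "air_overhang": s.air_overhang,
                "needle_radius": s.needle_radius,
                "needle_hu": s.needle_hu,
            }
            for s in truth.specs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def bending_to_dataframe(metrics: list[BendingMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "needle_id": m.needle_id,
            "needle_length": m.needle_length,
            "reconstructed_length": m.reconstructed_length,
            "alpha_deg": m.alpha_deg,
            "db_total": m.db_total,
            "db_trans": m.db_trans,
            "db_long": m.db_long,
            "segment": m.segment,
            "truncated": m.truncated,
        }
        for m in metrics
    )


def spacing_to_dataframe(metrics: list[SpacingMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "center_id": m.center_id,
            "neighbor_A_id": m.neighbor_A_id,
            "neighbor_B_id": m.neighbor_B_id,
            "e_A": m.e_A,
            "e_B": m.e_B,
            "de_trans": m.de_trans,
            "dwell_slice_z": m.dwell_slice_z,
        }
        for m in metrics
    )
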