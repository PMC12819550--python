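"""Descriptive evaluation machinery: per-slice path comparisons, median/IQR
summaries, length-binned tables, fixed-width histograms and threshold counts.

Reporting conventions: median with the interquartile range as a single width
(Q3 - Q1, linear interpolation between order statistics), total range as
(min, max), length bins left-open/right-closed (a 120 mm needle belongs to
the 100-120 mm bin), and histograms with 0.5-unit bins starting at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import NeedleCurve
from .reconstruct import NeedlePath

__all__ = [
    "SummaryStats",
    "PathComparison",
    "summarize",
    "compare_paths",
    "path_from_curve",
    "intra_observer_protocol",
    "bin_table",
    "histogram",
    "threshold_counts",
]

DEFAULT_LENGTH_EDGES = (100.0, 120.0, 140.0, 160.0, 180.0, 200.0, 220.0)


@dataclass
class SummaryStats:
    n: int
    median: float
    iqr: float
    min: float
    max: float


@dataclass
class PathComparison:
    """Per-slice Euclidean distances between two reconstructions of a needle."""

    per_slice: list[tuple[float, float]]  # (z, distance mm)
    summary: SummaryStats
    pair_kind: str  # auto_vs_manual | repeat_vs_repeat | recon_vs_truth

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for _, d in self.per_slice])


def summarize(values) -> SummaryStats:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return SummaryStats(
        n=int(values.size),
        median=float(med),
        iqr=float(q3 - q1),
        min=float(values.min()),
        max=float(values.max()),
    )


def compare_paths(A: NeedlePath, B: NeedlePath, pair_kind: str = "recon_vs_truth",
                  z_tol: float = 1e-6) -> PathComparison:
    """Per-slice Euclidean distance between two paths on their shared slices.

    Points on the same slice share z, so the 3D distance equals the in-plane
    distance.  Fails when the paths share no slice.
    """
    za = A.points[:, 0]
    per_slice = []
    for pb in B.points:
        i = int(np.argmin(np.abs(za - pb[0])))
        if abs(za[i] - pb[0]) <= z_tol:
            d = A.points[i] - pb
            per_slice.append((float(pb[0]), float(np.sqrt(np.sum(d * d)))))
    if not per_slice:
        raise ValueError("paths share no axial slice")
    return PathComparison(
        per_slice=per_slice,
        summary=summarize([d for _, d in per_slice]),
        pair_kind=pair_kind,
    )


def path_from_curve(curve: NeedleCurve, dz: float = 2.0, z0: float | None = None,
                    needle_id: int | None = None) -> NeedlePath:
    """Sample an analytic truth curve at slice centers into a per-slice path."""
    zs = curve.points[:, 0]
    z_start = zs[0] if z0 is None else z0 + dz * np.ceil((zs[0] - z0) / dz)
    z_grid = np.arange(z_start, zs[-1] + 1e-9, dz)
    pts = np.array([[z, *curve.yx_at_z(z)] for z in z_grid])
    return NeedlePath(points=pts, nominal_length=curve.spec.nominal_length,
                      source="truth", needle_id=needle_id)


def intra_observer_protocol(
    truth_paths: list[NeedlePath],
    jitter_sigma: float = 0.1,
    repeats: int = 3,
    seed: int = 0,
) -> list[PathComparison]:
    """Emulate repeated manual reconstructions and their pairwise variability.

    Each needle is "reconstructed" ``repeats`` times by adding isotropic
    in-plane Gaussian click noise (sigma ``jitter_sigma`` mm in y and x) to
    every slice point; all pairwise per-slice distances between the repeats
    are returned, one comparison per (needle, pair).
    """
    rng = np.random.default_rng(seed)
    out = []
    for path in truth_paths:
        reps = []
        for _ in range(repeats):
            pts = path.points.copy()
            pts[:, 1:] += rng.normal(0.0, jitter_sigma, size=pts[:, 1:].shape)
            reps.append(NeedlePath(points=pts, nominal_length=path.nominal_length,
                                   source="manual", needle_id=path.needle_id))
        for i in range(repeats):
            for j in range(i + 1, repeats):
                out.append(compare_paths(reps[i], reps[j], pair_kind="repeat_vs_repeat"))
    return out


def bin_table(
    metrics: pd.DataFrame,
    length_column: str = "reconstructed_length",
    value_columns: tuple[str, ...] = ("db_total", "db_long", "db_trans", "alpha_deg"),
    length_edges: tuple[float, ...] = DEFAULT_LENGTH_EDGES,
) -> pd.DataFrame:
    """Length-binned median/IQR/range table (one row per bin plus "all").

    Length bins are left-open/right-closed (]100, 120], ...); needles outside
    every bin are collected in an explicit "outside" row rather than dropped.
    """
    if metrics.empty:
        raise ValueError("no metrics to tabulate")
    edges = list(length_edges)
    labels = [f"{int(a)}-{int(b)}" for a, b in zip(edges[:-1], edges[1:])]
    binned = pd.cut(metrics[length_column], bins=edges, right=True, labels=labels)
    rows = []

    def _row(name: str, sub: pd.DataFrame) -> dict:
        row: dict = {"length_bin": name, "n": len(sub)}
        for col in value_columns:
            if len(sub):
                s = summarize(sub[col].to_numpy())
                row.update({f"{col}_median": s.median, f"{col}_iqr": s.iqr,
                            f"{col}_min": s.min, f"{col}_max": s.max})
            else:
                row.update({f"{col}_median": np.nan, f"{col}_iqr": np.nan,
                            f"{col}_min": np.nan, f"{col}_max": np.nan})
        return row

    for lab in labels:
        rows.append(_row(lab, metrics[binned == lab]))
    outside = metrics[binned.isna()]
    if len(outside):
        rows.append(_row("outside", outside))
    rows.append(_row("all", metrics))
    return pd.DataFrame(rows)


def histogram(values, bin_width: float = 0.5) -> pd.DataFrame:
    """Fixed-width histogram with bins [0, w), [w, 2w), ... from zero."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty sample")
    if np.any(values < 0):
        raise ValueError("histogram expects non-negative values")
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    # np.histogram closes the last bin on the right; keep the maximum there
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def threshold_counts(values, thresholds=(1.0, 5.0, 10.0)) -> pd.DataFrame:
    """Counts and whole-percent fractions of values strictly above thresholds."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot count an empty sample")
    rows = []
    for t in thresholds:
        c = int(np.sum(values > t))
        rows.append({"threshold": t, "count": c, "percent": int(round(100.0 * c / values.size))})
    return pd.DataFrame(rows)
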