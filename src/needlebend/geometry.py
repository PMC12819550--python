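"""Bending and spacing geometry of reconstructed needles.

Bending is quantified against the straight course predicted from the distal
needle end: the most distal (free in air) 1 cm of a reconstructed needle is
fitted with a straight line and extrapolated by the known needle length to a
predicted tip T_e.  With C the vector from the most distal reconstruction
point to the actual tip T_n and E the vector to the predicted tip,

    alpha    = arccos( C.E / (|C| |E|) )          bending angle
    db_total = |T_n - T_e|                        total tip deviation
    db_trans = sin(alpha) * |C|                   transverse to the prediction
    db_long  = sqrt(db_total^2 - db_trans^2)      along the prediction

Spacing quality of a needle placed between two neighbors is the discrepancy
de_trans = |e_A - e_B| of its in-plane distances to them, measured in the
slice holding its first dwell position (9 mm from the tip by needle design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reconstruct import NeedlePath, fit_line

__all__ = [
    "BendingMetrics",
    "SpacingMetrics",
    "SegmentFrame",
    "predict_tip",
    "bending_angle",
    "tip_deviation",
    "analyze_bending",
    "assign_segment",
    "dwell_slice",
    "spacing_deviation",
]

DWELL_OFFSET_MM = 9.0  # first possible dwell position, from the tip


@dataclass
class BendingMetrics:
    """All bending quantities of one needle."""

    alpha_deg: float
    db_total: float
    db_trans: float
    db_long: float
    T_n: np.ndarray  # actual tip
    T_e: np.ndarray  # predicted tip
    C: np.ndarray  # distal point -> actual tip
    E: np.ndarray  # distal point -> predicted tip (straight course)
    needle_length: float
    reconstructed_length: float = float("nan")
    segment: int | None = None
    truncated: bool = False
    needle_id: int | None = None


@dataclass
class SpacingMetrics:
    """Equidistance discrepancy of a needle between two neighbors."""

    e_A: float
    e_B: float
    de_trans: float
    dwell_slice_z: float
    center_id: int | None = None
    neighbor_A_id: int | None = None
    neighbor_B_id: int | None = None


@dataclass
class SegmentFrame:
    """Six 60-degree anatomy sectors about the probe in the landmark slice.

    The landmark slice holds the longitudinal midpoint of the probe's caudal
    half.  Segment 1 is centered on anterior, segment 6 on posterior; sweeping
    from anterior toward ``right_yx`` passes segments 2 and 3, mirrored by 5
    and 4 on the opposite side.  The axis conventions are configurable and
    recorded here.
    """

    landmark_slice_z: float
    probe_center_yx: np.ndarray
    anterior_yx: np.ndarray = field(default_factory=lambda: np.array([-1.0, 0.0]))
    right_yx: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0]))
    #: sector order encountered sweeping from anterior toward right_yx
    sweep_order: tuple[int, ...] = (1, 2, 3, 6, 4, 5)

    def __post_init__(self) -> None:
        self.probe_center_yx = np.asarray(self.probe_center_yx, dtype=float)
        self.anterior_yx = np.asarray(self.anterior_yx, dtype=float)
        self.anterior_yx /= np.linalg.norm(self.anterior_yx)
        self.right_yx = np.asarray(self.right_yx, dtype=float)
        self.right_yx /= np.linalg.norm(self.right_yx)
        if sorted(self.sweep_order) != [1, 2, 3, 4, 5, 6]:
            raise ValueError("sweep_order must be a permutation of 1..6")

    @classmethod
    def from_probe(cls, probe_axis: np.ndarray, **kwargs) -> "SegmentFrame":
        """Frame at the midpoint of the caudal half of a probe segment."""
        a, b = np.asarray(probe_axis, dtype=float)
        if a[0] > b[0]:
            a, b = b, a
        mid = a + 0.5 * (b - a)  # longitudinal probe midpoint
        landmark = mid + 0.5 * (b - mid)  # midpoint of the caudal half
        return cls(landmark_slice_z=float(landmark[0]), probe_center_yx=landmark[1:], **kwargs)


def predict_tip(
    path: NeedlePath, needle_length: float, fit_extent_mm: float = 10.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Straight-course tip prediction from the most distal 1 cm of a path.

    Fits the most distal (caudal) 1 cm of the reconstruction — for needles the
    scan cut off, the most distal 1 cm actually recorded — with a straight
    line and extrapolates it by the known needle length from the most distal
    reconstruction point.  Returns ``(T_e, E, distal_point)`` with
    ``|E| = needle_length``.
    """
    if len(path.points) < 2:
        raise ValueError("need >= 2 distal points to predict the tip")
    line = fit_line(path.points, extent_mm=fit_extent_mm, end="caudal")
    distal = path.distal_point
    T_e = distal + needle_length * line.direction
    return T_e, T_e - distal, distal


def bending_angle(C: np.ndarray, E: np.ndarray) -> float:
    """Angle (degrees) between the actual chord C and the predicted course E."""
    C = np.asarray(C, dtype=float)
    E = np.asarray(E, dtype=float)
    nc, ne = np.linalg.norm(C), np.linalg.norm(E)
    if nc == 0 or ne == 0:
        raise ValueError("bending angle undefined for zero-length vectors")
    cos = np.clip(np.dot(C, E) / (nc * ne), -1.0, 1.0)
    return math.degrees(math.acos(cos))


def tip_deviation(T_n, T_e, C, E) -> tuple[float, float, float]:
    """Total / transverse / longitudinal tip deviation, by basic trigonometry."""
    T_n = np.asarray(T_n, dtype=float)
    T_e = np.asarray(T_e, dtype=float)
    alpha = math.radians(bending_angle(C, E))
    db_total = float(np.linalg.norm(T_n - T_e))
    db_trans = float(math.sin(alpha) * np.linalg.norm(C))
    db_long = math.sqrt(max(0.0, db_total**2 - db_trans**2))
    return db_total, db_trans, db_long


def analyze_bending(
    path: NeedlePath,
    needle_length: float | None = None,
    frame: SegmentFrame | None = None,
    fit_extent_mm: float = 10.0,
) -> BendingMetrics:
    """Full bending evaluation of one reconstructed needle.

    The actual tip T_n is the path's first (most cranial) point.  Truncated
    needles are still extrapolated by the full nominal length; the flag is
    carried over as a caveat on the metrics.
    """
    length = path.nominal_length if needle_length is None else needle_length
    if length is None:
        raise ValueError("needle length unknown: pass needle_length or set it on the path")
    T_e, E, distal = predict_tip(path, length, fit_extent_mm)
    T_n = path.tip
    C = T_n - distal
    alpha = bending_angle(C, E)
    db_total, db_trans, db_long = tip_deviation(T_n, T_e, C, E)
    return BendingMetrics(
        alpha_deg=alpha,
        db_total=db_total,
        db_trans=db_trans,
        db_long=db_long,
        T_n=T_n,
        T_e=T_e,
        C=C,
        E=E,
        needle_length=float(length),
        reconstructed_length=path.arc_length(),
        segment=None if frame is None else assign_segment(path, frame),
        truncated=path.truncated,
        needle_id=path.needle_id,
    )


def assign_segment(path: NeedlePath, frame: SegmentFrame) -> int | None:
    """Anatomy segment (1-6) the needle passes in the landmark slice.

    The needle's (y, x) in the landmark slice is mapped to the 60-degree
    sector (about the probe center) it falls in.  A point exactly on a sector
    boundary goes to the lower-numbered adjacent segment; a path that does not
    reach the landmark slice is unassigned (None).
    """
    p = path.point_at_z(frame.landmark_slice_z)
    if p is None:
        return None
    v = p[1:] - frame.probe_center_yx
    if np.linalg.norm(v) == 0:
        return frame.sweep_order[0]
    psi = math.degrees(math.atan2(np.dot(v, frame.right_yx), np.dot(v, frame.anterior_yx))) % 360.0
    t = (psi + 30.0) % 360.0
    idx = int(t // 60.0) % 6
    if abs(t % 60.0) < 1e-9 or abs(t % 60.0 - 60.0) < 1e-9:
        cand = (frame.sweep_order[idx], frame.sweep_order[(idx - 1) % 6])
        return min(cand)
    return frame.sweep_order[idx]


def dwell_slice(path: NeedlePath, offset_mm: float = DWELL_OFFSET_MM) -> float:
    """z of the slice containing the first possible dwell position.

    Walks the polyline from the tip accumulating arc length to ``offset_mm``
    and returns the z of the slice whose longitudinal interval
    ``(z - dz/2, z + dz/2]`` contains that point.
    """
    pts = path.points
    if offset_mm < 0:
        raise ValueError("offset must be >= 0")
    if offset_mm == 0:
        return float(pts[0, 0])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if offset_mm > cum[-1]:
        raise ValueError("path is shorter than the dwell offset")
    i = int(np.searchsorted(cum, offset_mm, side="left")) - 1
    i = max(0, min(i, len(seg) - 1))
    t = (offset_mm - cum[i]) / seg[i]
    zq = pts[i, 0] + t * (pts[i + 1, 0] - pts[i, 0])
    dz = path.dz()
    idx = math.ceil((zq - pts[0, 0]) / dz - 0.5)
    idx = max(0, min(idx, len(pts) - 1))
    return float(pts[0, 0] + idx * dz)


def spacing_deviation(
    center: NeedlePath,
    A: NeedlePath,
    B: NeedlePath,
    offset_mm: float = DWELL_OFFSET_MM,
) -> SpacingMetrics:
    """Equidistance discrepancy of ``center`` between neighbors ``A`` and ``B``.

    In the slice holding the center needle's first dwell position, the
    Euclidean distances e_A and e_B to the neighbors' reconstruction points
    are measured (same slice, hence in-plane); de_trans = |e_A - e_B|.
    """
    z = dwell_slice(center, offset_mm)
    pc = center.point_at_z(z)
    pa = A.point_at_z(z)
    pb = B.point_at_z(z)
    if pc is None or pa is None or pb is None:
        raise ValueError("all three needles need a reconstruction point in the dwell slice")
    e_a = float(np.linalg.norm(pc - pa))
    e_b = float(np.linalg.norm(pc - pb))
    return SpacingMetrics(
        e_A=e_a,
        e_B=e_b,
        de_trans=abs(e_a - e_b),
        dwell_slice_z=z,
        center_id=center.needle_id,
        neighbor_A_id=A.needle_id,
        neighbor_B_id=B.needle_id,
    )
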