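"""Semi-automated needle reconstruction on axial CT.

Starting from a clinically identified tip, the needle is tracked slice by
slice: in each adjacent axial slice, connected conglomerates of pixels with
CT number >= 600 HU are detected inside a 30 x 30 mm window around the
previous reconstruction point, and the conglomerate center nearest to that
point becomes the next reconstruction point.  Inside the template z-band,
metal artifacts make thresholding useless, so the most caudal 1 cm of the
already reconstructed section is fitted with a straight line and extrapolated
2 mm past the template's air-side face, from where tracking resumes until the
needle end (or the caudal scan border, for needles the scan range cut off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.measure import label, regionprops

from .phantom import TemplateRegion
from .volume import CTVolume

__all__ = [
    "NeedlePath",
    "StraightLineFit",
    "detect_conglomerates",
    "nearest_centroid",
    "trace",
    "fit_line",
    "bridge_template",
    "reconstruct_needle",
    "flag_merged",
]

DEFAULT_THRESHOLD_HU = 600.0
DEFAULT_WINDOW_MM = 30.0
DEFAULT_FIT_EXTENT_MM = 10.0


@dataclass
class NeedlePath:
    """An ordered per-slice needle reconstruction, tip first.

    ``points`` holds exactly one physical (z, y, x) point per axial slice the
    needle was followed through, with z strictly increasing (cranial tip to
    caudal end).  ``bridged_interval`` is the z-range whose points are
    straight-line extrapolations rather than detected centroids.
    """

    points: np.ndarray
    nominal_length: float | None = None
    truncated: bool = False
    bridged_interval: tuple[float, float] | None = None
    source: str = "semi_auto"  # semi_auto | manual | truth
    merged: bool = False
    termination_reason: str = ""
    needle_id: int | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3) (z, y, x)")
        if len(self.points) > 1 and not np.all(np.diff(self.points[:, 0]) > 0):
            raise ValueError("path z coordinates must be strictly increasing (tip first)")

    @property
    def tip(self) -> np.ndarray:
        return self.points[0]

    @property
    def distal_point(self) -> np.ndarray:
        return self.points[-1]

    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def dz(self) -> float:
        if len(self.points) < 2:
            raise ValueError("need >= 2 points to infer the slice spacing")
        return float(np.median(np.diff(self.points[:, 0])))

    def point_at_z(self, z: float, tol: float | None = None) -> np.ndarray | None:
        """The recorded point on the slice at ``z`` (within ``tol``), if any."""
        tol = (self.dz() / 2 if len(self.points) > 1 else 1.0) if tol is None else tol
        i = int(np.argmin(np.abs(self.points[:, 0] - z)))
        if abs(self.points[i, 0] - z) <= tol:
            return self.points[i]
        return None


@dataclass
class StraightLineFit:
    """Least-squares line through per-slice points, parameterised by z."""

    anchor: np.ndarray  # a point on the line (z, y, x)
    direction: np.ndarray  # unit vector, oriented caudal -> cranial (toward the tip)
    rms_residual: float
    n_points: int

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            self.direction = self.direction / n

    def at_z(self, z: float) -> np.ndarray:
        if abs(self.direction[0]) < 1e-12:
            raise ValueError("line is perpendicular to z and cannot be evaluated by slice")
        t = (z - self.anchor[0]) / self.direction[0]
        return self.anchor + t * self.direction


def detect_conglomerates(
    slice_hu: np.ndarray,
    pixel_y: np.ndarray,
    pixel_x: np.ndarray,
    center_yx,
    window_mm: float = DEFAULT_WINDOW_MM,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    weighted: bool = True,
) -> list[np.ndarray]:
    """Centers of >= threshold conglomerates inside a window around ``center_yx``.

    Connected components (8-connectivity) of pixels at or above the threshold
    are labelled inside the square window (side ``window_mm``, clipped at the
    image border).  With ``weighted`` (the default) each center is the
    background-subtracted intensity center of mass over the component dilated
    by one pixel: the dilation ring recovers partial-volume edge pixels that
    fall just below the threshold, which is what makes sub-voxel localisation
    possible; the background is the median of sub-threshold window pixels and
    negative excess weights are clipped to zero.  With ``weighted=False`` the
    unweighted binary centroid of the thresholded pixels is returned.
    Components touching the window edge are included as clipped.  Returns an
    empty list when nothing reaches the threshold — the caller decides whether
    that means the needle end or an artifact gap.
    """
    cy, cx = float(center_yx[0]), float(center_yx[1])
    half = window_mm / 2.0
    iy = np.nonzero((pixel_y >= cy - half) & (pixel_y <= cy + half))[0]
    ix = np.nonzero((pixel_x >= cx - half) & (pixel_x <= cx + half))[0]
    if len(iy) == 0 or len(ix) == 0:
        return []
    sub = slice_hu[iy[0] : iy[-1] + 1, ix[0] : ix[-1] + 1]
    mask = sub >= threshold_hu
    if not mask.any():
        return []
    labels = label(mask, connectivity=2)
    ys = pixel_y[iy[0] : iy[-1] + 1]
    xs = pixel_x[ix[0] : ix[-1] + 1]
    if weighted:
        below = sub[~mask]
        background = float(np.median(below)) if below.size else 0.0
        excess = np.clip(sub - background, 0.0, None)
    centers = []
    for region in regionprops(labels):
        if weighted:
            comp = labels == region.label
            support = binary_dilation(comp, structure=np.ones((3, 3), bool))
            # never borrow pixels that belong to another conglomerate
            support &= (labels == 0) | comp
            rr, cc = np.nonzero(support)
            w = excess[rr, cc]
            centers.append(np.array([np.average(ys[rr], weights=w),
                                     np.average(xs[cc], weights=w)]))
        else:
            rr = region.coords[:, 0]
            cc = region.coords[:, 1]
            centers.append(np.array([ys[rr].mean(), xs[cc].mean()]))
    return centers


def nearest_centroid(centroids, previous_yx) -> np.ndarray:
    """The centroid closest to ``previous_yx``; ties go to smaller y, then x."""
    if len(centroids) == 0:
        raise ValueError("no centroids to choose from")
    prev = np.asarray(previous_yx, dtype=float)
    keys = [
        (float(np.hypot(c[0] - prev[0], c[1] - prev[1])), float(c[0]), float(c[1]))
        for c in centroids
    ]
    return np.asarray(centroids[min(range(len(centroids)), key=lambda i: keys[i])], dtype=float)


@dataclass
class TraceResult:
    points: np.ndarray  # (N, 3), includes the start point
    reason: str  # "stop_z" | "volume_end" | "no_conglomerate"


def trace(
    volume: CTVolume,
    start_point,
    stop_z: float | None = None,
    window_mm: float = DEFAULT_WINDOW_MM,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    weighted: bool = True,
) -> TraceResult:
    """Track a needle caudally from ``start_point``, one slice at a time.

    Each step detects conglomerates in the next caudal slice around the
    previous point's (y, x) and takes the nearest center.  Tracking ends at
    ``stop_z`` (last slice with z <= stop_z), at the volume's caudal border,
    or when no conglomerate is found (needle end / artifact gap), and the
    reason is recorded.
    """
    start = np.asarray(start_point, dtype=float)
    k = volume.slice_index(start[0])
    pixel_y, pixel_x = volume.pixel_centers()
    points = [np.array([volume.slice_z(k), start[1], start[2]])]
    reason = "volume_end"
    while True:
        k += 1
        if k >= volume.shape[0]:
            reason = "volume_end"
            break
        z = volume.slice_z(k)
        if stop_z is not None and z > stop_z:
            reason = "stop_z"
            break
        prev = points[-1]
        centers = detect_conglomerates(
            volume.voxels[k], pixel_y, pixel_x, prev[1:], window_mm, threshold_hu, weighted
        )
        if not centers:
            reason = "no_conglomerate"
            break
        c = nearest_centroid(centers, prev[1:])
        points.append(np.array([z, c[0], c[1]]))
    return TraceResult(points=np.array(points), reason=reason)


def fit_line(
    points: np.ndarray,
    extent_mm: float = DEFAULT_FIT_EXTENT_MM,
    end: str = "caudal",
) -> StraightLineFit:
    """Least-squares straight line through the points nearest the chosen end.

    With one point per 2 mm slice, a 1 cm extent selects the five most extreme
    slices.  y and x are regressed on z (ordinary least squares); this is the
    natural parameterisation for per-slice points on a predominantly
    longitudinal needle.  The returned direction points caudal -> cranial.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ValueError("need at least 2 points to fit a line")
    order = np.argsort(pts[:, 0])
    pts = pts[order]
    if np.ptp(pts[:, 0]) == 0:
        raise ValueError("all points share one z; cannot parameterise by z")
    dz = float(np.median(np.abs(np.diff(pts[:, 0]))))
    n_sel = max(2, int(round(extent_mm / dz))) if dz > 0 else len(pts)
    sel = pts[-n_sel:] if end == "caudal" else pts[:n_sel]
    z = sel[:, 0]
    if np.ptp(z) == 0:
        raise ValueError("selected points share one z; cannot parameterise by z")
    A = np.column_stack([z, np.ones_like(z)])
    coef, *_ = np.linalg.lstsq(A, sel[:, 1:], rcond=None)
    resid = sel[:, 1:] - A @ coef
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    z0 = sel[-1, 0]
    anchor = np.array([z0, *(A[-1] @ coef)])
    direction = np.array([1.0, coef[0, 0], coef[0, 1]])
    direction /= np.linalg.norm(direction)
    if direction[0] > 0:  # orient toward the tip (decreasing z)
        direction = -direction
    return StraightLineFit(anchor=anchor, direction=direction, rms_residual=rms, n_points=len(sel))


def bridge_template(
    partial_points: np.ndarray,
    template: TemplateRegion,
    volume: CTVolume,
    margin_mm: float = 2.0,
    fit_extent_mm: float = DEFAULT_FIT_EXTENT_MM,
) -> tuple[np.ndarray, np.ndarray]:
    """Extrapolate a body-side partial path across the template artifact band.

    Fits the most caudal 1 cm of ``partial_points`` with a straight line and
    evaluates it on every slice from the one after the partial path through
    the slice nearest ``z_air_border + margin``.  Returns ``(seed, bridged)``:
    the extrapolated restart point on that air-side slice and the full array
    of bridged line points (seed included as its last row).
    """
    pts = np.atleast_2d(np.asarray(partial_points, dtype=float))
    line = fit_line(pts, extent_mm=fit_extent_mm, end="caudal")
    k_ex = volume.slice_index(template.z_air_border + margin_mm)
    k_from = volume.slice_index(pts[-1, 0]) + 1
    if k_from > k_ex:
        raise ValueError("partial path already extends past the template")
    bridged = np.array([line.at_z(volume.slice_z(k)) for k in range(k_from, k_ex + 1)])
    seed = bridged[-1]
    if not volume.contains_yx(seed[1], seed[2]):
        raise ValueError("extrapolated restart point exits the slice")
    return seed, bridged


def reconstruct_needle(
    volume: CTVolume,
    tip_seed,
    template: TemplateRegion,
    nominal_length: float | None = None,
    window_mm: float = DEFAULT_WINDOW_MM,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    weighted: bool = True,
    margin_mm: float = 2.0,
    fit_extent_mm: float = DEFAULT_FIT_EXTENT_MM,
    needle_id: int | None = None,
) -> NeedlePath:
    """Full tip-to-end reconstruction: trace, bridge the template, trace again.

    The body-side trace stops at the last slice at least ``margin_mm`` cranial
    of the template's body-side face; the artifact band (plus the 2 mm margins
    on both faces) is filled by straight-line extrapolation of the most caudal
    1 cm; tracking then resumes from the extrapolated air-side point until the
    needle end or the caudal scan border.  A path that hits the scan border
    before exhausting the nominal length is flagged ``truncated``.
    """
    tip_seed = np.asarray(tip_seed, dtype=float)
    first = trace(volume, tip_seed, stop_z=template.z_body_border - margin_mm,
                  window_mm=window_mm, threshold_hu=threshold_hu, weighted=weighted)
    points = first.points
    bridged_interval = None
    reason = first.reason
    if first.reason == "stop_z":
        seed, bridged = bridge_template(points, template, volume,
                                        margin_mm=margin_mm, fit_extent_mm=fit_extent_mm)
        second = trace(volume, seed, stop_z=None,
                       window_mm=window_mm, threshold_hu=threshold_hu, weighted=weighted)
        # the seed slice itself is a line point, not a detected centroid
        points = np.vstack([points, bridged, second.points[1:]])
        bridged_interval = (float(bridged[0, 0]), float(bridged[-1, 0]))
        reason = second.reason
    path = NeedlePath(
        points=points,
        nominal_length=nominal_length,
        bridged_interval=bridged_interval,
        source="semi_auto",
        termination_reason=reason,
        needle_id=needle_id,
    )
    if nominal_length is not None:
        dz = volume.spacing[0]
        path.truncated = reason == "volume_end" and path.arc_length() < nominal_length - dz
    return path


def flag_merged(paths: list[NeedlePath], tol: float = 1e-9) -> list[NeedlePath]:
    """Mark paths whose detected points coincide on any shared slice.

    Two needles whose disks merge into one conglomerate select the identical
    centroid, so coincident points (within ``tol``) on the same slice mean the
    courses are not separable by thresholding; both paths are flagged.
    """
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            a, b = paths[i], paths[j]
            for p in a.points:
                if _inside_bridge(a, p[0]) or _inside_bridge(b, p[0]):
                    continue
                q = b.point_at_z(p[0], tol=1e-6)
                if q is not None and np.hypot(p[1] - q[1], p[2] - q[2]) <= tol:
                    a.merged = True
                    b.merged = True
                    break
    return paths


def _inside_bridge(path: NeedlePath, z: float) -> bool:
    if path.bridged_interval is None:
        return False
    lo, hi = path.bridged_interval
    return lo - 1e-9 <= z <= hi + 1e-9
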