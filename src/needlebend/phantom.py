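"""Synthetic CT phantoms of bent brachytherapy needles with analytic truth.

The generator emulates the imaging situation of combined intracavitary /
interstitial gynecologic brachytherapy: titanium needles (very high HU)
inserted through a guidance template toward cranial, an intrauterine probe
(moderate HU, invisible to needle thresholding), soft-tissue background
noise, and a template z-band ruined by metal artifacts.  Needle bending is
modelled as a single-plane circular arc of the inserted section — a minimal
one-parameter shape whose chord/tangent geometry has closed forms, so every
downstream measurement can be checked against exact analytic truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .volume import CTVolume

__all__ = [
    "NeedleCurveSpec",
    "TemplateRegion",
    "NeedleCurve",
    "PhantomTruth",
    "CohortConfig",
    "make_needle_curve",
    "rasterize",
    "generate_cohort",
]

#: needles below this HU cannot be seen by the reconstruction threshold
MIN_VISIBLE_HU = 600.0
#: titanium needles cannot bend tighter than this radius of curvature (mm)
DEFAULT_MIN_BEND_RADIUS = 50.0


@dataclass(frozen=True)
class NeedleCurveSpec:
    """Generative parameters of one needle.

    The needle is parameterised from its distal end (caudal, hanging in air)
    to its tip (cranial, in tissue): a straight run of ``straight_extent`` mm
    covering the free-air part, the template and an optional proximal stretch,
    followed by a circular arc of total turning angle ``arc_angle_deg`` over
    the remaining length.  ``insertion_point`` is where the needle crosses the
    template's air-side face; ``air_overhang`` mm of the straight run protrude
    caudally beyond it.
    """

    nominal_length: float  # mm
    insertion_point: np.ndarray  # (z, y, x) mm at the template air-side face
    entry_direction: np.ndarray  # unit vector pointing toward the tip (cranial)
    straight_extent: float  # mm of distal straight section
    arc_angle_deg: float = 0.0  # total bending angle of the inserted arc
    bend_azimuth_deg: float = 0.0  # orientation of the bending plane
    air_overhang: float = 40.0  # mm protruding caudally past the template
    needle_radius: float = 0.8  # mm
    needle_hu: float = 3000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "insertion_point", np.asarray(self.insertion_point, dtype=float))
        d = np.asarray(self.entry_direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise ValueError("entry_direction must be non-zero")
        object.__setattr__(self, "entry_direction", d / n)
        if self.arc_angle_deg < 0:
            raise ValueError("arc_angle_deg must be >= 0")
        if not (0 <= self.bend_azimuth_deg < 360):
            raise ValueError("bend_azimuth_deg must lie in [0, 360)")
        if not (0 < self.straight_extent <= self.nominal_length):
            raise ValueError("straight_extent must lie in (0, nominal_length]")
        if not (0 <= self.air_overhang < self.straight_extent):
            raise ValueError("air_overhang must lie in [0, straight_extent)")
        if self.needle_hu < MIN_VISIBLE_HU:
            raise ValueError(
                f"needle_hu = {self.needle_hu} is below {MIN_VISIBLE_HU} HU and would be "
                "invisible to threshold-based reconstruction"
            )

    @property
    def arc_length(self) -> float:
        """Length of the bent (constant-curvature) section in mm."""
        return self.nominal_length - self.straight_extent


@dataclass(frozen=True)
class TemplateRegion:
    """The z-band occupied by the guidance template.

    ``z_body_border`` is the cranial (body-sided) face, ``z_air_border`` the
    caudal (air-sided) face; inside, metal artifacts defeat HU thresholding.
    """

    z_body_border: float
    z_air_border: float
    artifact_hu_range: tuple[float, float] = (600.0, 3000.0)
    artifact_density: float = 0.3

    def __post_init__(self) -> None:
        if self.z_air_border <= self.z_body_border:
            raise ValueError("air-side border must be caudal (larger z) of the body-side border")
        if not (0 <= self.artifact_density <= 1):
            raise ValueError("artifact_density must lie in [0, 1]")

    @property
    def thickness(self) -> float:
        return self.z_air_border - self.z_body_border


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to d (and each other), deterministically."""
    a = np.array([0.0, 1.0, 0.0]) if abs(d[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = a - np.dot(a, d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


@dataclass
class NeedleCurve:
    """Densely sampled analytic needle centerline, ordered tip-first."""

    points: np.ndarray  # (N, 3) physical (z, y, x) mm, z strictly increasing
    spec: NeedleCurveSpec

    @property
    def tip(self) -> np.ndarray:
        return self.points[0]

    @property
    def distal_end(self) -> np.ndarray:
        return self.points[-1]

    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def yx_at_z(self, z: float) -> np.ndarray | None:
        """In-plane intersection of the curve with the axial plane at ``z``."""
        zs = self.points[:, 0]
        # tolerance keeps endpoints that land exactly on a slice plane
        if z < zs[0] - 1e-9 or z > zs[-1] + 1e-9:
            return None
        y = np.interp(z, zs, self.points[:, 1])
        x = np.interp(z, zs, self.points[:, 2])
        return np.array([y, x])

    def point_at_arclength(self, s: float) -> np.ndarray:
        """Point at arc length ``s`` measured from the tip."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if s < 0 or s > cum[-1]:
            raise ValueError("arc length outside the curve")
        i = int(np.searchsorted(cum, s, side="right")) - 1
        i = min(i, len(seg) - 1)
        t = (s - cum[i]) / seg[i]
        return self.points[i] + t * (self.points[i + 1] - self.points[i])

    def clipped_to_zmax(self, z_max: float) -> "NeedleCurve":
        """Drop the distal part beyond ``z_max`` (scan-range truncation)."""
        keep = self.points[:, 0] <= z_max
        if keep.sum() < 2:
            raise ValueError("clipping would remove the entire curve")
        return NeedleCurve(points=self.points[keep], spec=self.spec)


@dataclass
class PhantomTruth:
    """Exact generative record of one phantom: the recovery oracle."""

    curves: list[NeedleCurve]
    specs: list[NeedleCurveSpec]
    probe_axis: np.ndarray | None  # (2, 3) segment, cranial point first
    truncation_mm: np.ndarray  # per-needle distal cut-off, mm
    seed: int


def make_needle_curve(
    spec: NeedleCurveSpec,
    step: float = 0.1,
    min_bend_radius: float = DEFAULT_MIN_BEND_RADIUS,
) -> NeedleCurve:
    """Sample the analytic centerline of a needle at arc-length steps ≤ ``step``.

    The curve starts at the distal end (``insertion_point`` minus the air
    overhang), runs straight for ``straight_extent`` mm along the entry
    direction, then follows a circular arc of angle ``arc_angle_deg`` in the
    plane selected by ``bend_azimuth_deg``, ending at the tip.  Total arc
    length equals the nominal needle length to within 0.01 mm.
    """
    d = spec.entry_direction
    theta = math.radians(spec.arc_angle_deg)
    L_arc = spec.arc_length
    if theta > 0 and L_arc > 0:
        radius = L_arc / theta
        if radius < min_bend_radius:
            raise ValueError(
                f"bend radius {radius:.1f} mm below the physical minimum {min_bend_radius} mm"
            )
    p0 = spec.insertion_point - spec.air_overhang * d

    n = max(2, int(math.ceil(spec.nominal_length / step)) + 1)
    s = np.linspace(0.0, spec.nominal_length, n)
    pts = np.empty((n, 3))
    straight = s <= spec.straight_extent
    pts[straight] = p0[None, :] + s[straight, None] * d[None, :]

    if not np.all(straight):
        e1, e2 = _perp_basis(d)
        phi = math.radians(spec.bend_azimuth_deg)
        u = math.cos(phi) * e1 + math.sin(phi) * e2
        sb = s[~straight] - spec.straight_extent
        pb = p0 + spec.straight_extent * d
        if theta == 0:
            pts[~straight] = pb[None, :] + sb[:, None] * d[None, :]
        else:
            kappa = theta / L_arc
            r = 1.0 / kappa
            pts[~straight] = (
                pb[None, :]
                + r * np.sin(kappa * sb)[:, None] * d[None, :]
                + r * (1.0 - np.cos(kappa * sb))[:, None] * u[None, :]
            )

    pts = pts[::-1]  # tip first
    if not np.all(np.diff(pts[:, 0]) > 0):
        raise ValueError("needle curve is not monotone in z; reduce tilt or bending")
    return NeedleCurve(points=pts, spec=spec)


def _paint_disk(slice_hu, y_centers, x_centers, y, x, radius, hu, supersample: int = 4):
    """Paint a disk with partial-volume rendering.

    Each pixel gets ``(1 - c) * old + c * hu`` where ``c`` is the fraction of
    the pixel footprint covered by the disk (estimated on a supersampled
    grid).  This emulates the partial-volume effect of real CT, where pixels
    straddling the metal edge take intermediate HU; ``supersample=1`` falls
    back to hard binary painting.
    """
    dy = y_centers[1] - y_centers[0]
    dx = x_centers[1] - x_centers[0]
    if (
        y - radius < y_centers[0] - dy / 2
        or y + radius > y_centers[-1] + dy / 2
        or x - radius < x_centers[0] - dx / 2
        or x + radius > x_centers[-1] + dx / 2
    ):
        raise ValueError("needle disk exits the grid laterally")
    i0 = max(0, int(np.floor((y - radius - y_centers[0]) / dy)))
    i1 = min(len(y_centers), int(np.ceil((y + radius - y_centers[0]) / dy)) + 1)
    j0 = max(0, int(np.floor((x - radius - x_centers[0]) / dx)))
    j1 = min(len(x_centers), int(np.ceil((x + radius - x_centers[0]) / dx)) + 1)
    if supersample <= 1:
        yy = y_centers[i0:i1, None] - y
        xx = x_centers[None, j0:j1] - x
        mask = yy**2 + xx**2 <= radius**2
        slice_hu[i0:i1, j0:j1][mask] = hu
        return
    off = (np.arange(supersample) + 0.5) / supersample - 0.5
    yy = (y_centers[i0:i1, None] + off[None, :] * dy).reshape(-1) - y
    xx = (x_centers[j0:j1, None] + off[None, :] * dx).reshape(-1) - x
    inside = (yy[:, None] ** 2 + xx[None, :] ** 2 <= radius**2).reshape(
        i1 - i0, supersample, j1 - j0, supersample
    )
    cov = inside.mean(axis=(1, 3))
    patch = slice_hu[i0:i1, j0:j1]
    slice_hu[i0:i1, j0:j1] = patch * (1.0 - cov) + hu * cov


def rasterize(
    truth: PhantomTruth,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (2.0, 0.3, 0.3),
    origin=(0.0, 0.0, 0.0),
    template: TemplateRegion | None = None,
    noise_sigma: float = 20.0,
    tissue_hu: float = 40.0,
    probe_hu: float = 300.0,
    probe_radius: float = 3.0,
    distractors: tuple = (),
    supersample: int = 4,
    rng: np.random.Generator | None = None,
) -> CTVolume:
    """Render a phantom truth into an HU voxel grid.

    Each axial slice a needle crosses gets a disk of ``needle_radius`` at
    ``needle_hu`` centered on the analytic curve/plane intersection, rendered
    with partial-volume coverage at the disk edge (see ``_paint_disk``).  The
    background is soft tissue ``N(tissue_hu, noise_sigma)``; the probe is a
    sub-threshold cylinder; inside the template band a fraction
    ``artifact_density`` of pixels is replaced by HU drawn uniformly from
    ``artifact_hu_range``, which makes thresholding unreliable exactly there.
    ``distractors`` are ``(center_zyx, radius_mm, hu)`` calcification spheres.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    nz, ny, nx = shape
    dz, dy, dx = spacing
    origin = np.asarray(origin, dtype=float)
    if noise_sigma > 0:
        voxels = rng.normal(tissue_hu, noise_sigma, size=shape)
    else:
        voxels = np.full(shape, tissue_hu, dtype=float)
    z_centers = origin[0] + dz * np.arange(nz)
    y_centers = origin[1] + dy * np.arange(ny)
    x_centers = origin[2] + dx * np.arange(nx)

    if truth.probe_axis is not None:
        a, b = truth.probe_axis
        for k, zc in enumerate(z_centers):
            if min(a[0], b[0]) <= zc <= max(a[0], b[0]):
                t = 0.0 if b[0] == a[0] else (zc - a[0]) / (b[0] - a[0])
                p = a + t * (b - a)
                _paint_disk(voxels[k], y_centers, x_centers, p[1], p[2], probe_radius, probe_hu)

    for center, radius, hu in distractors:
        center = np.asarray(center, dtype=float)
        for k, zc in enumerate(z_centers):
            h = radius**2 - (zc - center[0]) ** 2
            if h > 0:
                _paint_disk(voxels[k], y_centers, x_centers, center[1], center[2], math.sqrt(h), hu)

    disk_log: dict[int, list[tuple[float, float, float]]] = {}
    for curve in truth.curves:
        r = curve.spec.needle_radius
        for k, zc in enumerate(z_centers):
            yx = curve.yx_at_z(zc)
            if yx is None:
                continue
            for oy, ox, orad in disk_log.get(k, ()):
                if (yx[0] - oy) ** 2 + (yx[1] - ox) ** 2 < (r + orad) ** 2:
                    warnings.warn(
                        f"needle disks overlap in slice {k}: courses merge on CT",
                        stacklevel=2,
                    )
            _paint_disk(
                voxels[k], y_centers, x_centers, yx[0], yx[1], r,
                curve.spec.needle_hu, supersample,
            )
            disk_log.setdefault(k, []).append((yx[0], yx[1], r))

    if template is not None:
        lo, hi = template.artifact_hu_range
        in_band = (z_centers >= template.z_body_border) & (z_centers <= template.z_air_border)
        for k in np.nonzero(in_band)[0]:
            mask = rng.random((ny, nx)) < template.artifact_density
            voxels[k][mask] = rng.uniform(lo, hi, size=int(mask.sum()))

    return CTVolume(voxels=voxels, spacing=spacing, origin=origin)


@dataclass
class CohortConfig:
    """Study conditions for a generated phantom cohort.

    Defaults echo the clinical setting: 120–220 mm titanium needles, bending
    angles log-normal with median 1.8° and quartile width 1.1° clipped to the
    observed 0.1–6.6° range, ~7.4% of needles distally cut off by up to 16 mm,
    voxel grid 2 × 0.3 × 0.3 mm³, and a 15 mm template artifact band.
    """

    n_phantoms: int = 8
    needles_per_phantom: int = 6
    lengths: tuple[float, ...] = (120.0, 140.0, 160.0, 180.0, 200.0, 220.0)
    theta_mode: str = "lognormal"  # "lognormal" | "uniform" | "fixed"
    theta_median_deg: float = 1.8
    theta_sigma_log: float = 0.446
    theta_clip_deg: tuple[float, float] = (0.1, 6.6)
    theta_range_deg: tuple[float, float] = (0.5, 6.6)  # for "uniform"
    theta_fixed_deg: float = 0.0  # for "fixed"
    tilt_max_deg: float = 3.0  # entry tilt away from the z axis
    pitch_mm: float = 8.0  # template hole spacing along x
    air_overhang_mm: float = 40.0
    proximal_straight_mm: float = 8.0  # straight run body-side of the template
    template_thickness_mm: float = 15.0
    artifact_density: float = 0.3
    artifact_hu_range: tuple[float, float] = (600.0, 3000.0)
    needle_radius_mm: float = 0.8
    needle_hu: float = 3000.0
    noise_sigma: float = 20.0
    truncation_prob: float = 0.074
    truncation_max_mm: float = 16.0
    spacing: tuple[float, float, float] = (2.0, 0.3, 0.3)
    include_probe: bool = True
    probe_offset_y_mm: float = -10.0  # anterior of the needle row
    distractors_per_phantom: int = 0
    distractor_hu: float = 800.0
    distractor_clearance_mm: float = 5.0
    min_needle_clearance_mm: float = 2.2  # center-to-center, > 2 * radius

    def __post_init__(self) -> None:
        if self.needles_per_phantom < 1:
            raise ValueError("needles_per_phantom must be >= 1")
        if self.n_phantoms < 1:
            raise ValueError("n_phantoms must be >= 1")
        if self.theta_mode not in ("lognormal", "uniform", "fixed"):
            raise ValueError(f"unknown theta_mode {self.theta_mode!r}")
        if self.min_needle_clearance_mm <= 2 * self.needle_radius_mm:
            raise ValueError("min clearance must exceed the needle diameter")


def _sample_theta(config: CohortConfig, rng: np.random.Generator) -> float:
    if config.theta_mode == "fixed":
        return config.theta_fixed_deg
    if config.theta_mode == "uniform":
        lo, hi = config.theta_range_deg
        return float(rng.uniform(lo, hi))
    mu = math.log(config.theta_median_deg)
    theta = float(rng.lognormal(mu, config.theta_sigma_log))
    return float(np.clip(theta, *config.theta_clip_deg))


def _tilted_direction(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    tilt = math.radians(rng.uniform(0.0, config.tilt_max_deg))
    az = rng.uniform(0.0, 2 * math.pi)
    # toward cranial: negative z component
    return np.array([-math.cos(tilt), math.sin(tilt) * math.cos(az), math.sin(tilt) * math.sin(az)])


def _curves_separated(curves: list[NeedleCurve], clearance: float, dz: float) -> bool:
    if len(curves) < 2:
        return True
    z_lo = min(c.points[0, 0] for c in curves)
    z_hi = max(c.points[-1, 0] for c in curves)
    zs = np.arange(z_lo, z_hi + dz, dz / 2)
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            for z in zs:
                a = curves[i].yx_at_z(z)
                b = curves[j].yx_at_z(z)
                if a is not None and b is not None:
                    if np.hypot(a[0] - b[0], a[1] - b[1]) < clearance:
                        return False
    return True


def generate_cohort(
    config: CohortConfig, seed: int
) -> list[tuple[CTVolume, PhantomTruth, TemplateRegion]]:
    """Generate a reproducible cohort of phantoms with exact ground truth.

    Needles enter through template holes on a regular x-pitch row; per needle
    the nominal length, bending angle θ, bending azimuth φ and a small entry
    tilt are drawn from the configured distributions.  Placements whose curves
    would approach closer than the configured clearance are resampled; a
    config that cannot be placed raises.  Identical ``(config, seed)`` pairs
    produce bit-identical truth and volumes.
    """
    rng = np.random.default_rng(seed)
    dz, dy, dx = config.spacing
    max_len = max(config.lengths)
    z_entry = (max_len - config.air_overhang_mm) + 10.0  # air-side template face
    template = TemplateRegion(
        z_body_border=z_entry - config.template_thickness_mm,
        z_air_border=z_entry,
        artifact_hu_range=config.artifact_hu_range,
        artifact_density=config.artifact_density,
    )
    out = []
    for _ in range(config.n_phantoms):
        n = config.needles_per_phantom
        x_positions = (np.arange(n) - (n - 1) / 2) * config.pitch_mm
        specs: list[NeedleCurveSpec] = []
        curves: list[NeedleCurve] = []
        for i in range(n):
            length = float(rng.choice(config.lengths))
            straight = config.air_overhang_mm + config.template_thickness_mm + config.proximal_straight_mm
            placed = False
            for _attempt in range(60):
                spec = NeedleCurveSpec(
                    nominal_length=length,
                    insertion_point=np.array([z_entry, 0.0, x_positions[i]]),
                    entry_direction=_tilted_direction(config, rng),
                    straight_extent=straight,
                    arc_angle_deg=_sample_theta(config, rng),
                    bend_azimuth_deg=float(rng.uniform(0.0, 360.0)),
                    air_overhang=config.air_overhang_mm,
                    needle_radius=config.needle_radius_mm,
                    needle_hu=config.needle_hu,
                )
                curve = make_needle_curve(spec)
                if _curves_separated(curves + [curve], config.min_needle_clearance_mm, dz):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place {n} needles at pitch {config.pitch_mm} mm "
                    "without merges; reduce bending or needle count"
                )
            specs.append(spec)
            curves.append(curve)

        z_tip_min = min(c.tip[0] for c in curves)
        z_distal_max = max(c.distal_end[0] for c in curves)
        z0 = dz * math.floor((z_tip_min - 8.0) / dz)
        z_end = z_distal_max + 8.0
        truncation = np.zeros(n)
        truncate = rng.random() < config.truncation_prob
        if truncate:
            cut = float(rng.uniform(0.0, config.truncation_max_mm))
            z_end = z_distal_max - cut
            # floor, so the caudal border honours the requested cut
            nz = int(math.floor((z_end - z0) / dz)) + 1
        else:
            nz = int(math.ceil((z_end - z0) / dz)) + 1
        z_last = z0 + dz * (nz - 1)

        clipped = []
        for i, c in enumerate(curves):
            if c.distal_end[0] > z_last + dz / 2:
                full = c.arc_length()
                c = c.clipped_to_zmax(z_last + dz / 2)
                truncation[i] = full - c.arc_length()
            clipped.append(c)

        ys = np.concatenate([c.points[:, 1] for c in clipped])
        xs = np.concatenate([c.points[:, 2] for c in clipped])
        y_lo, y_hi = ys.min() - 20.0, ys.max() + 20.0
        x_lo, x_hi = xs.min() - 20.0, xs.max() + 20.0
        probe_axis = None
        if config.include_probe:
            x_mid = float(x_positions.mean())
            probe_axis = np.array(
                [
                    [z_tip_min + 5.0, config.probe_offset_y_mm, x_mid],
                    [template.z_body_border, config.probe_offset_y_mm, x_mid],
                ]
            )
            y_lo = min(y_lo, config.probe_offset_y_mm - 10.0)
        ny = int(math.ceil((y_hi - y_lo) / dy)) + 1
        nx = int(math.ceil((x_hi - x_lo) / dx)) + 1

        distractors = []
        for _ in range(config.distractors_per_phantom):
            for _attempt in range(100):
                zc = rng.uniform(z0 + 4, template.z_body_border - 6)
                yc = rng.uniform(y_lo + 6, y_hi - 6)
                xc = rng.uniform(x_lo + 6, x_hi - 6)
                rad = rng.uniform(1.0, 2.0)
                clear = all(
                    c.yx_at_z(zc) is None
                    or np.hypot(*(c.yx_at_z(zc) - [yc, xc])) >= config.distractor_clearance_mm
                    for c in clipped
                )
                if clear:
                    distractors.append((np.array([zc, yc, xc]), rad, config.distractor_hu))
                    break

        truth = PhantomTruth(
            curves=clipped, specs=specs, probe_axis=probe_axis,
            truncation_mm=truncation, seed=seed,
        )
        volume = rasterize(
            truth,
            shape=(nz, ny, nx),
            spacing=config.spacing,
            origin=(z0, y_lo, x_lo),
            template=template,
            noise_sigma=config.noise_sigma,
            distractors=tuple(distractors),
            rng=rng,
        )
        out.append((volume, truth, template))
    return out
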