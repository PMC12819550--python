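# Methods

## The measurement problem

Interstitial titanium needles appear on CT as thin, very high-HU curvilinear
structures, nominally straight but bent by tissue forces during insertion.
The package quantifies (a) the accuracy of a threshold/centroid tracking
reconstruction of each needle, (b) the deviation of the actual tip from the
straight course predicted by extrapolating the distal needle end — the
quantity that limits any external (e.g. optical) tracking approach that only
sees the distal end — and (c) deviations from equidistant needle spacing in
the first-dwell-position slice.

## Reconstruction algorithm

Given a tip seed, the tracker walks caudally one axial slice at a time.  Per
slice it thresholds a 30 × 30 mm² window around the previous point at
600 HU, labels 8-connected conglomerates, computes each conglomerate's
center, and takes the center nearest the previous point.  Termination is
recorded as one of `stop_z` (reached the requested boundary), `volume_end`
(caudal scan border) or `no_conglomerate` (needle end or signal gap).

**Conglomerate centers.**  The default center is a background-subtracted
intensity center of mass over the component dilated by one pixel.  The
dilation ring re-captures partial-volume edge pixels that fall just below the
600 HU threshold; the background is the median of sub-threshold pixels in the
window, and negative excess weights are clipped to zero.  On the default
phantom (0.8 mm needle radius, 0.3 mm pixels) this center has ≤ 0.015 mm
worst-case subpixel error, versus ≈ 0.07 mm for the plain binary centroid —
the difference matters because the distal 1 cm line fit is extrapolated over
up to 220 mm, multiplying any systematic per-slice bias by ≈ 25.  The
unweighted binary centroid remains available (`weighted=False`) for
sensitivity checks.

**Template bridging.**  Tracking stops 2 mm body-side of the template band
(≈ 15 mm thick), where metal artifacts make thresholding useless.  The most
caudal 1 cm of the traced section — exactly the five most caudal slices at
the 2 mm slice spacing — is fitted by ordinary least squares of y(z) and x(z)
(one point per slice makes z the natural abscissa; at the ≤ 7° obliquities of
template-guided needles the difference to orthogonal regression is
negligible).  The line fills the band and both 2 mm margins and supplies the
restart point 2 mm air-side of the template.

**Merged needles.**  Needles whose disks overlap in a slice produce one
conglomerate; both paths then select the identical center and are flagged
`merged` and excluded from analysis, mirroring how such needles cannot be
separated by thresholding.

## Bending and spacing geometry

The distal (free in air) 1 cm of the reconstruction — for truncated needles,
the most distal 1 cm actually recorded — is fitted with a straight line and
extrapolated by the known needle length from the most distal reconstruction
point, giving the predicted tip T_e.  With C from the distal point to the
actual tip T_n and E = T_e − distal point:
α = arccos(C·E/|C||E|) (the dot-product ratio clamped to [−1, 1] against
rounding), Δb_total = |T_n − T_e|, Δb_trans = sin(α)|C| (equal to the
perpendicular distance from T_n to the prediction line),
Δb_long = √(Δb_total² − Δb_trans²) with a zero clamp if rounding makes the
radicand negative.  Truncated needles are still extrapolated by the full
nominal length and carry a caveat flag.

Segments: six equal 60° sectors about the probe center in the landmark slice
(the z-midpoint of the probe's caudal half).  Segment 1 is centered anterior,
then 2 and 3 sweeping toward the configured lateral direction, 6 posterior,
mirrored by 4 and 5 on the other side.  The exact left/right numbering is a
convention, kept configurable in `SegmentFrame` and recorded with results; a
point exactly on a boundary goes to the lower-numbered adjacent segment.

Dwell slice: the first possible dwell position sits 9 mm from the tip along
the path (arc length, not z-distance); the slice whose longitudinal interval
(z − dz/2, z + dz/2] contains that point is used.  The interval is
left-open/right-closed so that a point landing exactly on an interval
boundary belongs to the more cranial slice.  Spacing distances e_A and e_B
are measured between reconstruction points in that one slice (same z, so 3D
and in-plane distance coincide); Δe_trans = |e_A − e_B|.  Note what this
statistic cannot see: a common-mode displacement of all three needles leaves
it unchanged (verified as an invariance test), so it measures equidistance,
not absolute placement.

## Statistics and reporting

Medians and interquartile ranges use linear interpolation between order
statistics (numpy's default quantile convention); the IQR is reported as the
single width Q3 − Q1.  Needle-length bins are left-open/right-closed
(]100, 120], …, ]200, 220]); lengths outside every bin appear in an explicit
"outside" row.  Histograms use fixed 0.5-unit bins starting at zero.
Threshold counts use strict inequalities and whole-percent rounding.

The intra-observer emulation re-creates a repeated manual reconstruction
protocol: each truth path is jittered three times with isotropic in-plane
Gaussian click noise (default σ = 0.1 mm) and all pairwise per-slice
distances are pooled (pooling, rather than per-slice averaging before
summarizing, is the default).  The pooled distances follow a Rayleigh(σ√2)
law, median σ√2·√(2 ln 2) ≈ 1.665 σ, which the emulation must reproduce.

## Synthetic phantom generator

The generator defines the study conditions:

- **Grid**: 2 × 0.3 × 0.3 mm³ voxels (dz, dy, dx); z index 0 is the most
  cranial slice; all coordinates are physical mm of voxel centers.
- **Needle shape**: a straight distal section (air overhang, default 40 mm,
  plus template and a short proximal run) followed by a single-plane circular
  arc of angle θ over the inserted remainder.  The arc is a one-parameter
  stand-in — the true in-situ bending shape of titanium needles is unknown —
  chosen because its chord/tangent geometry has closed forms.  Curves with a
  bend radius under 50 mm are rejected as unphysical.
- **Cohort distributions**: nominal lengths from {120 … 220} mm; θ log-normal
  with median 1.8° and log-σ 0.446 (so that the quartiles match a 1.8° ± 1.1°
  median ± IQR), clipped to the observed 0.1–6.6° range; bending azimuth φ
  uniform; entry tilt uniform up to 3° from the z axis; 7.4% of phantoms get
  a distal scan-range truncation uniform in (0, 16] mm.
- **Rendering**: needle disks (radius 0.8 mm, 3000 HU) are painted with
  supersampled partial-volume coverage at the rim, emulating the partial
  volume effect that makes sub-voxel localisation possible on real CT; soft
  tissue is N(40, 20) HU; the probe is a 300 HU cylinder (below threshold, so
  it never enters conglomerate detection); the template band receives salt
  noise (density 0.3, HU uniform in 600–3000) — not a physical streak-artifact
  simulation, merely enough to make thresholding unreliable exactly where the
  algorithm must bridge; optional calcification spheres (800 HU, 1–2 mm)
  act as distractors.
- **Determinism**: one `numpy` generator seeded per cohort; identical
  (config, seed) pairs give bit-identical truth and volumes.

What the phantom does **not** model: in-plane PSF blur (deliberately — with a
hard 600 HU threshold, blurring pushes edge mass below threshold and degrades
rather than improves center accuracy), beam hardening and streak physics,
tissue deformation under needle force, and anatomical background structure.
Passing recovery tests therefore demonstrates the correctness and intrinsic
precision of the algorithmic chain under controlled imaging, not clinical
accuracy on patient scans.

## Validation experiment design

- **Zero-bend null and length monotonicity** use perpendicular (tilt 0),
  grid-commensurate insertion so both path endpoints fall on slice centers.
  With random slice phase, the ±dz quantization of the tip and end alone adds
  up to ~4 mm of longitudinal prediction error — visible as the ~4 mm
  `db_long` floor in the default demo cohort — which would swamp the
  sub-0.5 mm null these experiments test.  The null isolates spurious
  *bending* signal; longitudinal slice quantization is a separate, fully
  understood effect.
- **Parameter recovery** (θ uniform in 0.5–6.6°, noise-free and default
  noise) compares the image-based reconstruction against an oracle that
  applies the identical tip-prediction geometry to the analytic curve sampled
  on the same slice grid, isolating the error added by imaging and tracking.
- **Problem sizes** (50 null needles, 2 × 100 recovery arcs, 6 × 20
  monotonicity phantoms, 20 oracle-equivalence volumes, 53 × 3 variability
  repeats, 8 × 6 demo pipeline) keep the whole validation in the
  tens-of-seconds range on one CPU while leaving the Monte-Carlo margins
  comfortably inside the tested bounds.

## Numerical choices and edge cases

- Equidistant-centroid ties break toward smaller y, then smaller x.
- An empty detection window mid-needle terminates the trace and records the
  reason; behavior at gaps outside the template is thereby explicit.
- Detection windows are clipped, not failed, at image borders; components
  touching the window edge count as (clipped) conglomerates.
- A fitted line perpendicular to z cannot be evaluated per slice and raises.
- The 600 HU threshold is inclusive (≥); a 599 HU structure is invisible, and
  needle specs below 600 HU are rejected at validation.
- JSON/CSV path serialization round-trips at machine precision (CSV reading
  uses round-trip float parsing); NIfTI stores float32 HU losslessly for the
  rendered volumes; DICOM stores int16 with slope 1/intercept 0, exact for
  integer HU.

## Known limitations

- The circular-arc bending model is a generative convenience, not a claim
  about titanium mechanics; recovery results quantify the measurement chain,
  not needle physics.
- Tip seeds come from the ground truth (the clinical workflow supplies them
  in practice); automatic tip detection is out of scope.
- Δb_long on per-slice paths is quantization-dominated (±dz per endpoint);
  only experiments designed around it (see above) can resolve sub-slice
  longitudinal effects.
- The spacing statistic is blind to common-mode displacement by construction.
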