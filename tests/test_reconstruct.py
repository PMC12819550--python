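import numpy as np
import pytest

from needlebend.phantom import TemplateRegion
from needlebend.reconstruct import (
    NeedlePath,
    StraightLineFit,
    bridge_template,
    detect_conglomerates,
    fit_line,
    flag_merged,
    nearest_centroid,
    reconstruct_needle,
    trace,
)
from needlebend.stats import path_from_curve
from needlebend.volume import CTVolume

from _oracles import oracle_detect
from conftest import make_small_phantom

PY = 0.3 * np.arange(128)
PX = 0.3 * np.arange(128)


class TestDetectConglomerates:
    def test_symmetric_blob_center(self):
        img = np.zeros((128, 128))
        iy = int(round(10.0 / 0.3))
        ix = int(round(12.0 / 0.3))
        img[iy - 2 : iy + 3, ix - 2 : ix + 3] = 3000.0
        centers = detect_conglomerates(img, PY, PX, (10.0, 12.0))
        assert len(centers) == 1
        assert np.allclose(centers[0], [PY[iy], PX[ix]], atol=1e-12)

    def test_uniform_slice_below_threshold_gives_empty(self):
        img = np.full((128, 128), 599.0)
        assert detect_conglomerates(img, PY, PX, (19.0, 19.0)) == []

    def test_boundary_value_600_included(self):
        img = np.zeros((128, 128))
        img[50, 50] = 600.0
        assert len(detect_conglomerates(img, PY, PX, (15.0, 15.0))) == 1

    @pytest.mark.parametrize("weighted", [False, True])
    def test_random_noise_matches_flood_fill_oracle(self, weighted, rng):
        img = np.where(rng.random((128, 128)) < 0.08, 1000.0, 0.0)
        img += rng.uniform(0, 400, img.shape)  # sub-threshold texture
        got = detect_conglomerates(img, PY, PX, (19.0, 19.0), weighted=weighted)
        exp = oracle_detect(img, PY, PX, (19.0, 19.0), weighted=weighted)
        got = sorted(map(tuple, got))
        exp = sorted(map(tuple, exp))
        assert len(got) == len(exp)
        assert np.allclose(got, exp, atol=1e-9)

    def test_window_clipped_at_border(self):
        img = np.zeros((128, 128))
        img[1, 1] = 3000.0
        centers = detect_conglomerates(img, PY, PX, (0.0, 0.0))
        assert len(centers) == 1


class TestNearestCentroid:
    def test_prefers_closer_centroid(self):
        c = nearest_centroid([np.array([0.0, 7.0]), np.array([0.0, 3.0])], (0.0, 0.0))
        assert np.allclose(c, [0.0, 3.0])

    def test_single_centroid_identity(self):
        c = nearest_centroid([np.array([2.0, 5.0])], (0.0, 0.0))
        assert np.allclose(c, [2.0, 5.0])

    def test_equidistant_tie_broken_by_smaller_y_then_x(self):
        c = nearest_centroid([np.array([1.0, 0.0]), np.array([-1.0, 0.0])], (0.0, 0.0))
        assert np.allclose(c, [-1.0, 0.0])
        c = nearest_centroid([np.array([0.0, 1.0]), np.array([0.0, -1.0])], (0.0, 0.0))
        assert np.allclose(c, [0.0, -1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nearest_centroid([], (0.0, 0.0))


class TestTrace:
    def test_straight_needle_traced_subvoxel(self):
        volume, truth, template, _ = make_small_phantom(
            seed=4, noise_sigma=0.0, with_template_band=False
        )
        curve = truth.curves[0]
        tp = path_from_curve(curve, dz=volume.spacing[0], z0=volume.origin[0])
        result = trace(volume, tp.points[0])
        assert result.reason == "no_conglomerate"
        for p in result.points:
            yx = curve.yx_at_z(p[0])
            assert np.hypot(p[1] - yx[0], p[2] - yx[1]) <= 0.15

    def test_trace_stops_where_signal_ends(self):
        volume, truth, template, _ = make_small_phantom(
            seed=5, noise_sigma=0.0, with_template_band=False
        )
        z_k = 80.0
        volume.voxels[volume.slice_index(z_k):] = 0.0
        tp = path_from_curve(truth.curves[0], dz=2.0, z0=0.0)
        result = trace(volume, tp.points[0])
        assert result.reason == "no_conglomerate"
        assert result.points[-1, 0] == pytest.approx(z_k - 2.0)

    def test_stop_z_respected(self):
        volume, truth, template, _ = make_small_phantom(seed=6, noise_sigma=0.0)
        tp = path_from_curve(truth.curves[0], dz=2.0, z0=0.0)
        result = trace(volume, tp.points[0], stop_z=50.0)
        assert result.reason == "stop_z"
        assert result.points[-1, 0] <= 50.0


class TestFitLine:
    def test_collinear_points_fit_exactly(self):
        z = np.arange(5) * 2.0
        pts = np.column_stack([z, 1.0 + 0.1 * z, -2.0 + 0.05 * z])
        fit = fit_line(pts)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)
        d = pts[0] - pts[-1]
        d /= np.linalg.norm(d)
        assert np.allclose(fit.direction, d, atol=1e-12)
        assert abs(np.linalg.norm(fit.direction) - 1.0) < 1e-12

    def test_alternating_perturbation_cancels(self):
        z = np.arange(5) * 2.0
        pts = np.column_stack([z, np.zeros(5), np.zeros(5)])
        pts[:, 2] += 0.1 * np.array([1, -1, 1, -1, 1])
        fit = fit_line(pts)
        assert np.allclose(fit.direction, [-1.0, 0.0, 0.0], atol=1e-12)

    def test_matches_polyfit_oracle_on_random_points(self, rng):
        from _oracles import oracle_fit_direction

        pts = np.column_stack([
            np.arange(8) * 2.0,
            rng.normal(0, 1, 8),
            rng.normal(0, 1, 8),
        ])
        fit = fit_line(pts)
        anchor, d = oracle_fit_direction(pts)
        assert np.allclose(fit.direction, d, atol=1e-9)
        assert np.allclose(fit.at_z(anchor[0]), anchor, atol=1e-9)

    def test_one_cm_extent_selects_five_slices_at_2mm(self):
        pts = np.column_stack([np.arange(10) * 2.0, np.zeros(10), np.zeros(10)])
        assert fit_line(pts, extent_mm=10.0).n_points == 5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_line(np.array([[0.0, 0.0, 0.0]]))

    def test_single_slice_points_rejected(self):
        pts = np.array([[2.0, 0.0, 0.0], [2.0, 1.0, 1.0]])
        with pytest.raises(ValueError, match="one z"):
            fit_line(pts)


class TestBridgeTemplate:
    def test_straight_needle_bridged_on_true_line(self):
        volume, truth, template, spec = make_small_phantom(
            seed=7, tilt_deg=2.0, tilt_az_deg=120.0, noise_sigma=0.0
        )
        curve = truth.curves[0]
        tp = path_from_curve(curve, dz=2.0, z0=0.0)
        first = trace(volume, tp.points[0], stop_z=template.z_body_border - 2.0)
        seed, bridged = bridge_template(first.points, template, volume)
        for p in bridged:
            yx = curve.yx_at_z(p[0])
            assert np.hypot(p[1] - yx[0], p[2] - yx[1]) <= 0.3

    def test_extrapolation_span_is_template_plus_margins(self):
        # path ends 2 mm body-side; restart 2 mm air-side: span 15 + 4 = 19 mm
        # (1 mm slices so the stated offsets land on slice centers)
        volume = CTVolume(voxels=np.zeros((120, 32, 32)), spacing=(1.0, 0.3, 0.3),
                          origin=np.array([0.0, -4.65, -4.65]))
        template = TemplateRegion(z_body_border=81.0, z_air_border=96.0)
        z = np.arange(60.0, 80.0)  # ends at z_body_border - 2
        pts = np.column_stack([z, np.zeros_like(z), np.zeros_like(z)])
        seed, bridged = bridge_template(pts, template, volume)
        assert seed[0] - pts[-1, 0] == pytest.approx(template.thickness + 4.0)
        assert bridged[0, 0] == pytest.approx(80.0)
        assert np.allclose(bridged[:, 1:], 0.0, atol=1e-12)

    def test_line_perpendicular_to_z_cannot_bridge(self):
        fit = StraightLineFit(anchor=np.zeros(3), direction=np.array([0.0, 1.0, 0.0]),
                              rms_residual=0.0, n_points=5)
        with pytest.raises(ValueError, match="perpendicular"):
            fit.at_z(10.0)


class TestReconstructNeedle:
    def test_full_length_straight_needle(self):
        volume, truth, template, spec = make_small_phantom(seed=9)
        tp = path_from_curve(truth.curves[0], dz=2.0, z0=0.0)
        path = reconstruct_needle(volume, tp.points[0], template,
                                  nominal_length=spec.nominal_length)
        assert not path.truncated
        assert path.arc_length() == pytest.approx(spec.nominal_length, abs=2.0)
        assert path.bridged_interval is not None
        lo, hi = path.bridged_interval
        assert lo == pytest.approx(template.z_body_border, abs=2.0)
        assert hi == pytest.approx(template.z_air_border + 2.0, abs=1.0)
        # one point per slice, strictly monotone z
        assert np.allclose(np.diff(path.points[:, 0]), volume.spacing[0])

    def test_distal_cutoff_flags_truncated(self):
        volume, truth, template, spec = make_small_phantom(seed=10)
        cut_index = volume.slice_index(truth.curves[0].distal_end[0]) - 8  # ~16 mm
        volume = CTVolume(voxels=volume.voxels[:cut_index], spacing=volume.spacing,
                          origin=volume.origin)
        tp = path_from_curve(truth.curves[0], dz=2.0, z0=0.0)
        path = reconstruct_needle(volume, tp.points[0], template,
                                  nominal_length=spec.nominal_length)
        assert path.truncated
        assert path.termination_reason == "volume_end"
        missing = spec.nominal_length - path.arc_length()
        assert missing == pytest.approx(16.0, abs=2.0)

    def test_no_needle_beyond_template_ends_at_restart_point(self):
        volume, truth, template, spec = make_small_phantom(seed=11)
        k_air = volume.slice_index(template.z_air_border)
        volume.voxels[k_air + 1 :] = 0.0  # erase the air-side needle
        tp = path_from_curve(truth.curves[0], dz=2.0, z0=0.0)
        path = reconstruct_needle(volume, tp.points[0], template,
                                  nominal_length=spec.nominal_length)
        assert path.termination_reason == "no_conglomerate"
        assert path.points[-1, 0] == pytest.approx(template.z_air_border + 2.0, abs=1.0)

    def test_parallel_needles_one_mm_apart_flagged_merged(self):
        from needlebend.phantom import NeedleCurveSpec, PhantomTruth, make_needle_curve, rasterize
        import warnings

        specs = [
            NeedleCurveSpec(
                nominal_length=90.0,
                insertion_point=np.array([96.0, 0.0, x0]),
                entry_direction=np.array([-1.0, 0.0, 0.0]),
                straight_extent=45.0,
                air_overhang=20.0,
            )
            for x0 in (0.0, 1.0)
        ]
        curves = [make_needle_curve(s) for s in specs]
        truth = PhantomTruth(curves=curves, specs=specs, probe_axis=None,
                             truncation_mm=np.zeros(2), seed=0)
        template = TemplateRegion(z_body_border=81.0, z_air_border=96.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            volume = rasterize(truth, shape=(64, 128, 128), origin=(0.0, -19.05, -19.05),
                               template=template, noise_sigma=0.0,
                               rng=np.random.default_rng(0))
        paths = [
            reconstruct_needle(volume, path_from_curve(c, dz=2.0, z0=0.0).points[0],
                               template, nominal_length=90.0, needle_id=i)
            for i, c in enumerate(curves)
        ]
        flag_merged(paths)
        assert paths[0].merged and paths[1].merged

    def test_distant_distractor_does_not_divert_tracking(self):
        volume, truth, template, spec = make_small_phantom(seed=12, noise_sigma=0.0,
                                                           with_template_band=False)
        curve = truth.curves[0]
        # calcification blob 6 mm from the needle on every slice
        py, px = volume.pixel_centers()
        for k, z in enumerate(volume.z_coords):
            yx = curve.yx_at_z(z)
            if yx is None:
                continue
            iy = int(round((yx[0] + 6.0 - volume.origin[1]) / 0.3))
            ix = int(round((yx[1] - volume.origin[2]) / 0.3))
            volume.voxels[k, iy - 3 : iy + 4, ix - 3 : ix + 4] = 800.0
        tp = path_from_curve(curve, dz=2.0, z0=0.0)
        result = trace(volume, tp.points[0])
        for p in result.points:
            yx = curve.yx_at_z(p[0])
            assert np.hypot(p[1] - yx[0], p[2] - yx[1]) <= 0.2


class TestNeedlePath:
    def test_non_monotone_z_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            NeedlePath(points=[[0, 0, 0], [4, 0, 0], [2, 0, 0]])

    def test_point_lookup_by_slice(self):
        p = NeedlePath(points=[[0, 1, 2], [2, 3, 4], [4, 5, 6]])
        assert np.allclose(p.point_at_z(2.0), [2, 3, 4])
        assert p.point_at_z(7.5) is None
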