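"""Rendering, LoG enhancement, detection, observer filtering, flex."""

import math

import numpy as np
import pytest
from scipy import ndimage

from epival.config import PANEL_PITCH_MM
from epival.geometry import BeamGeometry, project_points
from epival.motion_sim import aperture_polygon
from epival.portal_imaging import (
    FlexEstimationError,
    MarkerLocalizationSet,
    apply_flex_correction,
    detect_markers,
    estimate_flex,
    infer_obscured_marker,
    interobserver_filter,
    log_filter,
    make_aperture_template,
    match_to_reference,
    render_portal,
)

MARKERS = np.array([[-6.0, -4.0, 3.0], [7.0, -1.0, -4.0], [0.0, 6.0, 2.0]])
N = 256


def _scene(gantry=0.0, flex=(0.0, 0.0), noise=0.0, markers=MARKERS, seed=0,
           halfwidth=20.0):
    geom = BeamGeometry(gantry)
    template = make_aperture_template(aperture_polygon(halfwidth), N, geom)
    rng = np.random.default_rng(seed)
    image, visible, uv = render_portal(markers, geom, template, noise, flex, rng)
    return geom, template, image, visible, uv


def _uv_to_px(uv, geom):
    c0 = (N - 1) / 2
    col = c0 + uv[0] * geom.magnification / PANEL_PITCH_MM
    row = c0 - uv[1] * geom.magnification / PANEL_PITCH_MM
    return row, col


class TestRenderPortal:
    def test_blob_minima_at_projected_positions(self):
        geom, template, image, visible, uv = _scene()
        assert visible.all()
        pix = image.pixels.astype(float)
        for m in uv:
            r, c = _uv_to_px(m, geom)
            ri, ci = int(round(r)), int(round(c))
            win = pix[ri - 4:ri + 5, ci - 4:ci + 5]
            dr, dc = np.unravel_index(np.argmin(win), win.shape)
            assert abs((ri - 4 + dr) - r) <= 0.5
            assert abs((ci - 4 + dc) - c) <= 0.5

    def test_marker_outside_aperture_is_occluded(self):
        markers = MARKERS.copy()
        markers[0] = [25.0, 0.0, 0.0]  # outside the 20 mm aperture but on the panel
        geom, template, image, visible, uv = _scene(markers=markers)
        assert visible.tolist() == [False, True, True]
        # no blob drawn where the occluded marker would project
        r, c = _uv_to_px(uv[0], geom)
        patch = image.pixels[int(r) - 3:int(r) + 4, int(c) - 3:int(c) + 4].astype(float)
        out_level = float(np.median(image.pixels[:20, :20]))
        assert abs(patch.mean() - out_level) < 30.0

    def test_blob_integral_matches_gaussian_closed_form(self):
        # single marker deep inside a large open field, no noise
        markers = np.array([[0.0, 0.0, 0.0], [15.0, 0.0, 0.0], [-15.0, 0.0, 0.0]])
        geom, template, image, visible, uv = _scene(markers=markers, halfwidth=24.0)
        pix = image.pixels.astype(float)
        r, c = _uv_to_px(uv[0], geom)
        ri, ci = int(round(r)), int(round(c))
        background = 3000.0
        half = 14
        win = pix[ri - half:ri + half + 1, ci - half:ci + half + 1]
        integral = float((background - win).sum())
        sigma_px = 1.5 * geom.magnification / (2 * math.sqrt(2 * math.log(2))) / PANEL_PITCH_MM
        expected = 1500.0 * 2 * math.pi * sigma_px**2
        assert integral == pytest.approx(expected, rel=0.01)


class TestLogFilter:
    def test_constant_image_maps_to_zero(self, geom0):
        img = np.full((128, 128), 1234.0)
        out = log_filter(img, iso_pixel_mm=0.25)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_delta_reproduces_discrete_kernel(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = log_filter(img, iso_pixel_mm=0.25)
        # convolution identity: symmetric kernel with near-zero sum and a
        # negative center lobe (bright dot -> negative response)
        np.testing.assert_allclose(out, out[::-1, :], atol=1e-12)
        np.testing.assert_allclose(out, out[:, ::-1], atol=1e-12)
        assert out[32, 32] < 0
        assert abs(out.sum()) < 1e-6 * np.abs(out).max() * out.size

    def test_gaussian_blob_extremum_at_center(self):
        # dark blob of SD 1.0 mm: maximum LoG response at the blob center
        yy, xx = np.mgrid[0:129, 0:129]
        r0, c0 = 61.3, 70.7
        sigma_px = 1.0 / 0.25
        img = 1000.0 - 500.0 * np.exp(-((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * sigma_px**2))
        out = log_filter(img, iso_pixel_mm=0.25)
        r, c = np.unravel_index(np.argmax(out), out.shape)
        assert abs(r - r0) < 0.75 and abs(c - c0) < 0.75

    def test_extent_precondition(self):
        with pytest.raises(ValueError):
            log_filter(np.zeros((32, 32)), kernel_extent_mm=1.0, sigma_mm=1.0,
                       iso_pixel_mm=0.25)


class TestDetectMarkers:
    def test_three_markers_recovered_within_tolerance(self):
        geom, template, image, _, uv = _scene()
        det = detect_markers(log_filter(image), template, geom)
        assert len(det) == 3
        for m in uv:
            assert np.linalg.norm(det.uv - m, axis=1).min() < 0.3

    def test_single_visible_marker_flags_exclusion(self):
        markers = MARKERS.copy()
        markers[0] = [25.0, 0.0, 0.0]
        markers[1] = [0.0, 25.0, 0.0]
        geom, template, image, visible, _ = _scene(markers=markers)
        assert visible.sum() == 1
        det = detect_markers(log_filter(image), template, geom)
        assert len(det) < 2  # caller's single-marker exclusion condition

    def test_uniform_image_yields_no_detections(self):
        geom = BeamGeometry(0.0)
        template = make_aperture_template(aperture_polygon(20.0), N, geom)
        rng = np.random.default_rng(0)
        img = rng.normal(2000.0, 20.0, size=(N, N))
        det = detect_markers(log_filter(img, iso_pixel_mm=0.25), template, geom)
        assert len(det) == 0


class TestInferObscuredMarker:
    def test_no_motion_gives_exact_reference_projection(self):
        geom = BeamGeometry(30.0)
        ref_uv = project_points(MARKERS, geom)
        inferred, mid = infer_obscured_marker(ref_uv[[0, 1]], [0, 1], MARKERS, geom)
        np.testing.assert_allclose(inferred, ref_uv[2], atol=1e-9)
        assert mid == 2

    def test_pure_translation_preserves_offsets(self):
        geom = BeamGeometry(0.0)
        shift = np.array([2.0, -1.0, 1.5])
        moved = MARKERS + shift
        moved_uv = project_points(moved, geom)
        inferred, mid = infer_obscured_marker(moved_uv[[0, 2]], [0, 2], MARKERS, geom)
        assert np.linalg.norm(inferred - moved_uv[1]) < 0.1

    def test_rotation_error_bounded_by_geometry(self):
        # rotate the constellation 10 degrees about the beam axis (z at gantry 0)
        geom = BeamGeometry(0.0)
        a = math.radians(10.0)
        rz = np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]])
        rotated = MARKERS @ rz.T
        rot_uv = project_points(rotated, geom)
        inferred, mid = infer_obscured_marker(rot_uv[[0, 1]], [0, 1], MARKERS, geom)
        err = np.linalg.norm(inferred - rot_uv[2])
        offset_len = np.linalg.norm(MARKERS[2] - MARKERS[[0, 1]].mean(axis=0))
        # small-angle bound with a magnification allowance
        assert 0.0 < err <= 2.5 * offset_len * math.sin(a)

    def test_more_than_one_obscured_is_exclusion(self):
        geom = BeamGeometry(0.0)
        with pytest.raises(ValueError):
            infer_obscured_marker(project_points(MARKERS, geom)[[0]], [0], MARKERS, geom)


class TestInterobserverFilter:
    def test_identical_sets_retained_unchanged(self):
        uv = np.array([[1.0, 2.0], [3.0, -1.0], [0.0, 0.0]])
        sets = [MarkerLocalizationSet(f"o{i}", uv.copy()) for i in range(3)]
        mean, dropped = interobserver_filter(sets)
        assert dropped == []
        np.testing.assert_allclose(mean.uv, uv)

    def test_disagreeing_marker_excluded(self):
        uv = np.array([[1.0, 2.0], [3.0, -1.0], [0.0, 0.0]])
        uv2 = uv.copy()
        uv2[1, 0] += 2.0  # 2.0 mm apart on marker 1
        mean, dropped = interobserver_filter(
            [MarkerLocalizationSet("a", uv), MarkerLocalizationSet("b", uv2)]
        )
        assert dropped == [1]
        assert len(mean) == 2

    def test_small_triangle_averages_to_centroid(self):
        base = np.array([[5.0, 5.0]])
        side = 1.0
        verts = base + side * np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]])
        sets = [MarkerLocalizationSet(f"o{i}", verts[i:i + 1]) for i in range(3)]
        # pad to 2 markers so the image is not excluded
        anchor = np.array([[-5.0, -5.0]])
        sets = [
            MarkerLocalizationSet(f"o{i}", np.vstack([verts[i:i + 1], anchor]))
            for i in range(3)
        ]
        mean, dropped = interobserver_filter(sets)
        assert dropped == []
        np.testing.assert_allclose(mean.uv[0], verts.mean(axis=0), atol=1e-12)

    def test_image_excluded_when_fewer_than_two_remain(self):
        uv = np.array([[1.0, 2.0], [3.0, -1.0]])
        uv2 = uv + 2.0
        mean, dropped = interobserver_filter(
            [MarkerLocalizationSet("a", uv), MarkerLocalizationSet("b", uv2)]
        )
        assert mean is None
        assert dropped == [0, 1]


class TestFlex:
    def test_zero_flex_recovered_near_zero(self):
        geom, template, image, _, _ = _scene(noise=30.0)
        est = estimate_flex(image, template)
        assert math.hypot(est.fu, est.fv) < 0.1

    def test_known_flex_recovered(self):
        geom, template, image, _, _ = _scene(flex=(1.3, -0.7), noise=30.0)
        est = estimate_flex(image, template)
        assert est.fu == pytest.approx(1.3, abs=0.2)
        assert est.fv == pytest.approx(-0.7, abs=0.2)
        assert est.peak > 0.9

    def test_correction_scale_arithmetic(self):
        geom = BeamGeometry(0.0)
        locs = MarkerLocalizationSet("c", np.array([[1.0, 1.0], [2.0, 0.0]]))
        corrected = apply_flex_correction(locs, (1.0, 1.0), geom)
        np.testing.assert_allclose(locs.uv - corrected.uv, 0.625)

    def test_correction_then_reestimation_is_null(self):
        geom, template, image, _, _ = _scene(flex=(1.5, -1.2), noise=20.0)
        est = estimate_flex(image, template)
        unshifted = ndimage.shift(
            image.pixels.astype(float),
            (est.fv / PANEL_PITCH_MM, -est.fu / PANEL_PITCH_MM), order=1, mode="nearest",
        )
        image2 = type(image)(np.clip(unshifted, 0, 65535).astype(np.uint16),
                             geom, image.t_acq, image.field_id)
        est2 = estimate_flex(image2, template)
        assert math.hypot(est2.fu, est2.fv) < 0.1

    def test_weak_match_raises(self):
        geom = BeamGeometry(0.0)
        template = make_aperture_template(aperture_polygon(20.0), N, geom)
        rng = np.random.default_rng(1)
        img = rng.normal(1000.0, 200.0, size=(N, N))
        from epival.portal_imaging import PortalImage

        with pytest.raises((FlexEstimationError, ValueError)):
            estimate_flex(PortalImage(np.clip(img, 0, 65535).astype(np.uint16),
                                      geom, 0.0, 1), template)


class TestMatching:
    def test_detection_identity_matching(self):
        geom = BeamGeometry(0.0)
        ref = project_points(MARKERS, geom)
        det = ref[[2, 0]] + 0.05  # markers 2 and 0, slightly perturbed
        ids, missing = match_to_reference(det, ref)
        assert ids.tolist() == [2, 0]
        assert missing == [1]

    def test_com_is_identity_free(self):
        s1 = MarkerLocalizationSet("a", np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]]))
        s2 = MarkerLocalizationSet("b", s1.uv[::-1].copy())
        assert s1.com().u == pytest.approx(s2.com().u)
        assert s1.com().v == pytest.approx(s2.com().v)


class TestEndToEndLocalization:
    def test_noise_free_median_error_and_monotone_degradation(self):
        rng_levels = [0.0, 60.0, 300.0, 900.0]
        medians = []
        for noise in rng_levels:
            errs = []
            for seed in range(4):
                geom, template, image, _, uv = _scene(noise=noise, seed=seed,
                                                      gantry=45.0 * seed)
                det = detect_markers(log_filter(image), template, geom)
                for m in det.uv:
                    errs.append(np.linalg.norm(uv - m, axis=1).min())
            medians.append(np.median(errs))
        assert medians[0] < 0.3
        assert all(a <= b + 1e-9 for a, b in zip(medians, medians[1:]))
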