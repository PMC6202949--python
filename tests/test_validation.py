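"""Pipeline core: error computation, exclusion logic, studies, phantom."""

import dataclasses

import numpy as np
import pytest

from epival.config import AnalysisConfig, ConfidenceModel, SessionConfig
from epival.geometry import BeamGeometry, project_points
from epival.motion_sim import MotionSample, aperture_polygon, make_session
from epival.portal_imaging import MarkerLocalizationSet, make_aperture_template, render_portal
from epival.validation import (
    EXCLUSION_REASONS,
    FieldValidation,
    _localize_image,
    compute_field_error,
    predict_marker_positions,
    run_phantom_study,
    run_study,
    run_validation,
    study_config_pairs,
)

from conftest import quiet_session_config

MARKERS = np.array([[-6.0, -4.0, 3.0], [7.0, -1.0, -4.0], [0.0, 6.0, 2.0]])


def _sample(translation=(0.0, 0.0, 0.0), confidence=0.9):
    return MotionSample(0.0, tuple(translation), (0.0, 0.0, 0.0), confidence)


class TestPredictMarkerPositions:
    def test_zero_translation_is_identity(self):
        np.testing.assert_array_equal(predict_marker_positions(MARKERS, _sample()), MARKERS)

    def test_translation_applied_to_every_marker(self):
        out = predict_marker_positions(MARKERS, _sample((1.0, 2.0, 3.0)))
        np.testing.assert_allclose(out - MARKERS, [[1, 2, 3]] * 3)

    def test_com_linearity(self):
        shift = np.array([0.7, -1.1, 2.2])
        out = predict_marker_positions(MARKERS, _sample(tuple(shift)))
        np.testing.assert_allclose(out.mean(axis=0), MARKERS.mean(axis=0) + shift,
                                   atol=1e-12)

    def test_rotation_disregarded(self):
        s = MotionSample(0.0, (0.0, 0.0, 0.0), (5.0, -3.0, 2.0), 0.9)
        np.testing.assert_array_equal(predict_marker_positions(MARKERS, s), MARKERS)


class TestComputeFieldError:
    def test_three_four_five(self):
        geom = BeamGeometry(0.0)
        # localized CoM offset from projected CoM by (0.3, 0.4) mm
        predicted = np.array([[0.0, 5.0, 0.0], [0.0, -5.0, 0.0], [5.0, 0.0, 0.0]])
        proj = project_points(predicted, geom)
        locs = MarkerLocalizationSet("c", proj - np.array([0.3, 0.4]))
        fv = compute_field_error(predicted, locs, geom)
        assert fv.e_u == pytest.approx(0.3, abs=1e-9)
        assert fv.e_v == pytest.approx(0.4, abs=1e-9)
        assert fv.e_mag == pytest.approx(0.5, abs=1e-9)

    def test_unit_lateral_bias_at_gantry_zero(self):
        # markers in the isocenter plane (z = 0): unit magnification is exact
        geom = BeamGeometry(0.0)
        markers = np.array([[0.0, 5.0, 0.0], [0.0, -5.0, 0.0], [5.0, 0.0, 0.0]])
        locs = MarkerLocalizationSet("c", project_points(markers, geom))
        predicted = markers + np.array([1.0, 0.0, 0.0])
        fv = compute_field_error(predicted, locs, geom)
        assert fv.e_u == pytest.approx(1.0, abs=1e-9)
        assert fv.e_v == pytest.approx(0.0, abs=1e-9)

    def test_single_marker_exclusion(self):
        geom = BeamGeometry(0.0)
        locs = MarkerLocalizationSet("c", np.array([[0.0, 0.0]]))
        fv = compute_field_error(MARKERS[:1], locs, geom)
        assert fv.excluded and fv.reason == "single_marker"

    def test_field_validation_invariants(self):
        with pytest.raises(ValueError):
            FieldValidation(1, excluded=True, reason="bogus")
        with pytest.raises(ValueError):
            FieldValidation(1, e_u=1.0, e_v=0.0, e_mag=2.0)


class TestBiasProjection:
    @pytest.mark.parametrize("gantry", [0, 45, 90, 135, 180, 225, 270, 315])
    def test_injected_bias_recovered_as_its_projection(self, gantry):
        # a systematic monitoring error b appears in E as the projection of b
        bias = np.array([0.8, -0.5, 0.6])
        geom = BeamGeometry(float(gantry))
        template = make_aperture_template(aperture_polygon(20.0), 256, geom)
        rng = np.random.default_rng(gantry)
        image, _, _ = render_portal(MARKERS, geom, template, 0.0, (0.0, 0.0), rng)
        cfg = AnalysisConfig(observer_noise_sd_mm=0.0)
        consensus, reason = _localize_image(image, template, MARKERS, bias, cfg,
                                            np.random.default_rng(0))
        assert reason is None and len(consensus) == 3
        predicted = MARKERS[[int(i) for i in consensus.marker_ids]] + bias
        fv = compute_field_error(predicted, consensus, geom)
        expected = (project_points(MARKERS + bias, geom)
                    - project_points(MARKERS, geom)).mean(axis=0)
        assert fv.e_u == pytest.approx(expected[0], abs=0.15)
        assert fv.e_v == pytest.approx(expected[1], abs=0.15)


class TestRunValidation:
    def test_noiseless_session_has_near_zero_errors(self, quiet_session):
        sdir, gt, cfg = quiet_session
        fields, summary = run_validation(
            sdir, AnalysisConfig(observer_noise_sd_mm=0.0)
        )
        assert all(not f.excluded for f in fields)
        assert np.median([f.e_mag for f in fields]) < 0.3
        assert summary.n_included == cfg.n_fields

    def test_poor_probe_fraction_excluded(self, tmp_path):
        cfg = quiet_session_config(seed=31, confidence=ConfidenceModel(poor_probe=True))
        make_session(cfg, tmp_path / "s")
        fields, summary = run_validation(tmp_path / "s")
        assert all(f.excluded and f.reason == "low_confidence" for f in fields)
        assert summary.n_included == 0
        assert summary.c_f < 0.5

    def test_forced_observer_outlier_excludes_field(self, quiet_session):
        sdir, gt, cfg = quiet_session
        fields, _ = run_validation(
            sdir, AnalysisConfig(observer_outlier_fields=(2,))
        )
        by_id = {f.field_id: f for f in fields}
        assert by_id[2].excluded and by_id[2].reason == "interobserver"
        assert not by_id[1].excluded

    def test_missing_files_enumerated(self, tmp_path):
        (tmp_path / "plan.json").write_text("{}")
        with pytest.raises(FileNotFoundError, match="monitor_log.csv"):
            run_validation(tmp_path)

    def test_exclusion_states_exhaustive_and_exclusive(self, default_session):
        sdir, gt, cfg = default_session
        fields, _ = run_validation(sdir, AnalysisConfig(seed=5))
        for f in fields:
            if f.excluded:
                assert f.reason in EXCLUSION_REASONS and f.e_mag is None
            else:
                assert f.reason is None and f.e_mag is not None


class TestRunStudy:
    def test_study_determinism(self, tmp_path):
        pairs = study_config_pairs(seed=9, n_fractions=2, n_five_field=1,
                                   n_outlier_fields=1, poor_probe_fraction=None)
        f1, s1 = run_study(pairs, tmp_path / "a")
        f2, s2 = run_study(pairs, tmp_path / "b")
        assert f1.equals(f2) and s1.equals(s2)
        assert len(f1) == 8  # one 5-field and one 3-field fraction

    def test_error_width_monotone_in_monitoring_noise(self, tmp_path):
        # E-distribution width must track the injected estimation noise
        widths = []
        levels = [0.1, 0.25, 0.5, 1.0, 2.0]
        for j, noise in enumerate(levels):
            pairs = study_config_pairs(
                seed=100 + j, n_fractions=3, n_five_field=3, n_outlier_fields=0,
                poor_probe_fraction=None, us_noise_sd=noise,
            )
            fields, _ = run_study(pairs, tmp_path / f"lvl{j}")
            ok = fields[~fields["excluded"]]
            q25, q75 = np.quantile(ok["e_u"], [0.25, 0.75])
            widths.append(float(q75 - q25))
        from scipy.stats import spearmanr

        rho = spearmanr(levels, widths).statistic
        assert rho > 0.9


class TestPhantom:
    def test_protocol_yields_thirty_images(self):
        res = run_phantom_study(seed=2)
        assert res.n_images == 30

    def test_zero_noise_localization_floor(self):
        res = run_phantom_study(seed=2, image_noise_sd=0.0, with_flex=False,
                                cfg=AnalysisConfig(observer_noise_sd_mm=0.0))
        assert res.median_error < 0.3

    def test_default_noise_submillimeter_and_ordered(self):
        res = run_phantom_study(seed=4)
        assert res.median_error < 1.0
        assert res.loa95 >= res.median_error
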