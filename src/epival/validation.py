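"""Pipeline core: compare monitored motion against portal-imaged markers.

For each treatment field the initial (CBCT-time) marker positions are
shifted by the monitoring system's 3D translation estimate at the
field's first-segment beam-on time (rotation estimates are disregarded),
projected onto the portal imager, and the projected center of mass is
compared with the center of mass of the image-localized markers.  The
per-field monitoring error E is reported along the two imager axes and
as the 2D magnitude, all in mm at isocenter scale.

Exclusion rules mirror clinical practice: a field is excluded when
observers disagree beyond the interobserver limit, when fewer than two
markers are identifiable, when the fraction's monitoring confidence is
persistently below the warning threshold, or when the logs cannot be
synchronized; every field ends up in exactly one of these states or in
the included set.

The phantom protocol replaces the monitoring estimate by exactly known
programmed platform shifts, so the localization chain (rendering, LoG
detection, observer filtering, flex correction) is the only error
source; it quantifies the precision floor of the validation itself.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import (
    PANEL_PITCH_MM,
    AnalysisConfig,
    ConfidenceModel,
    SessionConfig,
    derive_rng,
    derive_seed,
)
from .geometry import BeamGeometry, project_points
from .log_sync import (
    StaleEstimateError,
    SyncError,
    estimate_offset,
    field_first_segment_time,
    motion_at,
    parse_linac_log,
    parse_monitor_log,
)
from .motion_sim import MotionSample, aperture_polygon, make_session
from .portal_imaging import (
    FlexEstimate,
    FlexEstimationError,
    MarkerLocalizationSet,
    PortalImage,
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

__all__ = [
    "FieldValidation",
    "FractionSummary",
    "PhantomResult",
    "EXCLUSION_REASONS",
    "predict_marker_positions",
    "compute_field_error",
    "run_validation",
    "run_study",
    "study_config_pairs",
    "run_phantom_study",
    "fields_to_dataframe",
    "fractions_to_dataframe",
]

EXCLUSION_REASONS = ("interobserver", "single_marker", "low_confidence", "sync_failure")


@dataclass(frozen=True)
class FieldValidation:
    """Per-field monitoring error, or the exclusion that prevented it."""

    field_id: int
    fraction_id: str = ""
    e_u: float | None = None  # mm, projected minus imaged CoM, u axis
    e_v: float | None = None
    e_mag: float | None = None  # sqrt(e_u^2 + e_v^2)
    confidence: float | None = None  # C at the first-segment time
    excluded: bool = False
    reason: str | None = None
    n_markers: int = 0
    n_inferred: int = 0

    def __post_init__(self) -> None:
        if self.excluded:
            if self.reason not in EXCLUSION_REASONS:
                raise ValueError(f"unknown exclusion reason {self.reason!r}")
            if self.e_u is not None or self.e_v is not None or self.e_mag is not None:
                raise ValueError("excluded fields carry no error values")
        else:
            if self.reason is not None:
                raise ValueError("included fields carry no exclusion reason")
            if not np.isclose(self.e_mag, float(np.hypot(self.e_u, self.e_v))):
                raise ValueError("e_mag must equal the Euclidean norm of (e_u, e_v)")


@dataclass(frozen=True)
class FractionSummary:
    """Per-fraction aggregates and pass-through study labels."""

    fraction_id: str
    c_f: float  # mean monitoring confidence over the fraction
    e_f: float | None  # mean E magnitude over included fields
    n_included: int
    n_fields: int
    marker_group: str = "negative"
    iq_score: int = 3
    n_features_category: str = ">5 but <10"

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_f <= 1.0:
            raise ValueError("C_f must lie in [0, 1]")
        if self.e_f is not None and self.e_f < 0:
            raise ValueError("E_f must be non-negative")


@dataclass(frozen=True)
class PhantomResult:
    """Marker-localization precision from the programmed-motion protocol."""

    median_error: float  # mm
    loa95: float  # mm, one-sided 95% limit of agreement
    n_images: int

    def __post_init__(self) -> None:
        if not self.loa95 >= self.median_error >= 0.0:
            raise ValueError("require loa95 >= median_error >= 0")


def predict_marker_positions(markers_cbct: np.ndarray, sample: MotionSample) -> np.ndarray:
    """Shift the initial marker positions by the monitored 3D translation.

    Rotation estimates are deliberately ignored (they are not part of the
    clinically displayed motion and are disregarded in the comparison).
    """
    markers = np.atleast_2d(np.asarray(markers_cbct, dtype=float))
    return markers + np.asarray(sample.translation, dtype=float)[None, :]


def compute_field_error(
    predicted: np.ndarray,
    localized: MarkerLocalizationSet,
    geom: BeamGeometry,
    field_id: int = 0,
    fraction_id: str = "",
    confidence: float | None = None,
) -> FieldValidation:
    """Projected-minus-imaged center-of-mass error for one field.

    ``predicted`` must hold the same markers (same order) as ``localized``;
    fewer than two markers is the single-marker exclusion.
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    if len(localized) < 2 or len(predicted) < 2:
        return FieldValidation(field_id, fraction_id, excluded=True,
                               reason="single_marker", confidence=None,
                               n_markers=len(localized))
    if len(predicted) != len(localized):
        raise ValueError("predicted and localized marker counts differ")
    proj = project_points(predicted, geom)
    e = proj.mean(axis=0) - localized.uv.mean(axis=0)
    return FieldValidation(
        field_id, fraction_id,
        e_u=float(e[0]), e_v=float(e[1]), e_mag=float(np.hypot(e[0], e[1])),
        confidence=confidence, n_markers=len(localized),
        n_inferred=int(localized.inferred.sum()),
    )


# ---------------------------------------------------------------------------
# single-image localization chain (shared by session analysis and phantom)


def _localize_image(
    image: PortalImage,
    template,
    markers_cbct: np.ndarray,
    translation: np.ndarray,
    cfg: AnalysisConfig,
    rng_obs: np.random.Generator,
    outlier: bool = False,
) -> tuple[MarkerLocalizationSet | None, str | None]:
    """Full localization chain; returns (consensus set, exclusion reason)."""
    geom = image.geom
    try:
        flex_est = estimate_flex(
            image, template, cfg.threshold_quantile, cfg.flex_search_mm, cfg.flex_min_peak
        )
    except FlexEstimationError:
        warnings.warn(f"field {image.field_id}: unreliable flex match, no correction")
        flex_est = FlexEstimate(0.0, 0.0, 0.0)

    filtered = log_filter(image, cfg.log_extent_mm, cfg.log_sigma_mm)
    det = detect_markers(
        filtered, template, geom, image.pitch_panel,
        n_expected=3, min_separation_mm=cfg.min_separation_mm,
        edge_margin_mm=cfg.edge_margin_mm, detection_snr=cfg.detection_snr,
    )
    if len(det) < 2:
        return None, "single_marker"

    # identity against the predicted constellation (flex-shifted like the image)
    ref_uv = project_points(markers_cbct + translation[None, :], geom)
    ref_uv = ref_uv + np.array([flex_est.fu, flex_est.fv]) * geom.sad / geom.sdd
    ids, missing_after_detection = match_to_reference(det.uv, ref_uv)
    det.marker_ids = ids

    observers = []
    for o in range(cfg.observer_count):
        uv_o = det.uv + rng_obs.normal(0.0, cfg.observer_noise_sd_mm, det.uv.shape)
        if outlier and o == 0:
            uv_o = uv_o + cfg.observer_outlier_offset_mm / np.sqrt(2.0)
        observers.append(
            MarkerLocalizationSet(f"observer_{o + 1}", uv_o, marker_ids=ids.copy(),
                                  inferred=det.inferred.copy())
        )
    consensus, _dropped = interobserver_filter(observers, cfg.interobserver_threshold_mm)
    if consensus is None:
        return None, "interobserver"

    corrected = apply_flex_correction(consensus, flex_est, geom)

    # reconstruct a marker the MLC/bony anatomy hid (never one observers dropped)
    present = set(int(i) for i in corrected.marker_ids)
    absent = sorted(set(range(3)) - present)
    if len(corrected) == 2 and len(absent) == 1 and absent[0] in missing_after_detection:
        uv_inf, mid = infer_obscured_marker(
            corrected.uv, [int(i) for i in corrected.marker_ids], markers_cbct, geom
        )
        corrected = MarkerLocalizationSet(
            "consensus",
            np.vstack([corrected.uv, uv_inf]),
            marker_ids=np.append(corrected.marker_ids, mid),
            inferred=np.append(corrected.inferred, True),
        )
    return corrected, None


# ---------------------------------------------------------------------------
# session analysis


def run_validation(
    session_dir: str | Path,
    cfg: AnalysisConfig | None = None,
    fraction_id: str | None = None,
) -> tuple[list[FieldValidation], FractionSummary]:
    """Analyze one session directory end to end.

    Per-field failures become exclusion reasons and never abort the run;
    a fraction whose monitoring confidence sits persistently below the
    warning threshold during beam-on is excluded wholesale.
    """
    cfg = cfg or AnalysisConfig()
    sd = Path(session_dir)
    missing = [n for n in ("plan.json", "markers_cbct.csv", "monitor_log.csv", "linac_log.csv")
               if not (sd / n).exists()]
    if missing:
        raise FileNotFoundError(f"session {sd}: missing {missing}")
    with open(sd / "plan.json") as fh:
        plan = json.load(fh)
    markers_cbct = pd.read_csv(sd / "markers_cbct.csv")[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    trace = parse_monitor_log(sd / "monitor_log.csv")
    events = parse_linac_log(sd / "linac_log.csv")
    meta = plan.get("metadata", {})
    frac = fraction_id if fraction_id is not None else sd.name
    pitch = float(plan["image"]["pitch_panel_mm"])
    size = int(plan["image"]["size_px"])
    c_f = float(np.mean(trace.confidence))

    def _summary(results: list[FieldValidation]) -> FractionSummary:
        included = [r.e_mag for r in results if not r.excluded]
        return FractionSummary(
            fraction_id=frac, c_f=c_f,
            e_f=float(np.mean(included)) if included else None,
            n_included=len(included), n_fields=len(plan["beams"]),
            marker_group=meta.get("marker_group", "negative"),
            iq_score=int(meta.get("iq_score", 3)),
            n_features_category=meta.get("n_features_category", ">5 but <10"),
        )

    def _exclude_all(reason: str) -> tuple[list[FieldValidation], FractionSummary]:
        results = [
            FieldValidation(int(b["field_id"]), frac, excluded=True, reason=reason)
            for b in plan["beams"]
        ]
        return results, _summary(results)

    try:
        offset = estimate_offset(
            trace, events, cfg.sync_resolution_s, cfg.couch_jump_threshold_mm,
            cfg.max_clock_offset_s,
        )
    except SyncError:
        return _exclude_all("sync_failure")

    # persistent low confidence during beam-on excludes the whole fraction
    beam_samples = np.zeros(len(trace), dtype=bool)
    on_t = None
    for ev in events:
        if ev.kind == "beam_on":
            on_t = ev.t
        elif ev.kind == "beam_off" and on_t is not None:
            lo, hi = on_t + offset.offset, ev.t + offset.offset
            beam_samples |= (trace.t >= lo) & (trace.t <= hi)
            on_t = None
    if beam_samples.any():
        frac_below = float(np.mean(trace.confidence[beam_samples] < cfg.confidence_threshold))
        if frac_below > cfg.low_confidence_fraction:
            return _exclude_all("low_confidence")

    results: list[FieldValidation] = []
    for b in plan["beams"]:
        fid = int(b["field_id"])
        geom = BeamGeometry(float(b["gantry_deg"]), float(b["sad_mm"]), float(b["sdd_mm"]))
        t0 = field_first_segment_time(events, fid)
        try:
            sample = motion_at(trace, t0, offset, cfg.max_hold_gap_s)
        except StaleEstimateError:
            results.append(FieldValidation(fid, frac, excluded=True, reason="sync_failure"))
            continue
        pixels = tifffile.imread(sd / f"field_{fid}.tif")
        image = PortalImage(pixels=pixels, geom=geom, t_acq=t0, field_id=fid,
                            pitch_panel=pitch)
        seg0 = b["segments"][0]
        template = make_aperture_template(seg0["aperture_iso_mm"], size, geom, pitch,
                                          segment_id=int(seg0.get("segment_id", 0)))
        translation = np.asarray(sample.translation, dtype=float)
        rng_obs = derive_rng(cfg.seed, "observers", index=fid)
        consensus, reason = _localize_image(
            image, template, markers_cbct, translation, cfg, rng_obs,
            outlier=fid in cfg.observer_outlier_fields,
        )
        if consensus is None:
            results.append(FieldValidation(fid, frac, excluded=True, reason=reason,
                                           confidence=None))
            continue
        predicted = predict_marker_positions(
            markers_cbct[[int(i) for i in consensus.marker_ids]], sample
        )
        results.append(
            compute_field_error(predicted, consensus, geom, fid, frac,
                                confidence=float(sample.confidence))
        )
    return results, _summary(results)


# ---------------------------------------------------------------------------
# multi-fraction studies


def run_study(
    pairs: Sequence[tuple[SessionConfig, AnalysisConfig]],
    workdir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate and analyze a list of fractions; returns (fields, fractions)."""
    workdir = Path(workdir)
    all_fields: list[FieldValidation] = []
    summaries: list[FractionSummary] = []
    for i, (scfg, acfg) in enumerate(pairs):
        frac = f"fx{i + 1:03d}"
        sdir = workdir / frac
        make_session(scfg, sdir)
        fields, summary = run_validation(sdir, acfg, fraction_id=frac)
        all_fields.extend(fields)
        summaries.append(summary)
    return fields_to_dataframe(all_fields), fractions_to_dataframe(summaries)


def fields_to_dataframe(fields: Sequence[FieldValidation]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(f) for f in fields])


def fractions_to_dataframe(fractions: Sequence[FractionSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(f) for f in fractions])


def study_config_pairs(
    seed: int = 0,
    n_fractions: int = 80,
    n_five_field: int = 56,
    n_outlier_fields: int = 17,
    poor_probe_fraction: int | None = 40,  # a five-field fraction
    image_size: int = 256,
    **session_overrides,
) -> list[tuple[SessionConfig, AnalysisConfig]]:
    """Configuration of the full monitored-IMRT validation study.

    The default mix (56 five-field + 24 three-field fractions = 352
    first-segment images) matches the clinical cohort; ``n_outlier_fields``
    fields get one degraded observer replicate (interobserver exclusion)
    and one fraction is monitored through a poorly placed probe
    (persistent low confidence).  Each fraction gets independent seeds
    derived from ``seed``.
    """
    if n_five_field > n_fractions:
        raise ValueError("n_five_field cannot exceed n_fractions")
    pairs: list[tuple[SessionConfig, AnalysisConfig]] = []
    outliers_left = n_outlier_fields
    for i in range(n_fractions):
        n_fields = 5 if i < n_five_field else 3
        poor = poor_probe_fraction is not None and i == poor_probe_fraction
        outlier_fields: tuple[int, ...] = ()
        if outliers_left > 0 and not poor:
            # one degraded field per fraction until the quota is spent,
            # cycling through field numbers
            outlier_fields = ((i % n_fields) + 1,)
            outliers_left -= 1
        scfg = SessionConfig(
            n_fields=n_fields,
            image_size=image_size,
            seed=derive_seed(seed, "study", index=2 * i),
            confidence=dataclasses.replace(ConfidenceModel(), poor_probe=poor),
            **session_overrides,
        )
        acfg = AnalysisConfig(
            seed=derive_seed(seed, "study", index=2 * i + 1),
            observer_outlier_fields=outlier_fields,
        )
        pairs.append((scfg, acfg))
    return pairs


# ---------------------------------------------------------------------------
# phantom precision protocol


def run_phantom_study(
    n_fractions: int = 6,
    n_fields: int = 5,
    motion_max: float = 5.0,
    seed: int = 0,
    image_size: int = 256,
    image_noise_sd: float = 30.0,
    with_flex: bool = True,
    cfg: AnalysisConfig | None = None,
    session_template: SessionConfig | None = None,
) -> PhantomResult:
    """Marker-localization precision with programmed platform motion.

    Static markers are shifted between fields by exactly known amounts
    (up to ``motion_max`` mm in all directions) standing in for the
    monitoring estimate with zero monitoring error; gantry and panel are
    repositioned (fresh random flex) each fraction.  Only the first image
    per field is analyzed, so the protocol yields
    ``n_fractions * n_fields`` images; the median 2D error and one-sided
    95% limit of agreement measure the localization chain alone.
    """
    cfg = cfg or AnalysisConfig()
    tpl = session_template or SessionConfig(image_size=image_size,
                                            image_noise_sd=image_noise_sd)
    rng = derive_rng(seed, "phantom")
    markers_cbct = np.asarray(tpl.marker_offsets_mm, dtype=float)
    poly = aperture_polygon(tpl.aperture_halfwidth_mm)
    gantries = tpl.gantry_deg if len(tpl.gantry_deg) == n_fields else \
        tuple(np.linspace(0.0, 360.0, n_fields, endpoint=False))
    errors = []
    n_images = 0
    for f in range(n_fractions):
        flex = rng.uniform(-1.8, 1.8, size=(n_fields, 2)) if with_flex else np.zeros((n_fields, 2))
        for k in range(n_fields):
            shift = rng.uniform(-motion_max, motion_max, size=3)
            geom = BeamGeometry(float(gantries[k]), tpl.sad_mm, tpl.sdd_mm,
                                flex=(float(flex[k, 0]), float(flex[k, 1])))
            template = make_aperture_template(poly, image_size, geom)
            image, _, _ = render_portal(
                markers_cbct + shift[None, :], geom, template, image_noise_sd,
                (float(flex[k, 0]), float(flex[k, 1])), rng,
                marker_fwhm_mm=tpl.marker_fwhm_mm, field_high=tpl.field_high,
                field_low=tpl.field_low, marker_depth=tpl.marker_depth,
            )
            n_images += 1
            rng_obs = derive_rng(seed, "observers", index=f * n_fields + k)
            consensus, reason = _localize_image(
                image, template, markers_cbct, shift, cfg, rng_obs
            )
            if consensus is None:  # pragma: no cover - not expected at defaults
                warnings.warn(f"phantom image {n_images} excluded ({reason})")
                continue
            fv = compute_field_error(
                markers_cbct[[int(i) for i in consensus.marker_ids]] + shift[None, :],
                consensus, geom,
            )
            if not fv.excluded:
                errors.append(fv.e_mag)
    errors = np.asarray(errors, dtype=float)
    return PhantomResult(
        median_error=float(np.median(errors)),
        loa95=float(np.quantile(errors, 0.95)),
        n_images=n_images,
    )
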