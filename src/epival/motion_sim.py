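"""Synthetic ground truth: prostate motion, a noisy monitoring oracle,
and complete simulated treatment sessions.

Prostate drift is modeled as a random walk (positional variance growing
linearly with time), sampled on a fine internal grid.  The ultrasound
monitoring system is emulated as an oracle that resamples the true
motion at ~3 Hz, adds independent Gaussian estimation noise per axis,
and attaches a confidence score from a declared surrogate model (the
vendor's confidence formula is proprietary; only its threshold behavior
at C < 0.5 matters downstream).

``make_session`` writes one fraction's worth of observable artifacts —
plan JSON, initial (CBCT-time) marker positions, monitoring log, linac
event log, one first-segment portal TIFF per field — plus a ground-truth
record used only by tests, never by the analysis pipeline.

Session timeline (linac clock): t = 0 is the CBCT reference at which the
initial marker positions are recorded and the monitoring reference is
set; monitoring starts shortly after; the couch then corrects the setup
error as a constant-speed ramp (this shared, sharp event is what clock
synchronization keys on); fields follow, each with its beam-on/off
segment events.  The monitoring log's clock runs ahead of the linac
clock by the session's (unknown to the analyzer) offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .config import PANEL_PITCH_MM, ConfidenceModel, SessionConfig, config_to_dict, derive_rng
from .geometry import BeamGeometry, project_points
from .portal_imaging import make_aperture_template, render_portal

__all__ = [
    "MotionSample",
    "MotionTrace",
    "TrueMotion",
    "ProstateState",
    "simulate_random_walk",
    "simulate_us_monitoring",
    "make_session",
    "aperture_polygon",
]


@dataclass(frozen=True)
class MotionSample:
    """One monitoring-log row: time (monitor clock), 3D motion, confidence."""

    t: float
    translation: tuple[float, float, float]  # mm, room frame
    rotation: tuple[float, float, float]  # degrees
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass
class MotionTrace:
    """A time-ordered monitoring trace at a nominal ~3 Hz rate."""

    t: np.ndarray  # (n,) s, monitor clock, strictly increasing
    translation: np.ndarray  # (n, 3) mm
    rotation: np.ndarray  # (n, 3) deg
    confidence: np.ndarray  # (n,) in [0, 1]
    rate: float = 3.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if len(self.t) == 0:
            raise ValueError("empty motion trace")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace timestamps must be strictly increasing")
        if len(self.t) > 1:
            med = float(np.median(np.diff(self.t)))
            if not 0.8 / self.rate <= med <= 1.2 / self.rate:
                raise ValueError(
                    f"median sampling interval {med:.3f}s outside 20% of 1/{self.rate}Hz"
                )

    def __len__(self) -> int:
        return len(self.t)

    def sample(self, i: int) -> MotionSample:
        return MotionSample(
            float(self.t[i]), tuple(self.translation[i]), tuple(self.rotation[i]),
            float(self.confidence[i]),
        )


@dataclass
class TrueMotion:
    """Ground-truth displacement on a fine time grid (no noise, no clock offset)."""

    t: np.ndarray  # (n,) s, linac clock
    translation: np.ndarray  # (n, 3) mm
    rotation: np.ndarray  # (n, 3) deg

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear-interpolated true translation at linac time(s) t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.stack(
            [np.interp(t, self.t, self.translation[:, k]) for k in range(3)], axis=-1
        )
        return out


@dataclass(frozen=True)
class ProstateState:
    """GPV center of mass with the three marker offsets riding on it."""

    gpv_com: tuple[float, float, float]
    rotation: tuple[float, float, float]
    marker_offsets: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.marker_offsets) != 3:
            raise ValueError("exactly 3 marker offsets required")
        off = np.asarray(self.marker_offsets, dtype=float)
        for i in range(3):
            for j in range(i + 1, 3):
                if np.linalg.norm(off[i] - off[j]) <= 2.0:
                    raise ValueError("marker pairwise separation must exceed 2 mm")

    def marker_positions(self) -> np.ndarray:
        return np.asarray(self.gpv_com, dtype=float) + np.asarray(self.marker_offsets)


def simulate_random_walk(
    duration: float,
    dt: float,
    step_sd: float,
    seed: int | np.random.Generator,
    rotation_step_sd: float = 0.0,
) -> TrueMotion:
    """Random-walk motion: cumulative Gaussian steps, variance linear in time.

    Each translation component accumulates independent N(0, step_sd^2 * dt)
    steps from zero displacement at t = 0, the discrete counterpart of a
    Wiener process with diffusion ``step_sd`` mm/sqrt(s).  Rotations are
    generated the same way with ``rotation_step_sd`` (default 0).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(np.floor(duration / dt)) + 1
    t = np.arange(n) * dt
    sd = step_sd * np.sqrt(dt)
    steps = rng.normal(0.0, sd, size=(n - 1, 3)) if sd > 0 else np.zeros((n - 1, 3))
    translation = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    rsd = rotation_step_sd * np.sqrt(dt)
    rsteps = rng.normal(0.0, rsd, size=(n - 1, 3)) if rsd > 0 else np.zeros((n - 1, 3))
    rotation = np.vstack([np.zeros(3), np.cumsum(rsteps, axis=0)])
    return TrueMotion(t=t, translation=translation, rotation=rotation)


def simulate_us_monitoring(
    true_motion: TrueMotion,
    rate: float,
    noise_sd: float,
    confidence_model: ConfidenceModel,
    seed: int | np.random.Generator,
    clock_offset: float = 0.0,
) -> MotionTrace:
    """Noisy ~rate Hz resampling of the true motion with surrogate confidence.

    Timestamps are reported on the monitor clock (= linac + clock_offset).
    """
    if len(true_motion.t) == 0:
        raise ValueError("true motion trace is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t0, t1 = float(true_motion.t[0]), float(true_motion.t[-1])
    times = np.arange(t0, t1 + 1e-9, 1.0 / rate)
    truth = true_motion.at(times)
    rot = np.stack(
        [np.interp(times, true_motion.t, true_motion.rotation[:, k]) for k in range(3)],
        axis=-1,
    )
    noise = rng.normal(0.0, noise_sd, size=truth.shape) if noise_sd > 0 else 0.0
    observed = truth + noise

    cm = confidence_model
    jitter = rng.normal(0.0, cm.jitter_sd, size=len(times)) if cm.jitter_sd > 0 else 0.0
    if cm.poor_probe:
        conf = rng.uniform(0.05, 0.45, size=len(times))
    else:
        disp = np.linalg.norm(observed, axis=-1)
        conf = np.clip(cm.baseline - cm.degradation_slope * disp + jitter, 0.0, 1.0)
    return MotionTrace(
        t=times + clock_offset, translation=observed, rotation=rot,
        confidence=conf, rate=rate,
    )


# ---------------------------------------------------------------------------
# full sessions


def aperture_polygon(halfwidth_mm: float, corner_cut: float = 0.35) -> list[list[float]]:
    """Beveled-square MLC aperture outline, (u, v) mm at isocenter scale."""
    h = halfwidth_mm
    c = corner_cut * h
    return [
        [h, h - c], [h - c, h], [-(h - c), h], [-h, h - c],
        [-h, -(h - c)], [-(h - c), -h], [h - c, -h], [h, -(h - c)],
    ]


def _field_segment_times(cfg: SessionConfig) -> list[list[tuple[float, float]]]:
    out = []
    for k in range(cfg.n_fields):
        first = cfg.first_field_time_s + k * cfg.field_gap_s
        segs = []
        for j in range(cfg.n_segments):
            on = first + j * (cfg.segment_duration_s + cfg.segment_gap_s)
            segs.append((on, on + cfg.segment_duration_s))
        out.append(segs)
    return out


def make_session(cfg: SessionConfig, out_dir: str | Path) -> dict:
    """Write one complete synthetic fraction; returns the ground-truth record.

    Artifacts: ``plan.json``, ``markers_cbct.csv``, ``monitor_log.csv``,
    ``linac_log.csv``, ``field_<k>.tif`` (one first-segment cine frame per
    field), ``ground_truth.json``.  The same configuration always yields
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed

    rng_setup = derive_rng(seed, "setup")
    # setup error measured (and corrected) at CBCT: random direction, 8-15 mm
    direction = rng_setup.normal(size=3)
    direction /= np.linalg.norm(direction)
    setup_error = direction * rng_setup.uniform(8.0, 15.0)
    couch_vector = -setup_error
    clock_offset = (
        float(rng_setup.uniform(-120.0, 120.0))
        if cfg.clock_offset_s is None
        else float(cfg.clock_offset_s)
    )

    rng_flex = derive_rng(seed, "flex")
    if cfg.flex_per_field_mm is None:
        flex = rng_flex.uniform(-1.8, 1.8, size=(cfg.n_fields, 2))
    else:
        flex = np.asarray(cfg.flex_per_field_mm, dtype=float)

    segments = _field_segment_times(cfg)
    t_end = segments[-1][-1][1] + 10.0

    # true prostate drift on a fine grid, then the couch ramp added on top
    walk = simulate_random_walk(
        t_end, 0.1, cfg.walk_step_sd, derive_rng(seed, "walk"),
        rotation_step_sd=cfg.rotation_step_sd,
    )
    c0, c1 = cfg.couch_move_start_s, cfg.couch_move_start_s + cfg.couch_move_duration_s
    ramp = np.clip((walk.t - c0) / (c1 - c0), 0.0, 1.0)[:, None]
    truth = TrueMotion(
        t=walk.t,
        translation=walk.translation + ramp * couch_vector[None, :],
        rotation=walk.rotation,
    )

    monitor_start = 5.0
    keep = truth.t >= monitor_start
    monitored = truth.translation[keep]
    if cfg.reference_time_offset_s:
        # guide-vs-CBCT mismatch: the monitoring reference was set this much
        # after the CBCT, so reported displacements miss the motion in between
        monitored = monitored - truth.at(cfg.reference_time_offset_s)
    span = TrueMotion(
        t=truth.t[keep],
        translation=monitored,
        rotation=truth.rotation[keep],
    )
    trace = simulate_us_monitoring(
        span, cfg.rate_hz, cfg.us_noise_sd, cfg.confidence,
        derive_rng(seed, "monitoring"), clock_offset=clock_offset,
    )

    # --- observable artifacts -------------------------------------------
    base_markers = np.asarray(cfg.marker_offsets_mm, dtype=float)
    markers_cbct = base_markers + setup_error[None, :]

    poly = aperture_polygon(cfg.aperture_halfwidth_mm)
    beams = []
    for k in range(cfg.n_fields):
        beams.append({
            "field_id": k + 1,
            "gantry_deg": float(cfg.gantry_deg[k]),
            "sad_mm": cfg.sad_mm,
            "sdd_mm": cfg.sdd_mm,
            "segments": [
                {"segment_id": j, "start_s": on, "stop_s": off, "aperture_iso_mm": poly}
                for j, (on, off) in enumerate(segments[k])
            ],
        })
    plan = {
        "beams": beams,
        "image": {"size_px": cfg.image_size, "pitch_panel_mm": PANEL_PITCH_MM},
        "metadata": {
            "marker_group": cfg.marker_group,
            "iq_score": cfg.iq_score,
            "n_features_category": cfg.n_features_category,
        },
    }
    with open(out / "plan.json", "w") as fh:
        json.dump(plan, fh, indent=1, sort_keys=True)

    with open(out / "markers_cbct.csv", "w") as fh:
        fh.write("id,x_mm,y_mm,z_mm\n")
        for i, m in enumerate(markers_cbct):
            fh.write(f"{i + 1},{float(m[0])!r},{float(m[1])!r},{float(m[2])!r}\n")

    with open(out / "monitor_log.csv", "w") as fh:
        fh.write("t_s,dx_mm,dy_mm,dz_mm,rx_deg,ry_deg,rz_deg,confidence\n")
        for i in range(len(trace)):
            tr = [float(v) for v in trace.translation[i]]
            ro = [float(v) for v in trace.rotation[i]]
            fh.write(
                f"{float(trace.t[i])!r},{tr[0]!r},{tr[1]!r},{tr[2]!r},"
                f"{ro[0]!r},{ro[1]!r},{ro[2]!r},{float(trace.confidence[i])!r}\n"
            )

    detail = ";".join(repr(float(v)) for v in couch_vector)
    lines = [
        (c0, "couch_move_start", "", detail),
        (c1, "couch_move_stop", "", detail),
    ]
    for k in range(cfg.n_fields):
        for on, off in segments[k]:
            lines.append((on, "beam_on", str(k + 1), ""))
            lines.append((off, "beam_off", str(k + 1), ""))
    lines.sort(key=lambda r: r[0])
    with open(out / "linac_log.csv", "w") as fh:
        fh.write("t_s,event,field_id,detail\n")
        for t, ev, fid, det in lines:
            fh.write(f"{float(t)!r},{ev},{fid},{det}\n")

    # --- portal frames at each field's first-segment time ---------------
    rng_image = derive_rng(seed, "image")
    gt_fields = []
    for k in range(cfg.n_fields):
        t_first = segments[k][0][0]
        geom = BeamGeometry(
            gantry_deg=float(cfg.gantry_deg[k]), sad=cfg.sad_mm, sdd=cfg.sdd_mm,
            flex=(float(flex[k, 0]), float(flex[k, 1])),
        )
        disp = truth.at(t_first)[0]
        markers_true = markers_cbct + disp[None, :]
        template = make_aperture_template(poly, cfg.image_size, geom)
        image, visible, uv = render_portal(
            markers_true, geom, template, cfg.image_noise_sd,
            (float(flex[k, 0]), float(flex[k, 1])), rng_image,
            t_acq=t_first, field_id=k + 1,
            marker_fwhm_mm=cfg.marker_fwhm_mm, field_high=cfg.field_high,
            field_low=cfg.field_low, marker_depth=cfg.marker_depth,
        )
        tifffile.imwrite(out / f"field_{k + 1}.tif", image.pixels)
        gt_fields.append({
            "field_id": k + 1,
            "t_first_segment_s": t_first,
            "true_displacement_mm": [float(v) for v in disp],
            "flex_mm": [float(flex[k, 0]), float(flex[k, 1])],
            "true_marker_positions_mm": markers_true.tolist(),
            "projected_uv_mm": uv.tolist(),
            "visible": [bool(v) for v in visible],
        })

    ground_truth = {
        "config": config_to_dict(cfg),
        "clock_offset_s": clock_offset,
        "setup_error_mm": [float(v) for v in setup_error],
        "couch_vector_mm": [float(v) for v in couch_vector],
        "couch_move_s": [c0, c1],
        "fields": gt_fields,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=True)
    return ground_truth
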