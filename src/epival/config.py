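"""Run configuration: schema, defaults, validation, and seed derivation.

A run is described by one document (YAML or JSON) with two blocks:

``session``   — everything the synthetic session generator needs (plan
                layout, motion/monitoring/imaging noise, clock offset),
``analysis``  — every knob of the analysis pipeline (filter scales,
                exclusion thresholds, synchronization resolution).

Unknown keys are rejected with the full field path so that typos in a
config file fail loudly instead of silently falling back to defaults.

All lengths are mm, times s, angles degrees, everywhere in the package
and in every file it reads or writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "ConfidenceModel",
    "SessionConfig",
    "AnalysisConfig",
    "RunConfig",
    "ConfigError",
    "load_config",
    "config_hash",
    "derive_seed",
    "derive_rng",
]

#: Clinical step-and-shoot IMRT gantry layouts used when none is given.
DEFAULT_GANTRIES = {3: (0.0, 120.0, 240.0), 5: (35.0, 100.0, 180.0, 260.0, 325.0)}

#: Panel pixel pitch, mm/px at panel scale (41 cm detector / 1024 px).
PANEL_PITCH_MM = 410.0 / 1024.0


class ConfigError(ValueError):
    """A configuration document violates the schema."""


@dataclass(frozen=True)
class ConfidenceModel:
    """Surrogate for the monitoring system's proprietary confidence score.

    C = clip(baseline - degradation_slope * |displacement| + jitter, 0, 1).
    With ``poor_probe`` set the whole fraction reports C below the 0.5
    warning threshold, emulating an inadequately placed probe.
    """

    baseline: float = 0.9
    degradation_slope: float = 0.005  # per mm of displacement magnitude
    jitter_sd: float = 0.05
    poor_probe: bool = False


@dataclass(frozen=True)
class SessionConfig:
    """Conditions of one simulated treatment fraction.

    The defaults reproduce the monitored-IMRT study conditions: a 5- or
    3-field step-and-shoot plan, three implanted ~1x3 mm gold markers,
    random-walk prostate motion, a ~3 Hz monitoring trace with additive
    estimation noise, per-field panel flex below 2 mm, and two log clocks
    separated by an unknown offset.
    """

    n_fields: int = 5
    gantry_deg: tuple[float, ...] | None = None
    n_segments: int = 2
    segment_duration_s: float = 8.0
    segment_gap_s: float = 4.0
    field_gap_s: float = 45.0
    first_field_time_s: float = 60.0
    couch_move_start_s: float = 30.0
    couch_move_duration_s: float = 1.0
    walk_step_sd: float = 0.3  # mm / sqrt(s)
    rotation_step_sd: float = 0.0  # deg / sqrt(s)
    us_noise_sd: float = 0.3  # mm per axis
    rate_hz: float = 3.0
    confidence: ConfidenceModel = field(default_factory=ConfidenceModel)
    clock_offset_s: float | None = None  # None: drawn uniformly in +/-120 s
    reference_time_offset_s: float = 0.0  # guide-vs-CBCT reference mismatch
    flex_per_field_mm: tuple[tuple[float, float], ...] | None = None  # None: random < 2 mm
    image_noise_sd: float = 30.0  # detector intensity units
    image_size: int = 1024
    marker_offsets_mm: tuple[tuple[float, float, float], ...] = (
        (-6.0, -4.0, 3.0),
        (7.0, -1.0, -4.0),
        (0.0, 6.0, 2.0),
    )
    marker_fwhm_mm: float = 1.5  # blob FWHM at isocenter scale
    aperture_halfwidth_mm: float = 20.0  # MLC aperture half-width at iso scale
    field_high: float = 3000.0  # in-aperture background intensity
    field_low: float = 500.0  # out-of-aperture intensity
    marker_depth: float = 1500.0  # attenuation depth of a marker blob
    sad_mm: float = 1000.0
    sdd_mm: float = 1600.0
    seed: int = 0
    # pass-through fraction labels (observer study itself is out of scope)
    marker_group: str = "negative"
    iq_score: int = 3
    n_features_category: str = ">5 but <10"

    def __post_init__(self) -> None:
        if self.n_fields not in (3, 5):
            raise ConfigError(
                f"session.n_fields: must be 3 or 5 (step-and-shoot IMRT plans), got {self.n_fields}"
            )
        if self.gantry_deg is None:
            object.__setattr__(self, "gantry_deg", DEFAULT_GANTRIES[self.n_fields])
        if len(self.gantry_deg) != self.n_fields:
            raise ConfigError(
                f"session.gantry_deg: expected {self.n_fields} angles, got {len(self.gantry_deg)}"
            )
        if self.flex_per_field_mm is not None:
            if len(self.flex_per_field_mm) != self.n_fields:
                raise ConfigError("session.flex_per_field_mm: one (fu, fv) pair per field required")
            for f in self.flex_per_field_mm:
                if max(abs(f[0]), abs(f[1])) > 5.0:
                    raise ConfigError(f"session.flex_per_field_mm: |flex| {f} exceeds 5 mm")
        if len(self.marker_offsets_mm) != 3:
            raise ConfigError("session.marker_offsets_mm: exactly 3 markers required")
        off = np.asarray(self.marker_offsets_mm, dtype=float)
        for i in range(3):
            for j in range(i + 1, 3):
                if np.linalg.norm(off[i] - off[j]) <= 2.0:
                    raise ConfigError("session.marker_offsets_mm: pairwise separation must exceed 2 mm")
        for name in ("rate_hz", "image_size", "n_segments",
                     "segment_duration_s", "couch_move_duration_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"session.{name}: must be positive")
        for name in ("walk_step_sd", "us_noise_sd", "image_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"session.{name}: must be non-negative")
        if self.iq_score not in (1, 2, 3, 4):
            raise ConfigError("session.iq_score: must be 1-4")
        if self.marker_group not in ("positive", "negative"):
            raise ConfigError("session.marker_group: must be 'positive' or 'negative'")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable of the analysis pipeline, with study defaults."""

    observer_count: int = 3
    observer_noise_sd_mm: float = 0.3  # per-axis localization spread of a replicate
    observer_outlier_fields: tuple[int, ...] = ()  # fields where one replicate is degraded
    observer_outlier_offset_mm: float = 2.5
    interobserver_threshold_mm: float = 1.5
    log_sigma_mm: float = 1.0  # LoG Gaussian SD at isocenter scale
    log_extent_mm: float = 3.5  # LoG kernel width at isocenter scale
    min_separation_mm: float = 2.0
    detection_snr: float = 6.0  # robust threshold multiplier on filtered noise
    edge_margin_mm: float = 5.0  # keep detections this far inside the aperture
    confidence_threshold: float = 0.5
    low_confidence_fraction: float = 0.9  # "consistently below" operationalized
    sync_resolution_s: float = 0.1
    couch_jump_threshold_mm: float = 1.0  # per-axis jump flag in the monitor trace
    max_clock_offset_s: float = 600.0
    max_hold_gap_s: float = 2.0
    flex_search_mm: float = 5.0
    flex_min_peak: float = 0.5
    threshold_quantile: float | None = None  # None: midpoint of in/out field medians
    loa_levels: tuple[int, ...] = (25, 50, 75, 95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.observer_count < 2:
            raise ConfigError("analysis.observer_count: at least 2 replicates required")
        if not 0 < self.low_confidence_fraction <= 1:
            raise ConfigError("analysis.low_confidence_fraction: must be in (0, 1]")
        if self.sync_resolution_s <= 0:
            raise ConfigError("analysis.sync_resolution_s: must be positive")


@dataclass(frozen=True)
class RunConfig:
    """One self-contained description of a simulate-and-analyze run."""

    seed: int = 0
    session: SessionConfig = field(default_factory=SessionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


# ---------------------------------------------------------------------------
# document -> dataclass with unknown-key rejection


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name: f for f in dc_fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        sub = f"{path}.{key}" if path else key
        if key == "confidence":
            kwargs[key] = _build(ConfidenceModel, value, sub)
        elif key == "session":
            kwargs[key] = _build(SessionConfig, value, sub)
        elif key == "analysis":
            kwargs[key] = _build(AnalysisConfig, value, sub)
        elif isinstance(value, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or cls.__name__}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON run configuration, validating the full schema."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return _build(RunConfig, data, "")


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dc_fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def config_to_dict(cfg) -> dict:
    return _as_plain(cfg)


def config_hash(cfg) -> str:
    """Stable hash of a configuration document (for run manifests)."""
    blob = json.dumps(_as_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# seed fan-out

#: Named random streams; one global seed fans out through SeedSequence spawn
#: keys so each component is independently reproducible.
_STREAMS = {
    "walk": 0,
    "monitoring": 1,
    "setup": 2,
    "flex": 3,
    "image": 4,
    "observers": 5,
    "phantom": 6,
    "study": 7,
}


def derive_seed(root_seed: int, stream: str, index: int = 0) -> int:
    """Deterministic sub-seed (< 2**31) for a named component stream."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(_STREAMS[stream], index))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def derive_rng(root_seed: int, stream: str, index: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(root_seed, spawn_key=(_STREAMS[stream], index))
    return np.random.default_rng(ss)
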