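"""Shared fixtures: beam geometries, synthetic traces, small sessions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epival.config import ConfidenceModel, SessionConfig
from epival.log_sync import LinacEvent
from epival.motion_sim import TrueMotion, make_session, simulate_random_walk, simulate_us_monitoring

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MARKERS = np.array([[-6.0, -4.0, 3.0], [7.0, -1.0, -4.0], [0.0, 6.0, 2.0]])


@pytest.fixture(scope="session")
def geom0():
    from epival.geometry import BeamGeometry

    return BeamGeometry(gantry_deg=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_trace_with_couch(
    clock_offset: float,
    seed: int,
    couch_mag: tuple[float, float] = (8.0, 15.0),
    couch_start: float = 30.0,
    couch_duration: float = 1.0,
    duration: float = 300.0,
    walk_sd: float = 0.3,
    noise_sd: float = 0.3,
):
    """A monitoring trace containing one couch correction, plus its linac events."""
    rng = np.random.default_rng(seed)
    walk = simulate_random_walk(duration, 0.1, walk_sd, np.random.default_rng(seed + 7))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    couch = d * rng.uniform(*couch_mag)
    c0, c1 = couch_start, couch_start + couch_duration
    ramp = np.clip((walk.t - c0) / (c1 - c0), 0.0, 1.0)[:, None]
    truth = TrueMotion(walk.t, walk.translation + ramp * couch, walk.rotation)
    trace = simulate_us_monitoring(
        truth, 3.0, noise_sd, ConfidenceModel(), np.random.default_rng(seed + 13),
        clock_offset=clock_offset,
    )
    events = [
        LinacEvent(c0, "couch_move_start", None, tuple(couch)),
        LinacEvent(c1, "couch_move_stop", None, tuple(couch)),
    ]
    return trace, events, couch, truth


def quiet_session_config(seed: int = 3, n_fields: int = 3, **overrides) -> SessionConfig:
    """A session with every stochastic disturbance switched off."""
    defaults = dict(
        n_fields=n_fields,
        image_size=256,
        seed=seed,
        walk_step_sd=0.0,
        us_noise_sd=0.0,
        image_noise_sd=0.0,
        flex_per_field_mm=tuple((0.0, 0.0) for _ in range(n_fields)),
        clock_offset_s=17.3,
        confidence=ConfidenceModel(baseline=1.0, degradation_slope=0.0, jitter_sd=0.0),
    )
    defaults.update(overrides)
    return SessionConfig(**defaults)


@pytest.fixture(scope="session")
def quiet_session(tmp_path_factory):
    """A rendered noise-free session on disk, with its ground truth."""
    cfg = quiet_session_config()
    out = tmp_path_factory.mktemp("quiet_session")
    gt = make_session(cfg, out)
    return out, gt, cfg


@pytest.fixture(scope="session")
def default_session(tmp_path_factory):
    """A rendered session at the study's default noise conditions."""
    cfg = SessionConfig(n_fields=5, image_size=256, seed=21, clock_offset_s=-42.0)
    out = tmp_path_factory.mktemp("default_session")
    gt = make_session(cfg, out)
    return out, gt, cfg
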