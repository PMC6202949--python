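"""Log parsing and clock synchronization between monitor and linac.

The monitoring log and the linac event log run on different clocks with
an unknown, constant offset.  Couch corrections are visible in both: the
linac log records couch_move_start/stop events, and the monitor trace
shows the same move as a fast, large excursion of the reported target
position.  The offset is recovered by cross-correlating couch-activity
indicator series from both logs at a fixed resolution, then refined
below the sampling grid by fitting the known constant-speed couch ramp
to the monitored displacement projected on the couch direction.

Field timing: portal frames are tied to the linac clock through beam-on
events; the motion estimate for a field is the last monitor sample at or
before the field's first-segment beam-on time (zero-order hold), and an
estimate older than a configurable gap is treated as stale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .motion_sim import MotionSample, MotionTrace

__all__ = [
    "LinacEvent",
    "ClockOffset",
    "MalformedLogError",
    "SyncError",
    "StaleEstimateError",
    "parse_monitor_log",
    "parse_linac_log",
    "estimate_offset",
    "field_first_segment_time",
    "motion_at",
]

_MONITOR_COLUMNS = [
    "t_s", "dx_mm", "dy_mm", "dz_mm", "rx_deg", "ry_deg", "rz_deg", "confidence",
]


class MalformedLogError(ValueError):
    """A log file violates its declared format."""


class SyncError(RuntimeError):
    """Clock synchronization failed; the session is unusable."""


class StaleEstimateError(RuntimeError):
    """No sufficiently recent monitoring sample at the requested time."""


@dataclass(frozen=True)
class LinacEvent:
    """One linac log row (linac clock)."""

    t: float
    kind: str  # couch_move_start | couch_move_stop | beam_on | beam_off
    field_id: int | None = None
    detail: tuple[float, float, float] | None = None  # couch vector, mm


@dataclass(frozen=True)
class ClockOffset:
    """Estimated monitor-minus-linac clock offset with its uncertainty."""

    offset: float  # s
    uncertainty: float  # s

    def __post_init__(self) -> None:
        if abs(self.offset) >= 600.0:
            raise ValueError("clock offset beyond the 600 s plausibility bound")


def parse_monitor_log(path: str | Path, rate: float = 3.0) -> MotionTrace:
    """Read a monitoring-log CSV into a validated MotionTrace.

    Confidence values outside [0, 1] are clipped with a warning;
    non-monotone timestamps or missing columns raise MalformedLogError.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MONITOR_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedLogError(f"monitor log {path}: missing column(s) {missing}")
    t = df["t_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise MalformedLogError(f"monitor log {path}: timestamps not strictly increasing")
    conf = df["confidence"].to_numpy(float)
    if np.any((conf < 0) | (conf > 1)):
        warnings.warn("confidence values outside [0, 1] clipped")
        conf = np.clip(conf, 0.0, 1.0)
    return MotionTrace(
        t=t,
        translation=df[["dx_mm", "dy_mm", "dz_mm"]].to_numpy(float),
        rotation=df[["rx_deg", "ry_deg", "rz_deg"]].to_numpy(float),
        confidence=conf,
        rate=rate,
    )


def parse_linac_log(path: str | Path) -> list[LinacEvent]:
    """Read a linac event-log CSV (t_s,event,field_id,detail)."""
    df = pd.read_csv(path, dtype={"detail": str}, keep_default_na=False)
    for col in ("t_s", "event", "field_id", "detail"):
        if col not in df.columns:
            raise MalformedLogError(f"linac log {path}: missing column {col}")
    events = []
    for _, row in df.iterrows():
        fid = row["field_id"]
        field_id = int(fid) if str(fid).strip() != "" else None
        det = str(row["detail"]).strip()
        detail = tuple(float(v) for v in det.split(";")) if det else None
        events.append(LinacEvent(float(row["t_s"]), str(row["event"]), field_id, detail))
    if any(events[i].t > events[i + 1].t for i in range(len(events) - 1)):
        raise MalformedLogError(f"linac log {path}: events not time-ordered")
    return events


def _couch_intervals(events: Sequence[LinacEvent]) -> list[tuple[float, float, np.ndarray]]:
    out = []
    start: LinacEvent | None = None
    for ev in events:
        if ev.kind == "couch_move_start":
            start = ev
        elif ev.kind == "couch_move_stop" and start is not None:
            vec = np.asarray(ev.detail if ev.detail else start.detail or (1.0, 0.0, 0.0))
            out.append((start.t, ev.t, vec))
            start = None
    return out


def estimate_offset(
    trace: MotionTrace,
    linac_events: Sequence[LinacEvent],
    resolution: float = 0.1,
    jump_threshold: float = 1.0,
    max_offset: float = 600.0,
) -> ClockOffset:
    """Recover the monitor-minus-linac clock offset from couch activity.

    Coarse stage: samples whose per-axis position jump exceeds
    ``jump_threshold`` mark couch activity in the monitor trace; an
    indicator series (jump magnitudes spread over their sampling
    intervals) is cross-correlated against the linac couch intervals at
    ``resolution``, and the lag of the maximum is the coarse offset.

    Refinement: for the largest couch move, the monitored displacement
    projected on the couch direction is fit by the known constant-speed
    ramp plus a local linear baseline, scanning the ramp timing on a fine
    grid; this interpolates the event timing below the ~3 Hz sampling
    grid.  Raises SyncError when either log shows no couch move.
    """
    moves = _couch_intervals(linac_events)
    if not moves:
        raise SyncError("linac log contains no couch move")
    w = 3  # samples per side of the step statistic (~1 s at 3 Hz)
    if len(trace) < 2 * w + 1:
        raise SyncError("monitor trace too short to detect a couch move")
    # sustained level shift across each inter-sample boundary: mean of the
    # next w samples minus mean of the previous w.  A couch correction gives
    # ~ its full vector; reverting noise spikes and slow drift stay small.
    csum = np.vstack([np.zeros(3), np.cumsum(trace.translation, axis=0)])
    n_s = len(trace)
    idx = np.arange(w - 1, n_s - w)  # boundary between samples i and i+1
    pre = (csum[idx + 1] - csum[idx + 1 - w]) / w
    post = (csum[idx + 1 + w] - csum[idx + 1]) / w
    step = np.linalg.norm(post - pre, axis=1)
    flagged = step > 2.0 * jump_threshold
    if not np.any(flagged):
        raise SyncError("no couch-move step detected in the monitor trace")

    # --- coarse lag via indicator cross-correlation ---------------------
    res = resolution
    t_mon0 = trace.t[0]
    n_mon = int(np.ceil((trace.t[-1] - t_mon0) / res)) + 1
    mon = np.zeros(n_mon)
    for j in np.flatnonzero(flagged):
        i = int(idx[j])
        a = int(np.floor((trace.t[i] - t_mon0) / res))
        b = int(np.ceil((trace.t[i + 1] - t_mon0) / res))
        b = max(b, a + 1)
        mon[a:b] += (step[j] - jump_threshold) / (b - a)

    t_lin0 = min(m[0] for m in moves)
    t_lin1 = max(m[1] for m in moves)
    n_lin = int(np.ceil((t_lin1 - t_lin0) / res)) + 1
    lin = np.zeros(n_lin)
    for s0, s1, vec in moves:
        a = int(np.floor((s0 - t_lin0) / res))
        b = max(int(np.ceil((s1 - t_lin0) / res)), a + 1)
        lin[a:b] += float(np.linalg.norm(vec)) / (b - a)

    corr = fftconvolve(mon, lin[::-1], mode="full")
    lags = np.arange(-(n_lin - 1), n_mon) * res + (t_mon0 - t_lin0)
    ok = np.abs(lags) <= max_offset
    if not np.any(ok):
        raise SyncError("no admissible lag within the offset bound")
    coarse = float(lags[ok][np.argmax(corr[ok])])

    # --- sub-sample refinement on the strongest couch ramp ---------------
    s0, s1, vec = max(moves, key=lambda m: float(np.linalg.norm(m[2])))
    mag = float(np.linalg.norm(vec))
    direction = vec / mag
    duration = s1 - s0
    flank = max(3.0, 2 * duration)
    sel = (trace.t >= s0 + coarse - flank) & (trace.t <= s1 + coarse + flank)
    if sel.sum() >= 6:
        ts = trace.t[sel]
        p = trace.translation[sel] @ direction
        candidates = np.arange(coarse - 1.0, coarse + 1.0 + 1e-9, 0.01)
        design0 = np.stack([np.ones_like(ts), ts - ts.mean()], axis=1)
        best_sse, best = np.inf, coarse
        for off in candidates:
            ramp = np.clip((ts - (s0 + off)) / duration, 0.0, 1.0) * mag
            resid = p - ramp
            beta, *_ = np.linalg.lstsq(design0, resid, rcond=None)
            sse = float(np.sum((resid - design0 @ beta) ** 2))
            if sse < best_sse:
                best_sse, best = sse, float(off)
        offset = best
    else:  # pragma: no cover - degenerate window, fall back to coarse
        offset = coarse
    return ClockOffset(offset=offset, uncertainty=res)


def field_first_segment_time(linac_events: Sequence[LinacEvent], field_id: int) -> float:
    """Linac time of the first beam-on event for the given field."""
    times = [ev.t for ev in linac_events if ev.kind == "beam_on" and ev.field_id == field_id]
    if not times:
        raise KeyError(f"field {field_id} has no beam_on event in the linac log")
    return min(times)


def motion_at(trace: MotionTrace, t_linac: float, offset: ClockOffset | float,
              max_gap: float = 2.0) -> MotionSample:
    """Monitoring estimate at a linac time: hold-last-sample semantics.

    The linac time is converted to the monitor clock and the latest
    sample at or before it is returned; a gap larger than ``max_gap``
    raises StaleEstimateError.
    """
    off = offset.offset if isinstance(offset, ClockOffset) else float(offset)
    t_mon = t_linac + off
    idx = int(np.searchsorted(trace.t, t_mon + 1e-12, side="right")) - 1
    if idx < 0:
        raise StaleEstimateError(f"no monitoring sample at or before t={t_mon:.2f}s")
    gap = t_mon - trace.t[idx]
    if gap > max_gap:
        raise StaleEstimateError(f"latest monitoring sample is {gap:.1f}s old (> {max_gap}s)")
    return trace.sample(idx)
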