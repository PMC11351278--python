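"""I-VT gaze-event detection.

Each sample gets an angular velocity from the surrounding +/-10 ms of
movement (two-point: first vs. last valid sample in the window, visual
angle over elapsed time).  Samples below the 30 deg/s threshold are
fixation, at or above it saccade, and samples that are invalid or have
no computable velocity are unclassified.  Runs of identical annotations
become candidate events; same-kind candidates separated by no more than
``max_merge_gap_ms`` are combined; candidates shorter than the minimum
fixation (60 ms) or saccade (30 ms) duration are relabelled unclassified.

Sample occupancy convention: a sample at time ``t`` occupies
``[t, t + 1/rate)``, so an event's duration is ``n_samples / rate`` at a
uniform rate and abutting events share a boundary without overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .gaze_io import ScreenGeometry, proportion_to_pixels, visual_angle_deg

__all__ = [
    "EventDetectionConfig",
    "GazeEvent",
    "FIXATION",
    "SACCADE",
    "UNCLASSIFIED",
    "LABEL_NAMES",
    "compute_sample_velocity",
    "annotate_samples",
    "segment_and_merge",
    "summarize_event",
    "detect_events",
    "events_to_frame",
    "frame_to_events",
    "truncate_event",
]

FIXATION, SACCADE, UNCLASSIFIED = 0, 1, 2
LABEL_NAMES = {FIXATION: "fixation", SACCADE: "saccade", UNCLASSIFIED: "unclassified"}


@dataclass(frozen=True)
class EventDetectionConfig:
    velocity_threshold_deg_s: float = 30.0
    velocity_half_window_ms: float = 10.0
    min_fixation_ms: float = 60.0
    min_saccade_ms: float = 30.0
    #: Merge same-kind candidates across gaps up to this long (0 = only
    #: literally successive annotations merge, the strict reading).
    max_merge_gap_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.velocity_threshold_deg_s <= 0:
            raise ValueError("velocity_threshold_deg_s must be > 0")
        for name in ("velocity_half_window_ms", "min_fixation_ms", "min_saccade_ms", "max_merge_gap_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GazeEvent:
    """One detected fixation or saccade with its per-event summaries.

    ``amplitude_deg`` is the visual angle between the first and last valid
    sample positions; ``direction_deg`` is the displacement angle folded
    to [0, 90] degrees from the horizontal axis (saccades);
    ``rms_dispersion_px`` is the RMS sample distance from the centroid
    (fixations).  ``amplitude_px`` keeps the same displacement in pixel
    units for the configurable amplitude-unit switch downstream.
    """

    kind: str
    t_start: float
    t_end: float
    duration_ms: float
    n_samples: int
    centroid_x_px: float
    centroid_y_px: float
    amplitude_deg: float
    amplitude_px: float
    mean_velocity_deg_s: float
    peak_velocity_deg_s: float
    rms_dispersion_px: float
    direction_deg: float


# ---------------------------------------------------------------------------
# per-sample velocity and annotation
# ---------------------------------------------------------------------------

def compute_sample_velocity(
    samples: pd.DataFrame, geometry: ScreenGeometry, cfg: EventDetectionConfig = EventDetectionConfig()
) -> np.ndarray:
    """Angular velocity (deg/s) per sample; NaN where undefined.

    The velocity at a valid sample is the visual angle between the first
    and the last valid sample inside ``[t - hw, t + hw]`` divided by
    their time separation; it is undefined (NaN) for invalid samples and
    when fewer than two valid samples fall in the window.
    """
    n = len(samples)
    if n == 0:
        return np.empty(0, dtype=float)
    t = samples["t_sec"].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy(dtype=bool)
    x_px, y_px = proportion_to_pixels(samples["x_prop"].to_numpy(dtype=float),
                                      samples["y_prop"].to_numpy(dtype=float), geometry)

    hw = cfg.velocity_half_window_ms / 1000.0
    lo = np.searchsorted(t, t - hw, side="left")
    hi = np.searchsorted(t, t + hw, side="right")  # exclusive

    idx = np.arange(n)
    # first valid index at or after j, last valid index at or before j
    first_from = np.minimum.accumulate(np.where(valid, idx, n)[::-1])[::-1]
    first_from = np.append(first_from, n)
    last_upto = np.maximum.accumulate(np.where(valid, idx, -1))

    first = first_from[lo]
    last = last_upto[hi - 1]
    defined = valid & (first < last)

    v = np.full(n, np.nan)
    if defined.any():
        f = first[defined]
        l = last[defined]
        ang = visual_angle_deg((x_px[f], y_px[f]), (x_px[l], y_px[l]), geometry)
        v[defined] = np.asarray(ang) / (t[l] - t[f])
    return v


def annotate_samples(velocities: np.ndarray, cfg: EventDetectionConfig = EventDetectionConfig()) -> np.ndarray:
    """Label each sample fixation (< threshold), saccade (>= threshold) or unclassified (NaN)."""
    v = np.asarray(velocities, dtype=float)
    labels = np.full(v.shape, UNCLASSIFIED, dtype=np.int8)
    defined = np.isfinite(v)
    labels[defined & (v < cfg.velocity_threshold_deg_s)] = FIXATION
    labels[defined & (v >= cfg.velocity_threshold_deg_s)] = SACCADE
    return labels


# ---------------------------------------------------------------------------
# segmentation and merging
# ---------------------------------------------------------------------------

def _label_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of identical labels as (label, i_start, i_end_inclusive)."""
    n = len(labels)
    if n == 0:
        return []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries - 1, [n - 1]))
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def _merge_candidates(
    candidates: Sequence[tuple[int, list[tuple[int, int]]]],
    t: np.ndarray,
    dt: float,
    max_gap_ms: float,
) -> list[tuple[int, list[tuple[int, int]]]]:
    """Combine consecutive same-kind candidates whose time gap is <= max_gap_ms.

    A candidate is (kind, [(i0, i1), ...]) carrying its member sample runs;
    merging never crosses a candidate of the other kind.
    """
    merged: list[tuple[int, list[tuple[int, int]]]] = []
    for kind, runs in candidates:
        if merged:
            prev_kind, prev_runs = merged[-1]
            gap_s = t[runs[0][0]] - (t[prev_runs[-1][1]] + dt)
            if kind == prev_kind and gap_s <= max_gap_ms / 1000.0 + 1e-12:
                merged[-1] = (prev_kind, prev_runs + list(runs))
                continue
        merged.append((kind, list(runs)))
    return merged


def segment_and_merge(
    labels: np.ndarray,
    samples: pd.DataFrame,
    geometry: ScreenGeometry,
    cfg: EventDetectionConfig = EventDetectionConfig(),
    velocities: np.ndarray | None = None,
) -> tuple[list[GazeEvent], np.ndarray]:
    """Turn sample annotations into merged, duration-screened events.

    Returns the time-ordered event list and a per-sample membership array
    (event index, or -1 for samples belonging to no surviving event).
    Candidates shorter than the kind's minimum duration are relabelled
    unclassified, keeping the three-way sample partition well defined.
    """
    t = samples["t_sec"].to_numpy(dtype=float)
    dt = geometry.sample_period_s
    if velocities is None:
        velocities = compute_sample_velocity(samples, geometry, cfg)

    candidates = [(kind, [(s, e)]) for kind, s, e in _label_runs(np.asarray(labels)) if kind != UNCLASSIFIED]
    candidates = _merge_candidates(candidates, t, dt, cfg.max_merge_gap_ms)

    events: list[GazeEvent] = []
    membership = np.full(len(samples), -1, dtype=np.int64)
    for kind, runs in candidates:
        dur_ms = sum((t[i1] + dt - t[i0]) for i0, i1 in runs) * 1000.0
        min_ms = cfg.min_fixation_ms if kind == FIXATION else cfg.min_saccade_ms
        if dur_ms < min_ms - 1e-9:
            continue  # relabelled unclassified
        member_idx = np.concatenate([np.arange(i0, i1 + 1) for i0, i1 in runs])
        event = summarize_event(LABEL_NAMES[kind], samples.iloc[member_idx], geometry,
                                velocities=np.asarray(velocities)[member_idx], dt=dt)
        membership[member_idx] = len(events)
        events.append(event)
    return events, membership


def summarize_event(
    kind: str,
    event_samples: pd.DataFrame,
    geometry: ScreenGeometry,
    velocities: np.ndarray | None = None,
    dt: float | None = None,
) -> GazeEvent:
    """Per-event summaries from the event's member samples.

    Positions use valid samples only; a fixation needs >= 1 and a saccade
    >= 2 valid samples.  Velocity statistics are over the defined sample
    velocities within the event.
    """
    if dt is None:
        dt = geometry.sample_period_s
    t = event_samples["t_sec"].to_numpy(dtype=float)
    valid = event_samples["valid"].to_numpy(dtype=bool)
    x_px, y_px = proportion_to_pixels(event_samples["x_prop"].to_numpy(dtype=float),
                                      event_samples["y_prop"].to_numpy(dtype=float), geometry)
    xv, yv = x_px[valid], y_px[valid]
    min_needed = 1 if kind == "fixation" else 2
    if len(xv) < min_needed:
        raise ValueError(f"{kind} event needs >= {min_needed} valid samples, got {len(xv)}")

    cx, cy = float(np.mean(xv)), float(np.mean(yv))
    rms = float(np.sqrt(np.mean((xv - cx) ** 2 + (yv - cy) ** 2)))
    if len(xv) >= 2:
        amplitude = float(visual_angle_deg((xv[0], yv[0]), (xv[-1], yv[-1]), geometry))
        amplitude_px = float(np.hypot(xv[-1] - xv[0], yv[-1] - yv[0]))
        dx_cm = (xv[-1] - xv[0]) / geometry.px_per_cm_x
        dy_cm = (yv[-1] - yv[0]) / geometry.px_per_cm_y
        if dx_cm == 0.0 and dy_cm == 0.0:
            direction = 0.0
        else:
            direction = float(np.degrees(np.arctan2(abs(dy_cm), abs(dx_cm))))
    else:
        amplitude = amplitude_px = direction = 0.0

    if velocities is not None:
        vv = np.asarray(velocities, dtype=float)
        vv = vv[np.isfinite(vv)]
    else:
        vv = np.empty(0)
    mean_v = float(np.mean(vv)) if vv.size else 0.0
    peak_v = float(np.max(vv)) if vv.size else 0.0

    t_start = float(t[0])
    t_end = float(t[-1] + dt)
    return GazeEvent(
        kind=kind,
        t_start=t_start,
        t_end=t_end,
        duration_ms=(t_end - t_start) * 1000.0,
        n_samples=int(len(t)),
        centroid_x_px=cx,
        centroid_y_px=cy,
        amplitude_deg=amplitude,
        amplitude_px=amplitude_px,
        mean_velocity_deg_s=mean_v,
        peak_velocity_deg_s=peak_v,
        rms_dispersion_px=rms,
        direction_deg=direction,
    )


def detect_events(
    samples: pd.DataFrame, geometry: ScreenGeometry, cfg: EventDetectionConfig = EventDetectionConfig()
) -> tuple[list[GazeEvent], np.ndarray, np.ndarray, np.ndarray]:
    """Full I-VT pass: returns (events, velocities, labels, membership)."""
    velocities = compute_sample_velocity(samples, geometry, cfg)
    labels = annotate_samples(velocities, cfg)
    events, membership = segment_and_merge(labels, samples, geometry, cfg, velocities=velocities)
    return events, velocities, labels, membership


def events_to_frame(events: Sequence[GazeEvent]) -> pd.DataFrame:
    """Events as a tidy frame (the detect-events CSV layout)."""
    cols = [
        "kind", "t_start", "t_end", "duration_ms", "n_samples",
        "centroid_x_px", "centroid_y_px", "amplitude_deg", "amplitude_px",
        "mean_velocity_deg_s", "peak_velocity_deg_s", "rms_dispersion_px", "direction_deg",
    ]
    return pd.DataFrame([{c: getattr(ev, c) for c in cols} for ev in events], columns=cols)


def frame_to_events(frame: pd.DataFrame) -> list[GazeEvent]:
    """Inverse of :func:`events_to_frame`."""
    return [GazeEvent(**{k: (str(v) if k == "kind" else (int(v) if k == "n_samples" else float(v)))
                         for k, v in row.items()})
            for row in frame.to_dict(orient="records")]


def truncate_event(event: GazeEvent, t_lo: float, t_hi: float) -> GazeEvent | None:
    """Clip an event to [t_lo, t_hi]; duration is recomputed, other summaries kept.

    Returns None when the event does not overlap the span.
    """
    t_start = max(event.t_start, t_lo)
    t_end = min(event.t_end, t_hi)
    if t_end <= t_start:
        return None
    if t_start == event.t_start and t_end == event.t_end:
        return event
    return replace(event, t_start=t_start, t_end=t_end, duration_ms=(t_end - t_start) * 1000.0)
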