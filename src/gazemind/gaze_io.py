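"""Reading and writing gaze-sample and thought-probe logs.

Gaze logs are comma-delimited UTF-8 text with a header row and columns
``t_sec,x_prop,y_prop``: one row per sample, timestamps in seconds
(strictly increasing within a file), coordinates as screen proportions in
[0, 1].  A missing coordinate (blink / off-screen) is an empty field or a
NaN token; such samples are carried through as invalid rather than
dropped, because their durations matter downstream.

Probe logs have columns ``participant,session,t_sec,q1..q9,task_text``:
one row per thought probe, with nine Likert ratings in 1..7 (missing
allowed) and a free-text description of the self-selected task.

The module also owns the screen geometry: proportions are converted to
pixels, and pixel displacements to visual angle via the two-point formula
``2*atan(d_cm / (2*D))`` at viewing distance ``D``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "GazeLogError",
    "GAZE_COLUMNS",
    "PROBE_RATING_COLUMNS",
    "PROBE_COLUMNS",
    "read_gaze_samples",
    "write_gaze_samples",
    "read_probe_log",
    "write_probe_log",
    "proportion_to_pixels",
    "pixels_to_cm",
    "visual_angle_deg",
]

GAZE_COLUMNS = ("t_sec", "x_prop", "y_prop")
PROBE_RATING_COLUMNS = tuple(f"q{i}" for i in range(1, 10))
PROBE_COLUMNS = ("participant", "session", "t_sec") + PROBE_RATING_COLUMNS + ("task_text",)

#: String tokens accepted as a missing coordinate / rating.
_MISSING_TOKENS = {"", "nan", "na"}


class GazeLogError(ValueError):
    """Malformed, out-of-range or mis-ordered content in a gaze/probe log."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Recording geometry: screen size, resolution and viewing distance.

    The physical screen size is required to express gaze velocity in
    degrees of visual angle; the defaults describe a 24-inch 16:9 monitor
    viewed from 60 cm with a 250 Hz sampler.  Pixel pitch is kept per-axis
    so non-square pixels are handled correctly.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 53.1
    height_cm: float = 29.9
    viewing_distance_cm: float = 60.0
    sampling_rate_hz: float = 250.0

    def __post_init__(self) -> None:
        for name in (
            "width_px",
            "height_px",
            "width_cm",
            "height_cm",
            "viewing_distance_cm",
            "sampling_rate_hz",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be finite and > 0, got {value!r}")

    @property
    def px_per_cm_x(self) -> float:
        return self.width_px / self.width_cm

    @property
    def px_per_cm_y(self) -> float:
        return self.height_px / self.height_cm

    @property
    def sample_period_s(self) -> float:
        return 1.0 / self.sampling_rate_hz


# ---------------------------------------------------------------------------
# coordinate conversions
# ---------------------------------------------------------------------------

def proportion_to_pixels(x_prop, y_prop, geometry: ScreenGeometry):
    """Convert screen proportions in [0, 1] to pixel coordinates.

    Accepts scalars or arrays; NaNs (missing samples) pass through.
    Raises :class:`GazeLogError` if any finite input lies outside [0, 1].
    """
    x = np.asarray(x_prop, dtype=float)
    y = np.asarray(y_prop, dtype=float)
    for arr, name in ((x, "x_prop"), (y, "y_prop")):
        finite = np.isfinite(arr)
        if np.any((arr[finite] < 0) | (arr[finite] > 1)):
            raise GazeLogError(f"{name} outside [0, 1]")
    x_px = x * geometry.width_px
    y_px = y * geometry.height_px
    if np.ndim(x_prop) == 0 and np.ndim(y_prop) == 0:
        return float(x_px), float(y_px)
    return x_px, y_px


def pixels_to_cm(x_px, y_px, geometry: ScreenGeometry):
    """Convert pixel coordinates to centimetres on screen (per-axis pitch)."""
    return (
        np.asarray(x_px, dtype=float) / geometry.px_per_cm_x,
        np.asarray(y_px, dtype=float) / geometry.px_per_cm_y,
    )


def visual_angle_deg(p1, p2, geometry: ScreenGeometry):
    """Visual angle in degrees subtended between two on-screen pixel points.

    ``p1``/``p2`` are ``(x_px, y_px)`` pairs (scalars or aligned arrays).
    The separation is converted px -> cm per axis and the angle is
    ``2*atan(d_cm / (2*D))`` with ``D`` the viewing distance; zero
    separation gives exactly 0.
    """
    x1, y1 = p1
    x2, y2 = p2
    dx_cm = (np.asarray(x2, dtype=float) - np.asarray(x1, dtype=float)) / geometry.px_per_cm_x
    dy_cm = (np.asarray(y2, dtype=float) - np.asarray(y1, dtype=float)) / geometry.px_per_cm_y
    d_cm = np.hypot(dx_cm, dy_cm)
    angle = np.degrees(2.0 * np.arctan2(d_cm, 2.0 * geometry.viewing_distance_cm))
    if np.ndim(angle) == 0:
        return float(angle)
    return angle


# ---------------------------------------------------------------------------
# gaze-sample logs
# ---------------------------------------------------------------------------

def _parse_float_column(raw: pd.Series, column: str, allow_missing: bool) -> np.ndarray:
    values = pd.to_numeric(raw.str.strip(), errors="coerce").to_numpy(dtype=float)
    missing_token = raw.str.strip().str.lower().isin(_MISSING_TOKENS).to_numpy()
    bad = np.isnan(values) & ~missing_token
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
        raise GazeLogError(f"line {line}: malformed value {raw.iloc[int(np.flatnonzero(bad)[0])]!r} in column {column!r}")
    if not allow_missing and (np.isnan(values)).any():
        line = int(np.flatnonzero(np.isnan(values))[0]) + 2
        raise GazeLogError(f"line {line}: missing value in required column {column!r}")
    return values


def read_gaze_samples(path) -> pd.DataFrame:
    """Read a gaze log into a frame with columns t_sec, x_prop, y_prop, valid.

    Rows keep file order; strictly increasing timestamps are enforced.
    A sample is ``valid`` iff both coordinates are present; invalid
    samples keep NaN coordinates.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in GAZE_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise GazeLogError(f"gaze log missing columns {missing_cols}")
    t = _parse_float_column(raw["t_sec"], "t_sec", allow_missing=False)
    x = _parse_float_column(raw["x_prop"], "x_prop", allow_missing=True)
    y = _parse_float_column(raw["y_prop"], "y_prop", allow_missing=True)
    if len(t) > 1:
        non_mono = np.flatnonzero(np.diff(t) <= 0)
        if non_mono.size:
            line = int(non_mono[0]) + 3  # offending (second) row, one-based with header
            raise GazeLogError(f"line {line}: timestamps not strictly increasing")
    valid = np.isfinite(x) & np.isfinite(y)
    for arr, name in ((x, "x_prop"), (y, "y_prop")):
        finite = np.isfinite(arr)
        if np.any((arr[finite] < 0) | (arr[finite] > 1)):
            line = int(np.flatnonzero(finite & ((arr < 0) | (arr > 1)))[0]) + 2
            raise GazeLogError(f"line {line}: {name} outside [0, 1]")
    return pd.DataFrame({"t_sec": t, "x_prop": x, "y_prop": y, "valid": valid})


def write_gaze_samples(samples: pd.DataFrame, path) -> None:
    """Write a gaze frame in the canonical dialect (missing coordinate = empty field)."""
    out = samples.loc[:, ["t_sec", "x_prop", "y_prop"]].copy()
    out.to_csv(path, index=False, float_format="%.17g", na_rep="")


# ---------------------------------------------------------------------------
# probe logs
# ---------------------------------------------------------------------------

def read_probe_log(path) -> pd.DataFrame:
    """Read a thought-probe log, sorted by probe time within participant/session.

    Ratings are nullable integers in 1..7 (column order q1..q9 is the
    order the probe questions were asked in); out-of-range ratings raise
    :class:`GazeLogError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in PROBE_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise GazeLogError(f"probe log missing columns {missing_cols}")
    out = pd.DataFrame({
        "participant": raw["participant"].str.strip(),
        "session": raw["session"].str.strip(),
        "t_sec": _parse_float_column(raw["t_sec"], "t_sec", allow_missing=False),
    })
    for col in PROBE_RATING_COLUMNS:
        values = _parse_float_column(raw[col], col, allow_missing=True)
        finite = np.isfinite(values)
        in_range = np.isin(values[finite], np.arange(1, 8))
        if not in_range.all():
            bad_idx = np.flatnonzero(finite)[np.flatnonzero(~in_range)[0]]
            raise GazeLogError(
                f"line {int(bad_idx) + 2}: rating {values[bad_idx]!r} in column {col!r} outside 1..7"
            )
        out[col] = pd.array(values, dtype="Int64")
    out["task_text"] = raw["task_text"]
    out = out.sort_values(["participant", "session", "t_sec"], kind="stable")
    return out.reset_index(drop=True)


def write_probe_log(probes: pd.DataFrame, path) -> None:
    """Write a probe frame in the canonical dialect (missing rating = empty field)."""
    out = probes.loc[:, list(PROBE_COLUMNS)].copy()
    out.to_csv(path, index=False, na_rep="")
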