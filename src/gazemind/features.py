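"""The 29 global oculomotor features of a pre-probe window.

Stimulus-independent statistics only: fixation-duration summaries
(count, mean, median, min, max, range, std, RMSD), saccade-duration
summaries (count + the six statistics), saccade-amplitude and
saccade-velocity summaries (six statistics each), the fixation-saccade
count ratio, and the horizontal-saccade count.  Durations are in ms,
amplitudes in degrees of visual angle (pixel units available as a
config switch), velocities in deg/s.

Windows with no events of one kind get all-zero summaries for that
family so the feature vector stays finite; std is the sample (n-1)
standard deviation, zero for fewer than two values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_builder import TrialWindow

__all__ = [
    "StatSummary",
    "FeatureConfig",
    "FEATURE_NAMES",
    "N_FEATURES",
    "stat_summary",
    "compute_features",
    "horizontal_saccade_count",
    "fixation_rmsd_feature",
]

_STATS = ("mean", "median", "min", "max", "range", "std")

FEATURE_NAMES: tuple[str, ...] = (
    ("fixation_count",)
    + tuple(f"fixation_duration_{s}" for s in _STATS)
    + ("fixation_rmsd",)
    + ("saccade_count",)
    + tuple(f"saccade_duration_{s}" for s in _STATS)
    + tuple(f"saccade_amplitude_{s}" for s in _STATS)
    + tuple(f"saccade_velocity_{s}" for s in _STATS)
    + ("fixation_saccade_ratio", "horizontal_saccade_count")
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 29


@dataclass(frozen=True)
class StatSummary:
    mean: float
    median: float
    min: float
    max: float
    range: float
    std: float


@dataclass(frozen=True)
class FeatureConfig:
    """Switches for the conventions the feature set leaves open.

    ``horizontal_tolerance_deg``: a saccade counts as horizontal when its
    direction lies within this many degrees of the horizontal axis.
    ``rmsd_mode``: 'spatial' = mean per-fixation RMS distance from the
    centroid (px); 'duration' = RMS of the fixation durations (ms).
    ``velocity_stat``: per-saccade velocity summarized from the saccade's
    mean ('mean') or peak ('peak') sample velocity.
    ``amplitude_units``: 'deg' (visual angle) or 'px'.
    """

    horizontal_tolerance_deg: float = 30.0
    rmsd_mode: str = "spatial"
    velocity_stat: str = "mean"
    amplitude_units: str = "deg"

    def __post_init__(self) -> None:
        if self.rmsd_mode not in ("spatial", "duration"):
            raise ValueError(f"rmsd_mode must be 'spatial' or 'duration', got {self.rmsd_mode!r}")
        if self.velocity_stat not in ("mean", "peak"):
            raise ValueError(f"velocity_stat must be 'mean' or 'peak', got {self.velocity_stat!r}")
        if self.amplitude_units not in ("deg", "px"):
            raise ValueError(f"amplitude_units must be 'deg' or 'px', got {self.amplitude_units!r}")


def stat_summary(values) -> StatSummary:
    """Mean/median/min/max/range/sample-std of a value list; all 0 when empty.

    Values are sorted before summation so the result is bit-identical
    under any permutation of the input.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        return StatSummary(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    vmin, vmax = float(np.min(v)), float(np.max(v))
    return StatSummary(float(np.mean(v)), float(np.median(v)), vmin, vmax, vmax - vmin, std)


def horizontal_saccade_count(saccades, angle_tolerance_deg: float = 30.0) -> int:
    """Saccades whose direction is within the tolerance of horizontal."""
    return int(sum(1 for s in saccades if s.direction_deg <= angle_tolerance_deg))


def fixation_rmsd_feature(fixations, mode: str = "spatial") -> float:
    """Fixation RMSD: mean per-fixation spatial RMS dispersion, or RMS of durations."""
    if mode == "spatial":
        if not fixations:
            return 0.0
        return float(np.mean(np.sort([f.rms_dispersion_px for f in fixations])))
    if mode == "duration":
        if not fixations:
            return 0.0
        return float(np.sqrt(np.mean(np.sort([f.duration_ms**2 for f in fixations]))))
    raise ValueError(f"unknown rmsd mode {mode!r}")


def compute_features(window: TrialWindow, cfg: FeatureConfig = FeatureConfig()) -> pd.Series:
    """The 29-entry feature vector of one screened trial window."""
    fixations = window.fixations
    saccades = window.saccades

    fix_dur = stat_summary([f.duration_ms for f in fixations])
    sac_dur = stat_summary([s.duration_ms for s in saccades])
    amp_attr = "amplitude_deg" if cfg.amplitude_units == "deg" else "amplitude_px"
    sac_amp = stat_summary([getattr(s, amp_attr) for s in saccades])
    vel_attr = "mean_velocity_deg_s" if cfg.velocity_stat == "mean" else "peak_velocity_deg_s"
    sac_vel = stat_summary([getattr(s, vel_attr) for s in saccades])

    values = (
        (float(len(fixations)),)
        + tuple(getattr(fix_dur, s) for s in _STATS)
        + (fixation_rmsd_feature(fixations, cfg.rmsd_mode),)
        + (float(len(saccades)),)
        + tuple(getattr(sac_dur, s) for s in _STATS)
        + tuple(getattr(sac_amp, s) for s in _STATS)
        + tuple(getattr(sac_vel, s) for s in _STATS)
        + (
            len(fixations) / max(len(saccades), 1),
            float(horizontal_saccade_count(saccades, cfg.horizontal_tolerance_deg)),
        )
    )
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)
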