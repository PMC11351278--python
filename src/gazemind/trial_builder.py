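"""Pre-probe trial windows, label dichotomization and inclusion filters.

Every thought probe labels the 12 s of gaze immediately preceding it.
The nine Likert ratings (1..7) are dichotomized per dimension: 1-3 maps
to the low-end class, 5-7 to the high-end class, and the mid-scale 4 (or
a missing rating) is discarded for that dimension only.  Windows in
which too large a fraction of samples belongs to no fixation/saccade
event (off-screen gaze, blinks) are screened out, and a participant
enters a dimension's classification only with at least 10 kept trials
in each class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .event_detection import GazeEvent, truncate_event

__all__ = [
    "ThoughtDimension",
    "DIMENSIONS",
    "DIMENSION_NAMES",
    "CLASS_LOW",
    "CLASS_HIGH",
    "DISCARDED",
    "TrialWindow",
    "extract_window",
    "dichotomize",
    "screen_trial",
    "apply_inclusion",
]

CLASS_LOW = "low"
CLASS_HIGH = "high"
DISCARDED = "discarded"


@dataclass(frozen=True)
class ThoughtDimension:
    """One rated dimension of ongoing thought and its class polarity.

    ``low_class`` names the 1-end of the Likert scale and ``high_class``
    the 7-end.  Only the task question's polarity is canonical (1-3 =
    on-task); the other dimensions use the first-mentioned pole of their
    probe question as the 1-end, and the table is plain data that callers
    may replace.
    """

    name: str
    low_class: str
    high_class: str
    question_index: int  # 1-based probe question number (column q<i>)


DIMENSIONS: tuple[ThoughtDimension, ...] = (
    ThoughtDimension("task_relatedness", "on_task", "off_task", 1),
    ThoughtDimension("internal_external", "internal", "external", 2),
    ThoughtDimension("freely_moving", "not_freely_moving", "freely_moving", 3),
    ThoughtDimension("goal_directed", "not_goal_directed", "goal_directed", 4),
    ThoughtDimension("sticky", "not_sticky", "sticky", 5),
    ThoughtDimension("self_oriented", "not_self_oriented", "self_oriented", 6),
    ThoughtDimension("others_oriented", "not_others_oriented", "others_oriented", 7),
    ThoughtDimension("visual", "not_visual", "visual", 8),
    ThoughtDimension("auditory", "not_auditory", "auditory", 9),
)
DIMENSION_NAMES: tuple[str, ...] = tuple(d.name for d in DIMENSIONS)
_BY_NAME = {d.name: d for d in DIMENSIONS}


def get_dimension(name: str) -> ThoughtDimension:
    return _BY_NAME[name]


@dataclass
class TrialWindow:
    """A 12 s pre-probe window: clipped events plus data-quality and labels."""

    participant: str
    session: str
    t_probe: float
    t_start: float
    t_end: float
    events: list[GazeEvent]
    unclassified_fraction: float
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def fixations(self) -> list[GazeEvent]:
        return [e for e in self.events if e.kind == "fixation"]

    @property
    def saccades(self) -> list[GazeEvent]:
        return [e for e in self.events if e.kind == "saccade"]


def extract_window(
    events: Sequence[GazeEvent],
    samples: pd.DataFrame,
    t_probe: float,
    width_s: float = 12.0,
    membership: np.ndarray | None = None,
    participant: str = "",
    session: str = "",
) -> TrialWindow:
    """Cut the ``[t_probe - width_s, t_probe]`` window out of a session.

    Events straddling a boundary are truncated (duration recomputed,
    other summaries kept); the unclassified fraction is the share of the
    span's samples covered by no surviving fixation/saccade event.
    Raises ValueError when the probe falls earlier than ``width_s`` after
    the first sample.
    """
    t = samples["t_sec"].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValueError("cannot extract a window from an empty sample stream")
    t_lo = t_probe - width_s
    if t_lo < t[0] - 1e-9:
        raise ValueError(
            f"probe at t={t_probe} is earlier than {width_s} s after session start ({t[0]})"
        )
    clipped = [ev for ev in (truncate_event(e, t_lo, t_probe) for e in events) if ev is not None]

    in_span = (t >= t_lo) & (t < t_probe)
    n_span = int(in_span.sum())
    if n_span == 0:
        unclassified = 1.0
    elif membership is not None:
        unclassified = float(np.mean(np.asarray(membership)[in_span] < 0))
    else:
        covered = np.zeros(n_span, dtype=bool)
        ts = t[in_span]
        for ev in clipped:
            covered |= (ts >= ev.t_start) & (ts < ev.t_end)
        unclassified = float(np.mean(~covered))
    return TrialWindow(
        participant=participant,
        session=session,
        t_probe=float(t_probe),
        t_start=float(t_lo),
        t_end=float(t_probe),
        events=clipped,
        unclassified_fraction=unclassified,
    )


def dichotomize(rating, dimension: ThoughtDimension) -> str:
    """Map a 1..7 Likert rating to the dimension's binary class.

    1-3 -> low-end class, 5-7 -> high-end class, 4 or missing ->
    discarded.  Out-of-range ratings raise ValueError.
    """
    if rating is None or (isinstance(rating, float) and np.isnan(rating)) or rating is pd.NA:
        return DISCARDED
    value = int(rating)
    if value != rating or not 1 <= value <= 7:
        raise ValueError(f"rating {rating!r} outside 1..7 for dimension {dimension.name}")
    if value <= 3:
        return CLASS_LOW
    if value == 4:
        return DISCARDED
    return CLASS_HIGH


def screen_trial(window: TrialWindow, max_unclassified_fraction: float = 0.5) -> bool:
    """Keep the trial iff its unclassified fraction does not exceed the cap."""
    return window.unclassified_fraction <= max_unclassified_fraction


def apply_inclusion(
    trials: pd.DataFrame, min_per_class: int = 10
) -> dict[str, set[str]]:
    """Participants with >= min_per_class kept trials in BOTH classes, per dimension.

    ``trials`` needs columns participant, dimension, label (low/high;
    discarded rows are ignored).
    """
    included: dict[str, set[str]] = {}
    usable = trials[trials["label"].isin([CLASS_LOW, CLASS_HIGH])]
    for dimension, group in usable.groupby("dimension"):
        counts = group.groupby(["participant", "label"]).size().unstack(fill_value=0)
        for cls in (CLASS_LOW, CLASS_HIGH):
            if cls not in counts.columns:
                counts[cls] = 0
        ok = counts[(counts[CLASS_LOW] >= min_per_class) & (counts[CLASS_HIGH] >= min_per_class)]
        included[str(dimension)] = set(ok.index.astype(str))
    for d in DIMENSION_NAMES:
        included.setdefault(d, set())
    return included


def label_trials(
    windows: Iterable[TrialWindow],
    probes: pd.DataFrame,
    dimensions: Sequence[ThoughtDimension] = DIMENSIONS,
) -> None:
    """Fill each window's label map from its probe row (matched on keys).

    ``probes`` is the probe-log frame; matching is on (participant,
    session, t_sec ~= t_probe).
    """
    key = {(str(r.participant), str(r.session), round(float(r.t_sec), 6)): r
           for r in probes.itertuples(index=False)}
    for w in windows:
        row = key.get((w.participant, w.session, round(w.t_probe, 6)))
        if row is None:
            raise KeyError(f"no probe record for window at t={w.t_probe} ({w.participant}/{w.session})")
        for dim in dimensions:
            rating = getattr(row, f"q{dim.question_index}")
            w.labels[dim.name] = dichotomize(rating, dim)
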