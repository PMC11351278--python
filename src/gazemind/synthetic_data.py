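"""Synthetic gaze streams, probe schedules and labeled cohorts.

The generator emulates what the analysis consumes, not the physiology
that produced it: an alternating fixation/saccade renewal process at
250 Hz with Gaussian fixation jitter, gamma-distributed saccade
amplitudes, a main-sequence peak velocity (a * amplitude^b) shaped by a
raised-cosine profile, and Poisson missing-data episodes.  Probe
schedules follow the experience-sampling design (35 probes per session
at uniform 90-150 s intervals).  A cohort draws, per probe and thought
dimension, a latent binary state; under the null the gaze trace is
generated independently of every state, while an effect spec scales the
scanpath parameters inside the 12 s pre-probe window according to the
state, planting a learnable class signal with the reported directions.

Everything is driven by ``numpy.random.Generator`` (PCG64) seeds, so a
fixed seed reproduces a cohort byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gaze_io import ScreenGeometry, write_gaze_samples, write_probe_log
from .trial_builder import DIMENSION_NAMES

__all__ = [
    "ScanpathParams",
    "ParamShift",
    "ClassEffectSpec",
    "DEFAULT_EFFECTS",
    "CohortSpec",
    "CohortData",
    "generate_trace",
    "schedule_probes",
    "generate_cohort",
    "export_cohort",
    "generate_feature_cohort",
]


@dataclass(frozen=True)
class ScanpathParams:
    """Parameters of the alternating fixation/saccade scanpath process.

    Magnitudes are plausible for screen viewing and chosen so that a
    30 deg/s velocity threshold separates the two motion regimes; they
    are stand-ins, not estimates of any real dataset.
    """

    fixation_median_ms: float = 250.0
    fixation_sigma: float = 0.4  # lognormal sigma, log units
    saccade_amp_shape: float = 3.0
    saccade_amp_scale_deg: float = 2.0
    #: amplitudes are truncated below this so every saccade's +/-10 ms
    #: smoothed velocity clears the detection threshold for long enough
    #: to survive the minimum-duration rule
    saccade_amp_min_deg: float = 3.0
    main_seq_a: float = 75.0  # deg/s per deg^b
    main_seq_b: float = 0.6
    min_saccade_duration_ms: float = 44.0
    fixation_jitter_px: float = 3.0
    missing_rate_per_min: float = 2.0
    missing_duration_ms: tuple[float, float] = (100.0, 400.0)
    #: probability a saccade is aimed along the horizontal axis
    horizontal_bias: float = 0.5


@dataclass(frozen=True)
class ParamShift:
    """Multiplicative shifts applied to ScanpathParams for one class.

    The identity shift (all 1.0) is the null model.
    """

    fixation_duration_scale: float = 1.0
    saccade_amplitude_scale: float = 1.0
    velocity_scale: float = 1.0  # scales the main-sequence coefficient a
    horizontal_bias_scale: float = 1.0

    def is_identity(self) -> bool:
        return all(
            getattr(self, f) == 1.0
            for f in ("fixation_duration_scale", "saccade_amplitude_scale",
                      "velocity_scale", "horizontal_bias_scale")
        )


def apply_shift(params: ScanpathParams, shift: ParamShift) -> ScanpathParams:
    return replace(
        params,
        fixation_median_ms=params.fixation_median_ms * shift.fixation_duration_scale,
        saccade_amp_scale_deg=params.saccade_amp_scale_deg * shift.saccade_amplitude_scale,
        main_seq_a=params.main_seq_a * shift.velocity_scale,
        horizontal_bias=float(np.clip(params.horizontal_bias * shift.horizontal_bias_scale, 0.0, 1.0)),
    )


#: dimension -> shift applied in class-high pre-probe windows (class-low
#: windows use the base parameters).  Directions follow the reported
#: class-wise gaze differences; magnitudes (2-8 % parameter shifts) are
#: calibrated so classification lands in the moderate-MCC regime typical
#: of probe-caught thought decoding rather than in a separable limit.
#: Where a
#: reported direction pair is not jointly expressible in a fixed window
#: (e.g. more *and* longer fixations), the duration direction is kept.
ClassEffectSpec = Mapping[str, ParamShift]

DEFAULT_EFFECTS: dict[str, ParamShift] = {
    "task_relatedness": ParamShift(fixation_duration_scale=1.08),
    "internal_external": ParamShift(velocity_scale=1.03, horizontal_bias_scale=1.25),
    "freely_moving": ParamShift(fixation_duration_scale=0.93, saccade_amplitude_scale=0.94),
    "goal_directed": ParamShift(velocity_scale=0.975, fixation_duration_scale=1.05),
    "sticky": ParamShift(fixation_duration_scale=1.07, saccade_amplitude_scale=0.94),
    "self_oriented": ParamShift(velocity_scale=1.025, fixation_duration_scale=1.05),
    "others_oriented": ParamShift(velocity_scale=0.97),
    "visual": ParamShift(saccade_amplitude_scale=0.94, velocity_scale=0.975),
    "auditory": ParamShift(saccade_amplitude_scale=1.06, velocity_scale=1.025),
}


@dataclass(frozen=True)
class CohortSpec:
    """Structure of a simulated experience-sampling cohort."""

    n_participants: int = 7
    n_sessions: int = 7
    probes_per_session: int = 35
    probe_interval_s: tuple[float, float] = (90.0, 150.0)
    session_pad_s: float = 0.0
    window_s: float = 12.0
    #: probability a rating lands on the discarded mid-scale value 4
    mid_scale_rate: float = 0.1
    #: marginal probability of the high-end latent state, per dimension
    high_state_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_interval_s[0] < self.window_s:
            raise ValueError("probe interval lower bound must be >= window_s")
        if min(self.n_participants, self.n_sessions, self.probes_per_session) < 1:
            raise ValueError("cohort counts must be positive")


@dataclass
class CohortData:
    """An in-memory simulated cohort.

    ``traces`` maps a trace key to a gaze-sample frame; ``probes`` is a
    probe-log frame with an extra ``trace_key`` column tying each probe
    to the trace holding its pre-probe window; ``truth`` records the
    latent binary state per probe and dimension; ``truth_events`` the
    ground-truth segmentation per trace.
    """

    traces: dict[str, pd.DataFrame]
    probes: pd.DataFrame
    truth: pd.DataFrame
    truth_events: dict[str, pd.DataFrame]
    spec: CohortSpec
    geometry: ScreenGeometry


# ---------------------------------------------------------------------------
# single-trace generation
# ---------------------------------------------------------------------------

def _raised_cosine_positions(n: int) -> np.ndarray:
    """Cumulative displacement fractions at samples 1..n of a raised-cosine
    velocity profile (s(u) = u - sin(2*pi*u)/(2*pi), s(1) = 1)."""
    u = np.arange(1, n + 1) / n
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def generate_trace(
    params: ScanpathParams,
    duration_s: float,
    geometry: ScreenGeometry,
    rng: np.random.Generator,
    t0: float = 0.0,
    start_xy_px: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[float, float]]:
    """One alternating fixation/saccade trace with its ground truth.

    Returns (samples, truth_events, end_position).  Samples are spaced
    exactly 1/rate apart starting at ``t0``; truth events tile the trace
    (every sample belongs to exactly one fixation or saccade).  Missing
    episodes overwrite ``valid`` without altering the truth segmentation.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    dt = geometry.sample_period_s
    n_total = int(round(duration_s / dt))
    deg_to_cm = lambda a_deg: 2.0 * geometry.viewing_distance_cm * math.tan(math.radians(a_deg) / 2.0)

    margin_px = 10.0
    if start_xy_px is None:
        pos = np.array([geometry.width_px / 2.0, geometry.height_px / 2.0])
    else:
        pos = np.array(start_xy_px, dtype=float)

    xs = np.empty(n_total)
    ys = np.empty(n_total)
    truth_rows: list[tuple[str, int, int]] = []  # (kind, i0, n)
    i = 0
    fixating = True
    while i < n_total:
        if fixating:
            dur_ms = float(np.exp(rng.normal(math.log(params.fixation_median_ms), params.fixation_sigma)))
            n = max(1, int(round(dur_ms / 1000.0 / dt)))
            n = min(n, n_total - i)
            xs[i:i + n] = pos[0] + rng.normal(0.0, params.fixation_jitter_px, n)
            ys[i:i + n] = pos[1] + rng.normal(0.0, params.fixation_jitter_px, n)
            truth_rows.append(("fixation", i, n))
        else:
            amp_deg = max(params.saccade_amp_min_deg,
                          float(rng.gamma(params.saccade_amp_shape, params.saccade_amp_scale_deg)))
            d_cm = deg_to_cm(amp_deg)
            # pick a landing point inside the screen; fall back toward centre
            for _ in range(20):
                if rng.random() < params.horizontal_bias:
                    theta = rng.normal(0.0, 0.2) + (0.0 if rng.random() < 0.5 else math.pi)
                else:
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                delta = np.array([
                    math.cos(theta) * d_cm * geometry.px_per_cm_x,
                    math.sin(theta) * d_cm * geometry.px_per_cm_y,
                ])
                target = pos + delta
                if (margin_px <= target[0] <= geometry.width_px - margin_px
                        and margin_px <= target[1] <= geometry.height_px - margin_px):
                    break
            else:
                centre = np.array([geometry.width_px / 2.0, geometry.height_px / 2.0])
                direction = centre - pos
                direction /= max(np.linalg.norm(direction), 1.0)
                target = pos + direction * d_cm * geometry.px_per_cm_x
            peak_v = params.main_seq_a * amp_deg**params.main_seq_b
            dur_s = max(2.0 * amp_deg / peak_v, params.min_saccade_duration_ms / 1000.0)
            n = max(2, int(round(dur_s / dt)))
            n = min(n, n_total - i)
            frac = _raised_cosine_positions(n)
            xs[i:i + n] = pos[0] + frac * (target[0] - pos[0])
            ys[i:i + n] = pos[1] + frac * (target[1] - pos[1])
            truth_rows.append(("saccade", i, n))
            pos = target
        i += n
        fixating = not fixating

    valid = np.ones(n_total, dtype=bool)
    n_missing = rng.poisson(params.missing_rate_per_min * duration_s / 60.0)
    for _ in range(n_missing):
        m_start = rng.uniform(0.0, duration_s)
        m_dur = rng.uniform(*params.missing_duration_ms) / 1000.0
        j0 = int(m_start / dt)
        j1 = min(n_total, j0 + max(1, int(round(m_dur / dt))))
        valid[j0:j1] = False

    t = t0 + np.arange(n_total) * dt
    xs = np.clip(xs, 0.0, geometry.width_px)
    ys = np.clip(ys, 0.0, geometry.height_px)
    samples = pd.DataFrame({
        "t_sec": t,
        "x_prop": np.where(valid, xs / geometry.width_px, np.nan),
        "y_prop": np.where(valid, ys / geometry.height_px, np.nan),
        "valid": valid,
    })
    truth = pd.DataFrame(
        [
            {
                "kind": kind,
                "t_start": t0 + i0 * dt,
                "t_end": t0 + (i0 + n) * dt,
                "n_samples": n,
            }
            for kind, i0, n in truth_rows
        ]
    )
    return samples, truth, (float(pos[0]), float(pos[1]))


# ---------------------------------------------------------------------------
# probe schedules and cohorts
# ---------------------------------------------------------------------------

def schedule_probes(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Probe times for one session: i.i.d. uniform gaps, fixed probe count."""
    gaps = rng.uniform(spec.probe_interval_s[0], spec.probe_interval_s[1],
                       size=spec.probes_per_session)
    return spec.session_pad_s + np.cumsum(gaps)


def _draw_rating(latent_high: bool, mid_rate: float, rng: np.random.Generator) -> int:
    if rng.random() < mid_rate:
        return 4
    return int(rng.integers(5, 8)) if latent_high else int(rng.integers(1, 4))


def generate_cohort(
    spec: CohortSpec = CohortSpec(),
    effects: ClassEffectSpec | None = None,
    geometry: ScreenGeometry = ScreenGeometry(),
    params: ScanpathParams = ScanpathParams(),
    windows_only: bool = False,
    rng: np.random.Generator | None = None,
) -> CohortData:
    """Simulate a full cohort of gaze traces, probes and latent truth.

    ``effects=None`` is the null model: latent states and ratings are
    drawn, but gaze is generated from the base parameters everywhere, so
    labels are independent of the trace.  With an effect spec, the 12 s
    pre-probe segment of each probe is generated from parameters scaled
    by the product of the shifts of all latent-high dimensions.

    ``windows_only=True`` synthesizes gaze only inside the pre-probe
    windows (one trace per probe) -- the spans between probes are never
    read by the analysis, so this is purely a problem-size reduction.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    traces: dict[str, pd.DataFrame] = {}
    truth_events: dict[str, pd.DataFrame] = {}
    probe_rows = []
    truth_rows = []

    for p in range(spec.n_participants):
        pid = f"p{p + 1:02d}"
        for s in range(spec.n_sessions):
            sid = f"s{s + 1:02d}"
            probe_times = schedule_probes(spec, rng)
            latents = rng.random((spec.probes_per_session, len(DIMENSION_NAMES))) < spec.high_state_prob

            session_traces: list[pd.DataFrame] = []
            session_truths: list[pd.DataFrame] = []
            pos: tuple[float, float] | None = None
            t_cursor = 0.0
            for k, t_probe in enumerate(probe_times):
                shifted = params
                if effects is not None:
                    shift = ParamShift()
                    for d_idx, dim in enumerate(DIMENSION_NAMES):
                        if dim in effects and latents[k, d_idx]:
                            e = effects[dim]
                            shift = ParamShift(
                                fixation_duration_scale=shift.fixation_duration_scale * e.fixation_duration_scale,
                                saccade_amplitude_scale=shift.saccade_amplitude_scale * e.saccade_amplitude_scale,
                                velocity_scale=shift.velocity_scale * e.velocity_scale,
                                horizontal_bias_scale=shift.horizontal_bias_scale * e.horizontal_bias_scale,
                            )
                    shifted = apply_shift(params, shift)

                if windows_only:
                    key = f"{pid}_{sid}_w{k:03d}"
                    win, truth, pos = generate_trace(
                        shifted, spec.window_s, geometry, rng,
                        t0=t_probe - spec.window_s, start_xy_px=pos,
                    )
                    traces[key] = win
                    truth_events[key] = truth
                else:
                    key = f"{pid}_{sid}"
                    lead = (t_probe - spec.window_s) - t_cursor
                    if lead > geometry.sample_period_s:
                        seg, truth, pos = generate_trace(params, lead, geometry, rng,
                                                         t0=t_cursor, start_xy_px=pos)
                        session_traces.append(seg)
                        session_truths.append(truth)
                        t_cursor += len(seg) * geometry.sample_period_s
                    seg, truth, pos = generate_trace(shifted, spec.window_s, geometry, rng,
                                                     t0=t_cursor, start_xy_px=pos)
                    session_traces.append(seg)
                    session_truths.append(truth)
                    t_cursor += len(seg) * geometry.sample_period_s

                ratings = {
                    f"q{d_idx + 1}": _draw_rating(bool(latents[k, d_idx]), spec.mid_scale_rate, rng)
                    for d_idx in range(len(DIMENSION_NAMES))
                }
                probe_rows.append({
                    "participant": pid, "session": sid,
                    "t_sec": float(t_probe), **ratings,
                    "task_text": "self-selected computer task",
                    "trace_key": key if windows_only else f"{pid}_{sid}",
                })
                for d_idx, dim in enumerate(DIMENSION_NAMES):
                    truth_rows.append({
                        "participant": pid, "session": sid, "t_probe": float(t_probe),
                        "dimension": dim, "latent_high": bool(latents[k, d_idx]),
                    })

            if not windows_only:
                key = f"{pid}_{sid}"
                traces[key] = pd.concat(session_traces, ignore_index=True)
                truth_events[key] = pd.concat(session_truths, ignore_index=True)

    probes = pd.DataFrame(probe_rows)
    truth = pd.DataFrame(truth_rows)
    return CohortData(traces=traces, probes=probes, truth=truth,
                      truth_events=truth_events, spec=spec, geometry=geometry)


def export_cohort(cohort: CohortData, out_dir) -> None:
    """Write gaze, probe and ground-truth CSVs for a generated cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, trace in cohort.traces.items():
        write_gaze_samples(trace, out / f"gaze_{key}.csv")
        cohort.truth_events[key].to_csv(out / f"truth_events_{key}.csv", index=False)
    probes = cohort.probes.drop(columns=["trace_key"])
    write_probe_log(probes, out / "probes.csv")
    cohort.probes[["participant", "session", "t_sec", "trace_key"]].to_csv(
        out / "trace_keys.csv", index=False)
    cohort.truth.to_csv(out / "truth_states.csv", index=False)


# ---------------------------------------------------------------------------
# feature-level cohorts (planted-signal benchmarks)
# ---------------------------------------------------------------------------

def generate_feature_cohort(
    n_participants: int,
    n_trials_per_class: int,
    n_features: int = 29,
    informative: tuple[int, ...] = tuple(range(10)),
    effect_size: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Synthetic feature matrices with a known informative subset.

    Features are standard normal; the ``informative`` columns are shifted
    by ``effect_size`` in the high class, all others carry no signal.
    This bypasses gaze simulation so a test can control exactly which
    features are informative (gaze-derived features are correlated
    within families and cannot plant an exact subset).
    """
    if rng is None:
        rng = np.random.default_rng()
    cohort = {}
    info = np.asarray(informative, dtype=int)
    for p in range(n_participants):
        n = 2 * n_trials_per_class
        y = np.repeat([0, 1], n_trials_per_class)
        X = rng.normal(size=(n, n_features))
        X[np.ix_(y == 1, info)] += effect_size
        cohort[f"p{p + 1:02d}"] = (X, y)
    return cohort
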