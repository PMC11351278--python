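"""I-VT velocity estimation, annotation, segmentation and merging."""

import numpy as np
import pandas as pd
import pytest

from gazemind import (
    EventDetectionConfig,
    ScreenGeometry,
    annotate_samples,
    compute_sample_velocity,
    detect_events,
    segment_and_merge,
    summarize_event,
    visual_angle_deg,
)
from gazemind.event_detection import (
    FIXATION,
    SACCADE,
    UNCLASSIFIED,
    _label_runs,
    _merge_candidates,
    truncate_event,
)

from conftest import make_samples, uniform_times


def stationary_samples(n, geometry, x=0.5, y=0.5):
    return make_samples(uniform_times(n), np.full(n, x), np.full(n, y))


class TestSampleVelocity:
    def test_stationary_gaze_zero_velocity(self, geometry):
        samples = stationary_samples(20, geometry)
        v = compute_sample_velocity(samples, geometry)
        assert np.allclose(v, 0.0)

    def test_invalid_sample_velocity_undefined(self, geometry):
        samples = stationary_samples(10, geometry)
        samples.loc[4, ["x_prop", "y_prop"]] = np.nan
        samples.loc[4, "valid"] = False
        v = compute_sample_velocity(samples, geometry)
        assert np.isnan(v[4]) and np.isfinite(v[3])

    def test_constant_ramp_hits_threshold_velocity(self, geometry):
        # gaze crosses 0.6 deg of visual angle in 20 ms -> 30 deg/s everywhere
        n = 21
        total_deg = 0.6 * (n - 1) * 4 / 20  # constant angular rate, 30 deg/s
        d_cm = 2 * geometry.viewing_distance_cm * np.tan(np.radians(total_deg) / 2)
        x_px = np.linspace(0, d_cm * geometry.px_per_cm_x, n)
        samples = make_samples(uniform_times(n), x_px / geometry.width_px, np.full(n, 0.5))
        v = compute_sample_velocity(samples, geometry)
        assert v[n // 2] == pytest.approx(30.0, rel=1e-3)

    def test_empty_input(self, geometry):
        empty = make_samples([], [], [])
        assert compute_sample_velocity(empty, geometry).size == 0

    def test_too_few_valid_neighbors_undefined(self, geometry):
        samples = stationary_samples(5, geometry)
        samples.loc[[0, 1, 3, 4], "valid"] = False
        samples.loc[[0, 1, 3, 4], ["x_prop", "y_prop"]] = np.nan
        v = compute_sample_velocity(samples, geometry)
        assert np.isnan(v).all()  # lone valid sample has no partner in +/-10 ms


class TestAnnotate:
    @pytest.mark.parametrize(
        "velocity,expected",
        [(29.9, FIXATION), (30.0, SACCADE), (np.nan, UNCLASSIFIED), (0.0, FIXATION), (300.0, SACCADE)],
    )
    def test_threshold_rule(self, velocity, expected):
        assert annotate_samples(np.array([velocity]))[0] == expected

    def test_every_sample_gets_exactly_one_label(self, rng):
        v = rng.uniform(0, 60, 500)
        v[rng.random(500) < 0.1] = np.nan
        labels = annotate_samples(v)
        fracs = np.bincount(labels, minlength=3) / len(labels)
        assert fracs.sum() == pytest.approx(1.0)


class TestSegmentation:
    def test_single_long_run_one_event(self, geometry):
        n = 50  # 200 ms of fixation annotations
        samples = stationary_samples(n, geometry)
        labels = np.full(n, FIXATION, dtype=np.int8)
        events, membership = segment_and_merge(labels, samples, geometry)
        assert len(events) == 1
        assert events[0].kind == "fixation"
        assert events[0].duration_ms == pytest.approx(200.0)
        assert (membership == 0).all()

    def test_short_fixation_between_saccades_dropped(self, geometry):
        # 40 ms fixation run (< 60 ms) flanked by long saccade runs
        n_sac = 12
        labels = np.concatenate([
            np.full(n_sac, SACCADE), np.full(10, FIXATION), np.full(n_sac, SACCADE)
        ]).astype(np.int8)
        n = len(labels)
        samples = stationary_samples(n, geometry)
        events, membership = segment_and_merge(labels, samples, geometry)
        assert all(e.kind == "saccade" for e in events)
        assert (membership[n_sac:n_sac + 10] == -1).all()

    def test_abutting_same_kind_candidates_merge(self, geometry):
        # two fixation candidates of 30 + 40 ms with zero gap -> one 70 ms event
        t = uniform_times(18)
        candidates = [(FIXATION, [(0, 7)]), (FIXATION, [(8, 17)])]
        merged = _merge_candidates(candidates, t, 1 / 250.0, max_gap_ms=0.0)
        assert len(merged) == 1
        runs = merged[0][1]
        dur_ms = sum((t[i1] + 1 / 250 - t[i0]) for i0, i1 in runs) * 1000
        assert dur_ms == pytest.approx(72.0)  # 18 samples at 4 ms

    def test_merge_across_unclassified_gap_only_when_allowed(self, geometry):
        # fixation, 2 unclassified samples (8 ms gap), fixation
        labels = np.concatenate([
            np.full(20, FIXATION), np.full(2, UNCLASSIFIED), np.full(20, FIXATION)
        ]).astype(np.int8)
        samples = stationary_samples(len(labels), geometry)
        strict, _ = segment_and_merge(labels, samples, geometry, EventDetectionConfig())
        lenient, _ = segment_and_merge(labels, samples, geometry,
                                       EventDetectionConfig(max_merge_gap_ms=10.0))
        assert len(strict) == 2
        assert len(lenient) == 1
        assert lenient[0].duration_ms == pytest.approx(168.0)  # spans the gap

    def test_no_short_events_survive_and_events_sorted_disjoint(self, geometry, rng):
        n = 2000
        v = rng.uniform(0, 60, n)
        v[rng.random(n) < 0.05] = np.nan
        samples = stationary_samples(n, geometry)
        labels = annotate_samples(v)
        cfg = EventDetectionConfig()
        events, membership = segment_and_merge(labels, samples, geometry, cfg, velocities=v)
        for e in events:
            min_ms = cfg.min_fixation_ms if e.kind == "fixation" else cfg.min_saccade_ms
            assert e.duration_ms >= min_ms - 1e-9
        starts = [e.t_start for e in events]
        ends = [e.t_end for e in events]
        assert starts == sorted(starts)
        assert all(ends[i] <= starts[i + 1] + 1e-12 for i in range(len(events) - 1))

    def test_determinism(self, geometry, rng):
        n = 1000
        x = 0.5 + np.cumsum(rng.normal(0, 1e-4, n))
        samples = make_samples(uniform_times(n), x, np.full(n, 0.5))
        a, _, _, _ = detect_events(samples, geometry)
        b, _, _, _ = detect_events(samples, geometry)
        assert a == b


class TestSummarize:
    def test_coincident_fixation_zero_dispersion(self, geometry):
        samples = stationary_samples(10, geometry, x=0.25, y=0.25)
        ev = summarize_event("fixation", samples, geometry)
        assert ev.rms_dispersion_px == 0.0
        assert ev.amplitude_deg == 0.0

    def test_horizontal_saccade_direction_zero(self, geometry):
        t = uniform_times(10)
        x = np.linspace(0, 0.5, 10)
        samples = make_samples(t, x, np.full(10, 0.5))
        ev = summarize_event("saccade", samples, geometry)
        assert ev.direction_deg == pytest.approx(0.0)
        assert ev.amplitude_deg == pytest.approx(
            visual_angle_deg((0.0, 540.0), (960.0, 540.0), geometry))

    def test_vertical_direction_ninety(self, geometry):
        t = uniform_times(10)
        y = np.linspace(0.1, 0.6, 10)
        samples = make_samples(t, np.full(10, 0.5), y)
        ev = summarize_event("saccade", samples, geometry)
        assert ev.direction_deg == pytest.approx(90.0)

    def test_centroid_and_rms_hand_computation(self, geometry):
        # samples at (0,0) and (0,2) px -> centroid (0,1), rms dispersion 1
        t = uniform_times(2)
        samples = make_samples(t, [0.0, 0.0], [0.0, 2.0 / geometry.height_px])
        ev = summarize_event("fixation", samples, geometry)
        assert (ev.centroid_x_px, ev.centroid_y_px) == (0.0, 1.0)
        assert ev.rms_dispersion_px == pytest.approx(1.0)

    def test_saccade_needs_two_valid_samples(self, geometry):
        samples = stationary_samples(3, geometry)
        samples.loc[1:, "valid"] = False
        with pytest.raises(ValueError, match="valid samples"):
            summarize_event("saccade", samples, geometry)

    def test_duration_consistency(self, geometry):
        samples = stationary_samples(25, geometry)
        ev = summarize_event("fixation", samples, geometry)
        assert ev.duration_ms == pytest.approx((ev.t_end - ev.t_start) * 1000)


def test_truncate_event_recomputes_duration(geometry):
    samples = stationary_samples(50, geometry)
    ev = summarize_event("fixation", samples, geometry)
    clipped = truncate_event(ev, 0.1, 1.0)
    assert clipped.t_start == pytest.approx(0.1)
    assert clipped.duration_ms == pytest.approx((ev.t_end - 0.1) * 1000)
    assert truncate_event(ev, 5.0, 6.0) is None


def test_label_runs_roundtrip():
    labels = np.array([0, 0, 1, 1, 1, 2, 0], dtype=np.int8)
    runs = _label_runs(labels)
    assert runs == [(0, 0, 1), (1, 2, 4), (2, 5, 5), (0, 6, 6)]
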