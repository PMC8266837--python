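"""Fixation-episode detection semantics and the gaze audits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import gaze_frame
from sonoflow.gaze import (
    align_gaze_to_frames,
    detect_fixation_episodes,
    measurement_gaze_rate,
    scan_aoi_flag,
)
from sonoflow.screen import AOIRegion
from sonoflow.synth import GeneratorConfig, simulate_session

AOI = AOIRegion("box", 0, 0, 100, 100)
IN, OUT = 50.0, 500.0


def stream(ts, inside, valid=None):
    return gaze_frame(ts, [IN if i else OUT for i in inside], [50.0] * len(ts), valid)


def brute_force_episodes(ts, inside, min_fix=0.1, merge_gap=0.4):
    """Exhaustive run-scan + merge oracle, independent of the vectorized path."""
    fixations = []
    i, n = 0, len(ts)
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and inside[j + 1]:
            j += 1
        if ts[j] - ts[i] >= min_fix:
            fixations.append((ts[i], ts[j]))
        i = j + 1
    episodes = []
    for s, e in fixations:
        if episodes and s - episodes[-1][1] <= merge_gap:
            p = episodes[-1]
            episodes[-1] = (p[0], e, p[2] + 1)
        else:
            episodes.append((s, e, 1))
    return episodes


class TestBoundarySemantics:
    def test_single_run_above_threshold(self):
        ts = np.arange(0, 0.16, 0.01)
        eps = detect_fixation_episodes(stream(ts, [1] * len(ts)), AOI)
        assert len(eps) == 1 and eps[0].n_fixations == 1

    def test_gap_of_exactly_400ms_merges(self):
        ts = [0.0, 0.04, 0.08, 0.12, 0.2, 0.3, 0.4, 0.52, 0.56, 0.60, 0.64]
        inside = [1, 1, 1, 1, 0, 0, 0, 1, 1, 1, 1]
        eps = detect_fixation_episodes(stream(ts, inside), AOI)
        assert len(eps) == 1
        assert (eps[0].t_start, eps[0].t_end, eps[0].n_fixations) == (0.0, 0.64, 2)

    def test_gap_of_401ms_splits(self):
        ts = [0.0, 0.04, 0.08, 0.12, 0.2, 0.3, 0.4, 0.521, 0.561, 0.601, 0.641]
        inside = [1, 1, 1, 1, 0, 0, 0, 1, 1, 1, 1]
        eps = detect_fixation_episodes(stream(ts, inside), AOI)
        assert len(eps) == 2

    def test_run_below_100ms_discarded_before_merge(self):
        # 80 ms run between two long runs: it still merges episodes only if
        # the *surviving* fixations are close enough, and never counts itself
        ts = [0.0, 0.05, 0.10, 0.15, 0.5, 0.55, 0.9, 0.95, 1.0, 1.05]
        inside = [1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
        # contiguous run: single fixation
        eps = detect_fixation_episodes(stream(ts, inside), AOI)
        assert len(eps) == 1 and eps[0].n_fixations == 1

    def test_invalid_samples_break_runs(self):
        ts = np.arange(0, 0.3, 0.02)
        valid = [True] * 7 + [False] + [True] * (len(ts) - 8)
        eps = detect_fixation_episodes(stream(ts, [1] * len(ts), valid), AOI)
        oracle = brute_force_episodes(
            list(ts), [v for v in valid]
        )
        assert [(e.t_start, e.t_end, e.n_fixations) for e in eps] == pytest.approx(oracle)

    def test_empty_stream(self):
        assert detect_fixation_episodes(stream([], []), AOI) == []


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.data())
def test_detector_equals_bruteforce_oracle(data):
    n = data.draw(st.integers(2, 60))
    dts = data.draw(st.lists(st.floats(0.005, 0.3), min_size=n, max_size=n))
    inside = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
    ts = np.cumsum(dts)
    eps = detect_fixation_episodes(stream(ts, inside), AOI)
    oracle = brute_force_episodes(list(ts), inside)
    assert [(e.t_start, e.t_end, e.n_fixations) for e in eps] == pytest.approx(oracle)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.data())
def test_episode_count_monotone_in_thresholds(data):
    n = data.draw(st.integers(5, 50))
    dts = data.draw(st.lists(st.floats(0.005, 0.2), min_size=n, max_size=n))
    inside = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
    ts = np.cumsum(dts)
    g = stream(ts, inside)
    n_small_gap = len(detect_fixation_episodes(g, AOI, merge_gap=0.1))
    n_large_gap = len(detect_fixation_episodes(g, AOI, merge_gap=0.8))
    assert n_large_gap <= n_small_gap
    n_strict = len(detect_fixation_episodes(g, AOI, min_fix=0.3))
    n_loose = len(detect_fixation_episodes(g, AOI, min_fix=0.05))
    # raising min_fix can only remove fixations; fewer fixations can merge
    # into at most as many episodes as before
    assert n_strict <= n_loose + len(detect_fixation_episodes(g, AOI))


def test_detector_translation_invariant(rng):
    ts = np.cumsum(rng.uniform(0.005, 0.1, 40))
    inside = rng.random(40) < 0.5
    a = detect_fixation_episodes(stream(ts, inside), AOI)
    b = detect_fixation_episodes(stream(ts + 1000.0, inside), AOI)
    assert [e.n_fixations for e in a] == [e.n_fixations for e in b]
    # durations agree up to the float rounding introduced by the time shift
    assert [e.t_end - e.t_start for e in a] == pytest.approx(
        [e.t_end - e.t_start for e in b], abs=1e-9
    )


class TestScanFlag:
    def test_planted_fixation_flags_scan(self):
        ts = np.arange(0, 0.2, 0.02)
        assert scan_aoi_flag(stream(ts, [1] * len(ts)), AOI)

    def test_short_dwell_does_not_flag(self):
        ts = np.arange(0, 0.08, 0.02)
        assert not scan_aoi_flag(stream(ts, [1] * len(ts)), AOI)


class TestAlignGazeToFrames:
    def test_exact_timestamps_identity(self):
        ts = np.arange(0, 1, 1 / 30)
        g = gaze_frame(ts, np.arange(len(ts)), np.zeros(len(ts)))
        out = align_gaze_to_frames(g, ts)
        assert np.array_equal(out["x"].to_numpy(), np.arange(len(ts)))
        assert not out["missing"].any()

    def test_90hz_gaze_covers_30fps_frames(self):
        g = gaze_frame(np.arange(0, 2, 1 / 90), 0, 0)
        out = align_gaze_to_frames(g, np.arange(0, 2, 1 / 30))
        assert not out["missing"].any()

    def test_random_streams_match_linear_scan_oracle(self, rng):
        ts = np.sort(rng.uniform(0, 10, 200))
        g = gaze_frame(ts, np.arange(200), np.zeros(200))
        frames = rng.uniform(0, 10, 50)
        out = align_gaze_to_frames(g, frames)
        for k, tf in enumerate(frames):
            i = int(np.argmin(np.abs(ts - tf)))
            assert out["x"].iloc[k] == i or abs(ts[i] - tf) == abs(
                ts[int(out["x"].iloc[k])] - tf
            )

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            align_gaze_to_frames(gaze_frame([], [], []), [0.0])


class TestMeasurementGazeRate:
    cfg = GeneratorConfig(
        seed=31, duration_mean=2.0, duration_sd=0.2, duration_bounds=(1.6, 2.6)
    )

    def test_always_looking_gives_one(self):
        cfg = GeneratorConfig(
            seed=32, duration_mean=2.0, duration_sd=0.2,
            duration_bounds=(1.6, 2.6), p_measurement_glance=1.0,
        )
        sessions = [simulate_session(cfg, i) for i in range(4)]
        assert measurement_gaze_rate(sessions)["rate"] == 1.0

    def test_never_looking_gives_zero(self):
        cfg = GeneratorConfig(
            seed=33, duration_mean=2.0, duration_sd=0.2,
            duration_bounds=(1.6, 2.6), p_measurement_glance=0.0,
        )
        sessions = [simulate_session(cfg, i) for i in range(4)]
        assert measurement_gaze_rate(sessions)["rate"] == 0.0

    def test_planted_rate_recovered_within_sampling_error(self):
        cfg = GeneratorConfig(
            seed=34, duration_mean=2.0, duration_sd=0.2,
            duration_bounds=(1.6, 2.6), p_measurement_glance=0.93,
            measurement_plan={"HC": 2, "AC": 3, "FL": 2},
        )
        sessions = [simulate_session(cfg, i) for i in range(15)]
        out = measurement_gaze_rate(sessions)
        n = out["n_events"]
        se = np.sqrt(0.93 * 0.07 / n)
        assert out["rate"] == pytest.approx(0.93, abs=max(3 * se, 0.03))

    def test_no_events_raises(self):
        cfg = GeneratorConfig(
            seed=35, duration_mean=2.0, duration_sd=0.2,
            duration_bounds=(1.6, 2.6), measurement_plan={"HC": 0, "AC": 0, "FL": 0},
        )
        with pytest.raises(ValueError, match="no measurement events"):
            measurement_gaze_rate([simulate_session(cfg, 0)])
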