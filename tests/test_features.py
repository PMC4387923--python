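"""Feature extraction on analytic fixtures and simulated traces."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from canaryresp import (
    Trajectory,
    classify_pattern,
    dominant_period,
    extract_features,
    find_local_extrema,
    generate_fixture,
    ra_amplitude_trend,
    segment_pulses,
)


def as_trajectory(values, dt, channel="e_er"):
    """Wrap a scalar trace into a Trajectory (other channels zero)."""
    n = len(values)
    states = np.zeros((n, 4))
    col = {"e_er": 0, "i_er": 1, "e_ra": 2, "i_ra": 3}[channel]
    states[:, col] = values
    return Trajectory(
        times=dt * np.arange(n), states=states, drive_trace=np.zeros((n, 3)),
        meta={"dt": dt},
    )


class TestFindLocalExtrema:
    def test_sine_has_one_max_and_min_per_cycle(self):
        trace = generate_fixture("sine", n=2000, dt=0.1, period=20.0)
        ex = find_local_extrema(trace.values, 0.1, trace.dt)
        n_cycles = 2000 * 0.1 / 20.0
        maxima = [e for e in ex if e.kind == "max"]
        minima = [e for e in ex if e.kind == "min"]
        assert abs(len(maxima) - n_cycles) <= 1
        assert abs(len(minima) - n_cycles) <= 1

    def test_extrema_alternate_in_kind(self):
        trace = generate_fixture("sine", n=1500, dt=0.1, period=17.0)
        ex = find_local_extrema(trace.values, 0.1, trace.dt)
        kinds = [e.kind for e in ex]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_constant_series_has_no_extrema(self):
        assert find_local_extrema(np.ones(100), 0.01) == []

    def test_bump_pair_yields_two_maxima_one_minimum(self):
        trace = generate_fixture("bump_pair", n=2000, dt=0.1, valley=0.3)
        ex = find_local_extrema(trace.values, 0.1, trace.dt)
        assert [e.kind for e in ex] == ["max", "min", "max"]
        assert ex[1].value == pytest.approx(0.3, abs=0.01)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            find_local_extrema([1.0, 2.0], 0.1)

    @given(offset=st.floats(-5, 5, allow_nan=False))
    def test_invariant_under_constant_offset(self, offset):
        trace = generate_fixture("sine", n=800, dt=0.5, period=40.0)
        a = find_local_extrema(trace.values, 0.1, trace.dt)
        b = find_local_extrema(trace.values + offset, 0.1, trace.dt)
        assert [(e.time, e.kind) for e in a] == [(e.time, e.kind) for e in b]


class TestSegmentPulses:
    def test_all_zero_trace_has_no_pulses(self):
        assert segment_pulses(np.zeros(100), 0.1, dt=1.0) == []

    def test_bump_pair_splits_at_threshold_above_valley(self):
        trace = generate_fixture("bump_pair", n=2000, dt=0.1, valley=0.05)
        assert len(segment_pulses(trace.values, 0.1, trace.dt)) == 2

    def test_bump_pair_merges_at_threshold_below_valley(self):
        trace = generate_fixture("bump_pair", n=2000, dt=0.1, valley=0.3)
        assert len(segment_pulses(trace.values, 0.2, trace.dt)) == 1

    def test_count_non_increasing_in_threshold(self):
        trace = generate_fixture("decaying_train", n=3000, dt=0.1, period=30.0)
        counts = [
            len(segment_pulses(trace.values, thr, trace.dt))
            for thr in (0.05, 0.15, 0.3, 0.5, 0.8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_short_runs_discarded(self):
        y = np.zeros(100)
        y[10:12] = 1.0  # 2 samples at dt=0.5 -> 1 ms < 2 ms minimum
        assert segment_pulses(y, 0.5, dt=0.5) == []

    def test_half_open_interval_bounds(self):
        y = np.zeros(100)
        y[10:20] = 1.0
        [(a, b)] = segment_pulses(y, 0.5, dt=1.0)
        assert (a, b) == (10.0, 20.0)


class TestDominantPeriod:
    def test_recovers_sine_period(self):
        trace = generate_fixture("sine", n=4000, dt=0.1, period=20.0)
        assert dominant_period(trace.values, trace.dt) == pytest.approx(20.0, abs=0.1)

    def test_single_bump_has_no_period(self):
        trace = generate_fixture("bump_pair", n=400, dt=0.1, valley=0.3,
                                 separation=10.0)
        # narrow window holding one bump only
        assert dominant_period(trace.values[:220], trace.dt) is None

    def test_window_validation(self):
        trace = generate_fixture("sine", n=100, dt=1.0)
        with pytest.raises(ValueError):
            dominant_period(trace.values, trace.dt, window=(50.0, 2000.0))


class TestRaAmplitudeTrend:
    def test_decaying_envelope_is_decreasing(self):
        trace = generate_fixture("decaying_train", n=4000, dt=0.1, period=30.0)
        traj = as_trajectory(trace.values, trace.dt, channel="e_ra")
        assert ra_amplitude_trend(traj) == "decreasing"

    def test_flat_trace_is_constant(self):
        traj = as_trajectory(0.5 * np.ones(500), 0.5, channel="e_ra")
        assert ra_amplitude_trend(traj) == "constant"

    def test_pulsatile_ra_is_increasing(self, preset_runs):
        assert ra_amplitude_trend(preset_runs["pulsatile"]) == "increasing"

    def test_p1_ra_is_constant(self, preset_runs):
        assert ra_amplitude_trend(preset_runs["P1"]) == "constant"


class TestClassifier:
    def test_silent_trace_is_unknown(self):
        traj = as_trajectory(np.zeros(500), 0.5)
        assert classify_pattern(traj) == "unknown"

    @pytest.mark.parametrize("name", ["P0", "pulsatile", "P2", "P1"])
    def test_each_preset_maps_to_its_own_label(self, preset_runs, name):
        assert classify_pattern(preset_runs[name]) == name

    def test_report_fields(self, preset_runs):
        rep = extract_features(preset_runs["P0"])
        assert rep.label == "P0"
        assert rep.n_pulses == 1
        assert rep.threshold == pytest.approx(0.1 * preset_runs["P0"].e_er.max())
        kinds = [e.kind for e in rep.extrema]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        text = rep.to_text()
        assert "label\tP0" in text


class TestFixtures:
    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            generate_fixture("sawtooth")

    def test_jitter_requires_seed(self):
        with pytest.raises(ValueError):
            generate_fixture("sine", jitter=0.1)

    def test_jitter_deterministic_under_seed(self):
        a = generate_fixture("sine", jitter=0.1, seed=7)
        b = generate_fixture("sine", jitter=0.1, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            generate_fixture("sine", n=2)
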