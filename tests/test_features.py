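from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serj import features as ft
from serj.errors import InsufficientBeatsError, InvalidArgumentError
from serj.preprocess import preprocess_ppg
from serj.signal_io import Channel, SignalTrace, segment
from serj.synth import QuadrantScenario, generate_ppg


def brute_force_pnn(intervals, thr=50.0):
    count = 0
    for i in range(len(intervals) - 1):
        if abs(intervals[i + 1] - intervals[i]) > thr:
            count += 1
    return count / (len(intervals) - 1)


class TestBpnn50:
    def test_hand_enumeration(self):
        assert ft.bpnn50([800, 860, 870, 940]) == pytest.approx(2 / 3)

    def test_constant_intervals_zero(self):
        assert ft.bpnn50([800] * 6) == 0.0

    def test_boundary_difference_excluded(self):
        assert ft.bpnn50([800, 850]) == 0.0  # exactly 50 ms: strict >

    def test_too_few_intervals(self):
        with pytest.raises(InvalidArgumentError):
            ft.bpnn50([800])

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=300, max_value=1500), min_size=2, max_size=40))
    def test_matches_brute_force_enumeration(self, intervals):
        assert ft.bpnn50(intervals) == pytest.approx(brute_force_pnn(intervals))


class TestRangeAndSlope:
    def test_range_hand_example(self):
        assert ft.signal_range([2, 7, 4]) == 5.0

    def test_range_symmetry_and_scale(self):
        x = np.random.default_rng(0).normal(size=100)
        assert ft.signal_range(-x) == pytest.approx(ft.signal_range(x))
        assert ft.signal_range(3.0 * x) == pytest.approx(3.0 * ft.signal_range(x))

    def test_one_d_mean_hand_example(self):
        assert ft.one_d_mean([1, 3, 6]) == pytest.approx(2.5)

    def test_constant_is_zero(self):
        assert ft.one_d_mean([4.0] * 10) == 0.0
        assert ft.signal_range([4.0] * 10) == 0.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=2, max_size=100))
    def test_telescopes_to_endpoints(self, xs):
        x = np.asarray(xs)
        expected = (x[-1] - x[0]) / (x.size - 1)
        assert ft.one_d_mean(x) == pytest.approx(expected, abs=1e-9 * max(1, abs(expected)))


@pytest.fixture(scope="module")
def clean_ppg():
    sc = QuadrantScenario.for_quadrant("LANV", seed=11, duration_s=30)
    raw, beats = generate_ppg(sc, fs=100.0)
    return preprocess_ppg(raw), beats


class TestBeatDetection:
    def test_peaks_within_one_sample_of_truth(self, clean_ppg):
        trace, truth = clean_ppg
        detected = ft.main_peak_times(trace)
        assert detected.size == truth.size
        err = np.abs(detected[:, None] - truth[None, :]).min(axis=0)
        assert err.max() <= 1.0 / trace.fs + 1e-9

    def test_zero_jitter_periods_recovered(self):
        sc = replace(QuadrantScenario.for_quadrant("HANV", seed=4), ibi_jitter_ms=0.0)
        raw, truth = generate_ppg(sc, fs=100.0)
        detected = ft.main_peak_times(preprocess_ppg(raw))
        periods = np.diff(detected)
        base = np.diff(truth).mean()
        assert np.all(np.abs(periods - base) <= 1.0 / 100.0 + 1e-9)

    def test_fiducial_ordering_on_every_beat(self, clean_ppg):
        trace, _ = clean_ppg
        for b in ft.detect_beats(trace):
            assert b.main_wave[0] < b.dicrotic_notch[0] < b.dicrotic_wave[0]
            assert b.period_s > 0
            assert b.t_onset_to_main_peak_s < b.t_onset_to_notch_s

    def test_flat_signal_raises(self):
        flat = SignalTrace(Channel.PPG, 100.0, np.full(1000, 2.0))
        with pytest.raises(InsufficientBeatsError):
            ft.main_peak_times(flat)


class TestCatalog:
    def test_family_counts(self):
        cat = ft.catalog()
        assert len(cat["time_domain"]["ppg"]) == 18
        assert len(cat["time_domain"]["eda"]) == 24
        assert len(cat["physiological"]["eda"]) == 7
        assert len(cat["physiological"]["ppg"]) == 10

    def test_names_unique_and_complete(self):
        names = ft.feature_names()
        assert len(names) == len(set(names))
        assert {"bpnn50", "eda_range", "eda_1dmean"} <= set(names)

    def test_no_beats_flags_pulse_features_absent(self):
        rng = np.random.default_rng(0)
        eda = SignalTrace(Channel.EDA, 100.0, rng.normal(5, 1, 1000))
        flat_ppg = SignalTrace(Channel.PPG, 100.0, rng.normal(0, 0.01, 1000))
        (ew,), (pw,) = segment(eda, 10), segment(flat_ppg, 10)
        vec = ft.extract_catalog(ew, pw, beats=[])
        assert vec["bpnn50"] is None and vec["ppg_hr_mean"] is None
        assert vec["eda_range"] is not None

    def test_deterministic(self, default_clean):
        eda, ppg = default_clean
        (ew, pw) = segment(eda, 10)[0], segment(ppg, 10)[0]
        beats = ft.detect_beats(ppg)
        a = ft.extract_catalog(ew, pw, beats=beats)
        b = ft.extract_catalog(ew, pw, beats=beats)
        assert a == b
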