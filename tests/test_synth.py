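from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import argrelmin

from serj.errors import InvalidArgumentError
from serj.judge import EmotionQuadrant
from serj.signal_io import segment
from serj.synth import (
    DEFAULTS,
    QuadrantScenario,
    beat_template,
    generate_eda,
    generate_ppg,
    generate_session,
)


class TestGenerateEda:
    @pytest.mark.parametrize("slope", ["high", "low"])
    def test_rising_trend_orders_extrema(self, slope):
        sc = replace(QuadrantScenario.for_quadrant("HANV", seed=5), eda_slope_level=slope)
        for w in segment(generate_eda(sc), 10):
            assert w.n_max > w.n_min

    def test_falling_trend_orders_extrema(self):
        sc = QuadrantScenario.for_quadrant("LAPV", seed=5)
        for w in segment(generate_eda(sc), 10):
            assert w.n_max < w.n_min

    def test_deterministic_under_seed(self):
        sc = QuadrantScenario.for_quadrant("HANV", seed=9)
        a, b = generate_eda(sc), generate_eda(sc)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_range_levels_do_not_overlap(self):
        highs, lows = [], []
        for seed in range(5):
            hi = QuadrantScenario.for_quadrant("HANV", seed=seed)
            lo = QuadrantScenario.for_quadrant("LANV", seed=seed)
            highs += [w.x_max - w.x_min for w in segment(generate_eda(hi), 10)]
            lows += [w.x_max - w.x_min for w in segment(generate_eda(lo), 10)]
        assert min(highs) > max(lows)

    def test_too_low_fs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_eda(QuadrantScenario.for_quadrant("HANV"), fs=5.0)


class TestGeneratePpg:
    def test_no_jitter_gives_equal_intervals(self):
        sc = replace(QuadrantScenario.for_quadrant("HANV", seed=2), ibi_jitter_ms=0.0)
        _, beats = generate_ppg(sc)
        np.testing.assert_allclose(np.diff(beats), DEFAULTS.base_ibi_s, atol=1e-12)

    def test_jitter_produces_large_successive_differences(self):
        sc = replace(
            QuadrantScenario.for_quadrant("LANV", seed=2),
            ibi_jitter_ms=40.0,
            defaults=replace(DEFAULTS, base_ibi_s=0.8),
        )
        _, beats = generate_ppg(sc)
        diffs = np.abs(np.diff(np.diff(beats))) * 1000.0
        assert np.mean(diffs > 50.0) > 0

    def test_template_has_single_dicrotic_notch(self):
        tau = np.linspace(-0.1, 0.45, 551)
        y = beat_template(tau)
        main = int(np.argmax(y))
        dicrotic_region = y[main:]
        minima = argrelmin(dicrotic_region)[0]
        # exactly one local minimum between main wave and dicrotic wave
        dw = main + int(np.argmax(dicrotic_region[minima[0]:])) + minima[0]
        between = [m for m in minima + main if main < m < dw]
        assert len(between) == 1

    def test_deterministic_under_seed(self):
        sc = QuadrantScenario.for_quadrant("LANV", seed=7)
        (a, ba), (b, bb) = generate_ppg(sc), generate_ppg(sc)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(ba, bb)

    def test_excessive_jitter_rejected(self):
        sc = QuadrantScenario.for_quadrant("LANV")
        with pytest.raises(InvalidArgumentError):
            generate_ppg(replace(sc, ibi_jitter_ms=900.0))


class TestGenerateSession:
    def test_labels_follow_scenario_blocks(self):
        scenarios = [
            QuadrantScenario.for_quadrant("HANV", duration_s=30, seed=0),
            QuadrantScenario.for_quadrant("LAPV", duration_s=30, seed=1),
        ]
        session = generate_session(scenarios)
        assert [q.value for q in session.labels] == ["HANV"] * 3 + ["LAPV"] * 3

    def test_single_scenario_window_count(self):
        session = generate_session([QuadrantScenario.for_quadrant("LANV", duration_s=60)])
        assert session.n_windows == 6

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_session([])

    def test_non_multiple_duration_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_session([QuadrantScenario.for_quadrant("LANV", duration_s=25)])

    def test_beat_times_strictly_increasing(self, default_session):
        assert np.all(np.diff(default_session.beat_times) > 0)

    def test_quadrant_invariants(self):
        assert EmotionQuadrant.HAPV.arousal_sign == 1
        assert EmotionQuadrant.LAPV.valence_sign == 1
        assert EmotionQuadrant.LANV.arousal_sign == -1
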