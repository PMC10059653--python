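import numpy as np
import pytest

from serj.errors import DegenerateThresholdError, InvalidArgumentError
from serj.judge import (
    JUDGE_FEATURES,
    EmotionQuadrant,
    FeatureStream,
    WindowFeatures,
    compute_threshold,
    judge_window,
)
from serj.judge import judge_feature_windows
from serj.pipeline import extract_judge_features, judge_session, preprocess_session
from serj.signal_io import Channel, SignalTrace


class TestComputeThreshold:
    def test_direct_evaluation(self):
        s = compute_threshold([0.2, 0.4, 0.6, 0.8, 1.0])
        assert s.x_th == pytest.approx(0.5)

    def test_two_values_give_half(self):
        assert compute_threshold([3.0, 9.0]).x_th == pytest.approx(0.5)

    def test_affine_invariance(self):
        v = np.random.default_rng(0).normal(size=30)
        a = compute_threshold(v).x_th
        b = compute_threshold(7.5 * v + 3.0).x_th
        assert a == pytest.approx(b)

    def test_constant_span_rejected(self):
        with pytest.raises(DegenerateThresholdError):
            compute_threshold([2.0, 2.0, 2.0])

    def test_later_values_clipped(self):
        s = compute_threshold([0.0, 1.0])
        assert s.normalize(5.0) == 1.0
        assert s.normalize(-5.0) == 0.0


def unit_streams(thresholds):
    """Streams with identity normalization on [0, 1] and given thresholds."""
    return {
        name: FeatureStream(name=name, channel="x", x_min=0.0, x_max=1.0, x_th=thresholds[name])
        for name in JUDGE_FEATURES
    }


def literal_rule_text(f, th):
    """Straight nested-conditional transcription of the decision logic."""
    eda = None
    if f.eda_range > th["eda_range"]:
        if f.n_max <= f.n_min:
            eda = "LAPV"
        elif f.eda_1dmean > th["eda_1dmean"]:
            eda = "HANV"
    pulse = None
    if f.bpnn50 is not None and f.bpnn50 > th["bpnn50"]:
        if f.pulse_range > th["pulse_range"]:
            pulse = "LANV"
        elif f.pulse_1dmean > th["pulse_1dmean"]:
            pulse = "HAPV"
    if eda and pulse:
        for q in ("HANV", "LANV", "LAPV", "HAPV"):
            if q in (eda, pulse):
                return q
    return eda or pulse or "UNDECIDED"


class TestJudgeWindow:
    def test_guard_failure_yields_undecided(self):
        streams = unit_streams(dict.fromkeys(JUDGE_FEATURES, 0.5))
        f = WindowFeatures(0, eda_range=0.2, eda_1dmean=0.9, n_max=5, n_min=1,
                           bpnn50=0.1, pulse_range=0.9, pulse_1dmean=0.9)
        assert judge_window(f, streams).quadrant is EmotionQuadrant.UNDECIDED

    def test_max_before_min_is_lapv(self):
        streams = unit_streams(dict.fromkeys(JUDGE_FEATURES, 0.5))
        # window samples [1.0,0.5,0.0,0.2,0.3]: n_max=0 < n_min=2, high range
        f = WindowFeatures(0, eda_range=0.9, eda_1dmean=0.1, n_max=0, n_min=2,
                           bpnn50=0.0, pulse_range=0.0, pulse_1dmean=0.0)
        assert judge_window(f, streams).quadrant is EmotionQuadrant.LAPV

    def test_pulse_branch_hand_traces(self):
        streams = unit_streams(dict.fromkeys(JUDGE_FEATURES, 0.5))
        lanv = WindowFeatures(0, 0.1, 0.0, 5, 1, bpnn50=0.7, pulse_range=0.9, pulse_1dmean=0.1)
        assert judge_window(lanv, streams).quadrant is EmotionQuadrant.LANV
        hapv = WindowFeatures(0, 0.1, 0.0, 5, 1, bpnn50=0.7, pulse_range=0.2, pulse_1dmean=0.7)
        assert judge_window(hapv, streams).quadrant is EmotionQuadrant.HAPV

    def test_missing_pulse_features_flag_partial(self):
        streams = unit_streams(dict.fromkeys(JUDGE_FEATURES, 0.5))
        f = WindowFeatures(0, eda_range=0.9, eda_1dmean=0.9, n_max=5, n_min=1,
                           bpnn50=None, pulse_range=None, pulse_1dmean=None)
        d = judge_window(f, streams)
        assert d.partial and d.quadrant is EmotionQuadrant.HANV

    def test_engine_agrees_with_literal_transcription(self):
        """Oracle equivalence on 10,000 random normalized feature tuples."""
        rng = np.random.default_rng(123)
        mismatches = 0
        for _ in range(10_000):
            th = dict(zip(JUDGE_FEATURES, rng.uniform(0, 1, 5)))
            streams = unit_streams(th)
            n_max, n_min = rng.integers(0, 100, 2)
            f = WindowFeatures(
                0, *rng.uniform(0, 1, 1), rng.uniform(-1, 1), int(n_max), int(n_min),
                bpnn50=float(rng.uniform(0, 1)),
                pulse_range=float(rng.uniform(0, 1)),
                pulse_1dmean=float(rng.uniform(0, 1)),
            )
            # keep values inside the identity-normalization span
            f = WindowFeatures(0, float(np.clip(f.eda_range, 0, 1)),
                               float(np.clip(f.eda_1dmean, 0, 1)), f.n_max, f.n_min,
                               f.bpnn50, f.pulse_range, f.pulse_1dmean)
            got = judge_window(f, streams).quadrant.value
            want = literal_rule_text(f, th)
            mismatches += got != want
        assert mismatches == 0

    def test_rule_trace_replays_to_same_outcome(self, default_decisions):
        for d in default_decisions:
            if d.quadrant is EmotionQuadrant.UNDECIDED and not d.rule_trace:
                continue
            # every recorded test outcome is consistent with its operands
            for name, lhs, rhs, outcome in d.rule_trace:
                if name == "n_max<=n_min":
                    assert outcome == (lhs <= rhs)
                else:
                    assert outcome == (lhs > rhs)


class TestJudgeSession:
    def test_benchmark_recovery(self, default_session, default_decisions):
        truth = [q.value for q in default_session.labels]
        got = [d.quadrant.value for d in default_decisions]
        acc = np.mean([t == g for t, g in zip(truth[4:], got[4:])])
        assert acc >= 0.9

    def test_calibration_windows_are_undecided(self, default_decisions):
        assert all(d.quadrant is EmotionQuadrant.UNDECIDED for d in default_decisions[:4])

    def test_deterministic(self, default_session, default_decisions):
        again = judge_session(default_session)
        assert [d.to_dict() for d in again] == [d.to_dict() for d in default_decisions]

    def test_affine_rescaling_of_channels_is_invariant(self, default_session):
        base = [d.quadrant for d in judge_session(default_session)]
        eda = default_session.eda.with_samples(3.0 * default_session.eda.samples + 11.0)
        ppg = default_session.ppg.with_samples(0.5 * default_session.ppg.samples - 2.0)
        rescaled = [d.quadrant for d in judge_session(eda, ppg)]
        assert rescaled == base

    def test_constant_signals_degenerate(self):
        eda = SignalTrace(Channel.EDA, 100.0, np.full(6000, 5.0))
        ppg = SignalTrace(Channel.PPG, 100.0, np.full(6000, 1.0))
        with pytest.raises(DegenerateThresholdError):
            judge_session(eda, ppg, preprocess=False)

    def test_too_few_windows_rejected(self, default_session):
        feats = extract_judge_features(
            *preprocess_session(default_session.eda, default_session.ppg)
        )
        with pytest.raises(InvalidArgumentError):
            judge_feature_windows(feats[:4], calibration_windows=4)
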