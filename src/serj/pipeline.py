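"""End-to-end wiring: preprocess → window → features → judgment.

These helpers chain the stage modules on a pair of traces (or a synthetic
session) so the judge, baseline and comparison code all consume identical
inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from serj import features as ft
from serj import preprocess as pp
from serj.errors import InsufficientBeatsError
from serj.judge import EmotionDecision, WindowFeatures, judge_feature_windows
from serj.signal_io import DEFAULT_WINDOW_S, SignalTrace, segment
from serj.synth import SyntheticSession


def preprocess_session(
    eda: SignalTrace,
    ppg: SignalTrace,
    calibration: pp.CalibrationParams = pp.CalibrationParams(),
    denoise: pp.DenoiseSpec = pp.DenoiseSpec(),
    filt: pp.FilterSpec = pp.FilterSpec(),
) -> tuple[SignalTrace, SignalTrace]:
    """Condition both channels (EDA: calibrate/denoise; PPG: low-pass)."""
    return pp.preprocess_eda(eda, calibration, denoise), pp.preprocess_ppg(ppg, filt)


def extract_judge_features(
    eda: SignalTrace,
    ppg: SignalTrace,
    window_length_s: float = DEFAULT_WINDOW_S,
) -> list[WindowFeatures]:
    """Per-window values of the five gated feature streams.

    Beat detection runs once over the whole PPG trace; a window's BpNN50 uses
    only intervals whose bounding peaks both fall inside it.  Windows with too
    few beats get ``None`` pulse features (the judge then flags the decision
    as partial).
    """
    eda_wins = segment(eda, window_length_s)
    ppg_wins = segment(ppg, window_length_s)
    n = min(len(eda_wins), len(ppg_wins))
    try:
        peak_t = ft.main_peak_times(ppg)
    except InsufficientBeatsError:
        peak_t = np.array([])

    out: list[WindowFeatures] = []
    for k in range(n):
        ew, pw = eda_wins[k], ppg_wins[k]
        ivals = ft.intervals_in_window(peak_t, pw.t_start, pw.t_end)
        if ivals.size >= 2:
            b = ft.bpnn50(ivals)
            pr = ft.signal_range(pw.samples)
            pm = ft.one_d_mean(pw.samples)
        else:
            b = pr = pm = None
        out.append(
            WindowFeatures(
                window=k,
                eda_range=ft.signal_range(ew.samples),
                eda_1dmean=ft.one_d_mean(ew.samples),
                n_max=ew.n_max,
                n_min=ew.n_min,
                bpnn50=b,
                pulse_range=pr,
                pulse_1dmean=pm,
            )
        )
    return out


def judge_session(
    session_or_eda: SyntheticSession | SignalTrace,
    ppg: SignalTrace | None = None,
    *,
    window_length_s: float = DEFAULT_WINDOW_S,
    calibration_windows: int = 4,
    preprocess: bool = True,
) -> list[EmotionDecision]:
    """Judge every calculation segment of a session.

    The first ``calibration_windows`` windows seed the per-feature thresholds
    (emitted as UNDECIDED); each later window gets one rule-tree decision.
    Deterministic: identical inputs and settings yield identical decisions.
    """
    if isinstance(session_or_eda, SyntheticSession):
        eda, ppg = session_or_eda.eda, session_or_eda.ppg
    else:
        eda = session_or_eda
        if ppg is None:
            raise ValueError("ppg trace required when not passing a session")
    if preprocess:
        eda, ppg = preprocess_session(eda, ppg)
    feats = extract_judge_features(eda, ppg, window_length_s)
    return judge_feature_windows(feats, calibration_windows=calibration_windows)


def feature_table(
    session_or_eda: SyntheticSession | SignalTrace,
    ppg: SignalTrace | None = None,
    *,
    window_length_s: float = DEFAULT_WINDOW_S,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Full catalog feature table: one row per window, one column per feature."""
    if isinstance(session_or_eda, SyntheticSession):
        eda, ppg = session_or_eda.eda, session_or_eda.ppg
    else:
        eda = session_or_eda
        if ppg is None:
            raise ValueError("ppg trace required when not passing a session")
    if preprocess:
        eda, ppg = preprocess_session(eda, ppg)
    eda_wins = segment(eda, window_length_s)
    ppg_wins = segment(ppg, window_length_s)
    try:
        beats = ft.detect_beats(ppg)
    except InsufficientBeatsError:
        beats = []
    rows = [
        ft.extract_catalog(ew, pw, beats=beats)
        for ew, pw in zip(eda_wins, ppg_wins)
    ]
    df = pd.DataFrame(rows, columns=ft.feature_names())
    df.index.name = "window"
    return df
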