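"""Signal containers, CSV ingest/egress, and 10-s calculation-segment windowing.

A :class:`SignalTrace` is a uniformly sampled single-channel recording (EDA or
PPG).  Ingest validates the declared sampling rate against the time stamps and
drops them afterwards; downstream code works purely with sample indices.
:func:`segment` cuts a trace into the non-overlapping calculation segments on
which every feature and judgment is computed (default length 10 s), recording
per-window extrema and their first-occurrence indices, which the rule tree
uses to order the EDA maximum against the minimum.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from serj.errors import FormatError, InvalidArgumentError

DEFAULT_WINDOW_S = 10.0


class Channel(str, enum.Enum):
    EDA = "eda"
    PPG = "ppg"


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled one-dimensional physiological signal."""

    channel: Channel
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidArgumentError("samples must be a non-empty 1-D array")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        return SignalTrace(self.channel, self.fs, np.asarray(samples, dtype=float), self.t0)


@dataclass(frozen=True)
class SignalWindow:
    """One calculation segment with its extremum bookkeeping.

    ``n_min``/``n_max`` are 0-based indices of the *first* occurrence of the
    window minimum/maximum; the judgment rules compare them to decide whether
    the EDA maximum precedes or follows the minimum.
    """

    channel: Channel
    index: int
    fs: float
    samples: np.ndarray
    t_start: float
    x_min: float = field(init=False)
    x_max: float = field(init=False)
    n_min: int = field(init=False)
    n_max: int = field(init=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "x_min", float(samples.min()))
        object.__setattr__(self, "x_max", float(samples.max()))
        object.__setattr__(self, "n_min", int(np.argmin(samples)))
        object.__setattr__(self, "n_max", int(np.argmax(samples)))

    @property
    def t_end(self) -> float:
        return self.t_start + self.samples.size / self.fs


def read_trace(path: str | Path, channel: Channel | str, fs: float) -> SignalTrace:
    """Read a ``time_s,value`` CSV and validate it against the declared rate.

    Time stamps must be strictly increasing and uniform at ``1/fs`` (gaps of
    more than one sample period beyond tolerance are rejected); they are not
    retained after ingest.
    """
    channel = Channel(channel)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise FormatError(f"{path}: expected header 'time_s,value', got {list(df.columns)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no samples")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise FormatError(f"{path}: time not strictly increasing at row {bad + 1}")
    period = 1.0 / fs
    # allow 10% timestamp wobble but no dropped samples
    if dt.size and (np.any(dt > 1.5 * period) or np.any(dt < 0.5 * period)):
        raise FormatError(f"{path}: sampling gaps inconsistent with fs={fs} Hz")
    return SignalTrace(channel=channel, fs=fs, samples=v, t0=float(t[0]))


def write_trace(trace: SignalTrace, path: str | Path) -> None:
    """Write a trace as a ``time_s,value`` CSV (full float precision)."""
    df = pd.DataFrame({"time_s": trace.times, "value": trace.samples})
    df.to_csv(path, index=False, float_format="%.10g")


def segment(trace: SignalTrace, window_length_s: float = DEFAULT_WINDOW_S) -> list[SignalWindow]:
    """Cut a trace into non-overlapping half-open calculation segments.

    A trailing partial window is dropped so every window holds the same number
    of samples.  Raises if the trace is shorter than one window.
    """
    if window_length_s <= 0:
        raise InvalidArgumentError("window_length_s must be positive")
    n_per = int(round(window_length_s * trace.fs))
    if n_per < 2:
        raise InvalidArgumentError("window too short for the sampling rate")
    n_windows = trace.samples.size // n_per
    if n_windows == 0:
        raise InvalidArgumentError(
            f"trace of {trace.duration_s:.3g}s shorter than one {window_length_s}s window"
        )
    windows = []
    for k in range(n_windows):
        chunk = trace.samples[k * n_per : (k + 1) * n_per]
        windows.append(
            SignalWindow(
                channel=trace.channel,
                index=k,
                fs=trace.fs,
                samples=chunk,
                t_start=trace.t0 + k * n_per / trace.fs,
            )
        )
    return windows
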