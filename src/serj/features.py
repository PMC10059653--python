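"""Pulse-wave fiducials and the per-window feature catalog.

The named optimal features are

* ``bpnn50`` — fraction of successive inter-beat-interval differences whose
  magnitude exceeds 50 ms (a pNN50-style statistic over main-wave intervals),
* ``eda_range`` — max − min of the EDA calculation segment,
* ``eda_1dmean`` — mean first-order difference of the EDA segment, which
  telescopes to ``(x_N − x_1)/(N − 1)``.

Around them sits the full catalog the selection procedure screens: 24 EDA and
18 pulse time-domain descriptors, six frequency-domain descriptors per channel
(one shared implementation for both), and 7 EDA / 10 pulse physiological
descriptors (SCR-like phasic events for EDA; beat-timing and fiducial-
amplitude statistics for the pulse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from serj.errors import InsufficientBeatsError, InvalidArgumentError
from serj.signal_io import SignalTrace, SignalWindow


# ---------------------------------------------------------------------------
# Optimal features
# ---------------------------------------------------------------------------

def bpnn50(intervals_ms, threshold_ms: float = 50.0, signed_diffs: bool = False) -> float:
    """Fraction of successive interval differences exceeding ``threshold_ms``.

    ``intervals_ms`` are successive main-wave inter-beat intervals.  The
    comparison is strict and by default on the magnitude of the difference
    (the pNN50 convention); ``signed_diffs`` restricts it to increases.
    """
    x = np.asarray(list(intervals_ms), dtype=float)
    if x.size < 2:
        raise InvalidArgumentError("bpnn50 needs at least 2 intervals")
    d = np.diff(x)
    if not signed_diffs:
        d = np.abs(d)
    return float(np.count_nonzero(d > threshold_ms) / (x.size - 1))


def signal_range(x) -> float:
    """max(x) − min(x)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidArgumentError("empty window")
    return float(x.max() - x.min())


def one_d_mean(x) -> float:
    """Signed mean first-order difference; equals (x_N − x_1)/(N − 1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError("one_d_mean needs at least 2 samples")
    return float(np.mean(np.diff(x)))


# ---------------------------------------------------------------------------
# Pulse fiducials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseFiducials:
    """Per-beat landmarks, each as (time s, amplitude)."""

    main_wave: tuple[float, float]
    dicrotic_anterior: tuple[float, float]
    dicrotic_notch: tuple[float, float]
    dicrotic_wave: tuple[float, float]
    period_s: float
    t_onset_to_notch_s: float
    t_onset_to_main_peak_s: float


def main_peak_times(
    obj: SignalTrace | SignalWindow,
    fs: float | None = None,
    chunk_s: float = 10.0,
    overlap_s: float = 0.35,
) -> np.ndarray:
    """Main-wave peak instants by prominence-based peak picking.

    The dicrotic wave's prominence is bounded by its height above the notch,
    well below the main wave's, so a prominence floor at 30 % of the local
    robust amplitude span separates the two.  Detection runs on overlapping
    chunks with chunk-local prominence so that slow amplitude changes across
    a recording (perfusion, contact pressure) do not mask low-amplitude
    stretches; duplicate peaks in the overlaps are merged.
    """
    if isinstance(obj, (SignalTrace, SignalWindow)):
        x, fs = obj.samples, obj.fs
        t0 = obj.t0 if isinstance(obj, SignalTrace) else obj.t_start
    else:
        x = np.asarray(obj, dtype=float)
        if fs is None:
            raise InvalidArgumentError("fs required for bare arrays")
        t0 = 0.0
    n_chunk = max(2, int(chunk_s * fs))
    n_over = int(overlap_s * fs)
    distance = max(1, int(0.3 * fs))
    found: set[int] = set()
    for start in range(0, x.size, n_chunk):
        lo_i = max(0, start - n_over)
        hi_i = min(x.size, start + n_chunk + n_over)
        seg = x[lo_i:hi_i]
        # span from detrended samples so slow baseline drift cannot mask beats
        p5, p95 = np.percentile(sps.detrend(seg), [5, 95])
        span = p95 - p5
        if span <= 0:
            continue
        peaks, _ = sps.find_peaks(seg, prominence=0.3 * span, distance=distance)
        found.update(int(p) + lo_i for p in peaks)
    if not found:
        raise InsufficientBeatsError("flat signal: no beats detectable")
    idx = np.sort(np.fromiter(found, dtype=int))
    # merge duplicates from overlapping chunks
    keep = np.concatenate(([True], np.diff(idx) >= distance))
    idx = idx[keep]
    if idx.size < 2:
        raise InsufficientBeatsError(f"only {idx.size} beat(s) detected")
    return t0 + idx / fs


def detect_beats(obj: SignalTrace | SignalWindow) -> list[PulseFiducials]:
    """Locate all four fiducials for each fully observed beat.

    A beat spans one main-wave peak to the next; the dicrotic notch is the
    lowest local minimum between the main wave and the dicrotic wave, the
    dicrotic wave the largest local maximum after the notch within 60 % of the
    period, and the dicrotic anterior wave the point of maximum curvature
    (slope flattening) on the descent from main peak to notch.  The waveform
    onset is the foot (local minimum) preceding the main peak.
    """
    x, fs = obj.samples, obj.fs
    t0 = obj.t0 if isinstance(obj, SignalTrace) else obj.t_start
    peak_t = main_peak_times(obj)
    peak_idx = np.round((peak_t - t0) * fs).astype(int)

    out: list[PulseFiducials] = []
    for i in range(peak_idx.size - 1):
        p, q = peak_idx[i], peak_idx[i + 1]
        period = (q - p) / fs
        seg_end = p + int(0.6 * (q - p))
        seg = x[p:seg_end]
        if seg.size < 5:
            continue
        # notch: first local minimum on the descent from the main peak;
        # dicrotic wave: first local maximum after it.  A small prominence
        # floor suppresses residual noise wiggles.
        floor = 0.02 * (seg.max() - seg.min())
        minima, _ = sps.find_peaks(-seg, prominence=floor)
        if minima.size:
            notch_rel = int(minima[0])
        else:
            notch_rel = int(np.argmin(seg))
        tail = seg[notch_rel:]
        maxima, _ = sps.find_peaks(tail, prominence=floor)
        if maxima.size:
            dw_rel = notch_rel + int(maxima[0])
        else:
            dw_rel = notch_rel + int(np.argmax(tail))
        # anterior shoulder: maximum curvature between main peak and notch
        desc = seg[: notch_rel + 1]
        if desc.size >= 3:
            ant_rel = 1 + int(np.argmax(np.diff(desc, 2)))
        else:
            ant_rel = 0
        # onset: foot preceding the main peak
        back = max(0, p - int(0.4 * (q - p)))
        pre = x[back : p + 1]
        pre_minima, _ = sps.find_peaks(-pre)
        onset_idx = back + (int(pre_minima[-1]) if pre_minima.size else int(np.argmin(pre)))

        tt = lambda idx: t0 + idx / fs
        out.append(
            PulseFiducials(
                main_wave=(tt(p), float(x[p])),
                dicrotic_anterior=(tt(p + ant_rel), float(x[p + ant_rel])),
                dicrotic_notch=(tt(p + notch_rel), float(x[p + notch_rel])),
                dicrotic_wave=(tt(p + dw_rel), float(x[p + dw_rel])),
                period_s=period,
                t_onset_to_notch_s=tt(p + notch_rel) - tt(onset_idx),
                t_onset_to_main_peak_s=tt(p) - tt(onset_idx),
            )
        )
    if len(out) < 1:
        raise InsufficientBeatsError("no complete beat could be delineated")
    return out


def intervals_in_window(peak_times: np.ndarray, t_start: float, t_end: float) -> np.ndarray:
    """Inter-beat intervals (ms) whose two bounding peaks lie in the window."""
    inside = peak_times[(peak_times >= t_start) & (peak_times < t_end)]
    return np.diff(inside) * 1000.0


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

TIME_DOMAIN_EDA = (
    "mean", "std", "var", "median", "min", "max", "range", "iqr", "skew", "kurtosis",
    "rms", "mad", "p10", "p90", "zcr", "1dmean", "1dabsmean", "1dstd", "1dmax",
    "2dmean", "2dabsmean", "2dstd", "slope", "energy",
)  # 24
TIME_DOMAIN_PULSE = (
    "mean", "std", "var", "median", "min", "max", "range", "iqr", "skew", "kurtosis",
    "rms", "1dmean", "1dabsmean", "1dstd", "2dmean", "2dabsmean", "zcr", "slope",
)  # 18
FREQ_DOMAIN = (
    "total_power", "bp_low", "bp_mid", "bp_high", "spectral_centroid", "spectral_entropy",
)  # 6 per channel, one shared implementation
PHYSIO_EDA = (
    "scr_count", "scr_amp_mean", "scr_amp_max", "scr_rise_mean",
    "tonic_mean", "tonic_slope", "phasic_power",
)  # 7
PHYSIO_PULSE = (
    "hr_mean", "ibi_mean", "sdnn", "rmssd", "bpnn50", "main_amp_mean",
    "dicrotic_amp_mean", "notch_amp_mean", "dicrotic_main_ratio", "t_peak_to_notch_mean",
)  # 10

#: Frequency bands (Hz) for the shared band-power mold.
FREQ_BANDS = {"bp_low": (0.0, 0.5), "bp_mid": (0.5, 2.0), "bp_high": (2.0, 5.0)}


def catalog() -> dict[str, dict[str, tuple[str, ...]]]:
    """The full feature catalog, by family and channel."""
    return {
        "time_domain": {"eda": TIME_DOMAIN_EDA, "ppg": TIME_DOMAIN_PULSE},
        "frequency_domain": {"eda": FREQ_DOMAIN, "ppg": FREQ_DOMAIN},
        "physiological": {"eda": PHYSIO_EDA, "ppg": PHYSIO_PULSE},
    }


def feature_names() -> list[str]:
    """Flat, ordered list of catalog feature names with channel prefixes.

    ``bpnn50``, ``eda_range`` and ``eda_1dmean`` keep their canonical names.
    """
    names: list[str] = []
    cat = catalog()
    for family in ("time_domain", "frequency_domain", "physiological"):
        for channel in ("eda", "ppg"):
            for feat in cat[family][channel]:
                if feat == "bpnn50":
                    names.append("bpnn50")
                else:
                    names.append(f"{channel}_{feat}")
    return names


def _time_domain(x: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    d1 = np.diff(x)
    d2 = np.diff(x, 2)
    xc = x - x.mean()
    vals = {
        "mean": x.mean(), "std": x.std(ddof=1), "var": x.var(ddof=1),
        "median": np.median(x), "min": x.min(), "max": x.max(),
        "range": x.max() - x.min(), "iqr": np.subtract(*np.percentile(x, [75, 25])),
        "skew": stats.skew(x), "kurtosis": stats.kurtosis(x),
        "rms": np.sqrt(np.mean(x**2)), "mad": np.median(np.abs(x - np.median(x))),
        "p10": np.percentile(x, 10), "p90": np.percentile(x, 90),
        "zcr": np.count_nonzero(np.diff(np.signbit(xc))) / max(1, x.size - 1),
        "1dmean": d1.mean(), "1dabsmean": np.abs(d1).mean(), "1dstd": d1.std(ddof=1),
        "1dmax": np.abs(d1).max(),
        "2dmean": d2.mean(), "2dabsmean": np.abs(d2).mean(), "2dstd": d2.std(ddof=1),
        "slope": np.polyfit(np.arange(x.size), x, 1)[0], "energy": float(np.sum(xc**2)),
    }
    return {k: float(vals[k]) for k in names}


def _freq_domain(x: np.ndarray, fs: float) -> dict[str, float]:
    f, pxx = sps.periodogram(x - x.mean(), fs=fs)
    total = float(np.trapezoid(pxx, f))
    out = {"total_power": total}
    for name, (lo, hi) in FREQ_BANDS.items():
        m = (f >= lo) & (f < hi)
        out[name] = float(np.trapezoid(pxx[m], f[m])) if m.any() else 0.0
    psum = pxx.sum()
    if psum > 0:
        p = pxx / psum
        out["spectral_centroid"] = float(np.sum(f * p))
        nz = p[p > 0]
        out["spectral_entropy"] = float(-np.sum(nz * np.log(nz)) / np.log(p.size))
    else:
        out["spectral_centroid"] = 0.0
        out["spectral_entropy"] = 0.0
    return out


def _physio_eda(x: np.ndarray, fs: float) -> dict[str, float]:
    # crude tonic estimate: moving 2-s minimum, smoothed
    w = max(1, int(2.0 * fs))
    from scipy.ndimage import minimum_filter1d, uniform_filter1d

    tonic = uniform_filter1d(minimum_filter1d(x, size=w), size=w)
    phasic = x - tonic
    prom = 0.05 * max(signal_range(x), 1e-12)
    peaks, props = sps.find_peaks(phasic, prominence=prom)
    if peaks.size:
        amp = phasic[peaks]
        rise = (peaks - props["left_bases"]) / fs
        scr = {
            "scr_count": float(peaks.size),
            "scr_amp_mean": float(amp.mean()),
            "scr_amp_max": float(amp.max()),
            "scr_rise_mean": float(rise.mean()),
        }
    else:
        scr = {"scr_count": 0.0, "scr_amp_mean": 0.0, "scr_amp_max": 0.0, "scr_rise_mean": 0.0}
    return {
        **scr,
        "tonic_mean": float(tonic.mean()),
        "tonic_slope": float(np.polyfit(np.arange(x.size) / fs, tonic, 1)[0]),
        "phasic_power": float(np.mean(phasic**2)),
    }


def _physio_pulse(window: SignalWindow, beats: list[PulseFiducials]) -> dict[str, float | None]:
    in_win = [b for b in beats if window.t_start <= b.main_wave[0] < window.t_end]
    ivals = np.array([b.period_s for b in in_win]) * 1000.0
    if len(in_win) < 3 or ivals.size < 2:
        return {k: None for k in PHYSIO_PULSE}
    main_amp = np.array([b.main_wave[1] for b in in_win])
    dic_amp = np.array([b.dicrotic_wave[1] for b in in_win])
    notch_amp = np.array([b.dicrotic_notch[1] for b in in_win])
    return {
        "hr_mean": float(60000.0 / ivals.mean()),
        "ibi_mean": float(ivals.mean()),
        "sdnn": float(ivals.std(ddof=1)),
        "rmssd": float(np.sqrt(np.mean(np.diff(ivals) ** 2))),
        "bpnn50": bpnn50(ivals),
        "main_amp_mean": float(main_amp.mean()),
        "dicrotic_amp_mean": float(dic_amp.mean()),
        "notch_amp_mean": float(notch_amp.mean()),
        "dicrotic_main_ratio": float(dic_amp.mean() / main_amp.mean()),
        "t_peak_to_notch_mean": float(
            np.mean([b.dicrotic_notch[0] - b.main_wave[0] for b in in_win])
        ),
    }


def extract_catalog(
    eda_window: SignalWindow,
    ppg_window: SignalWindow,
    beats: list[PulseFiducials] | None = None,
) -> dict[str, float | None]:
    """One value per catalog feature for an aligned window pair.

    Beat-derived pulse features are reported as absent (``None``) — never
    zero — when fewer than three beats fall inside the window; a constant
    channel likewise yields absent values for that channel.
    """
    if abs(eda_window.t_start - ppg_window.t_start) > 0.5 / eda_window.fs:
        raise InvalidArgumentError("EDA and PPG windows are not aligned")
    out: dict[str, float | None] = {}

    for channel, window, names in (
        ("eda", eda_window, TIME_DOMAIN_EDA),
        ("ppg", ppg_window, TIME_DOMAIN_PULSE),
    ):
        degenerate = window.x_max <= window.x_min
        if degenerate:
            td = {k: None for k in names}
            fd = {k: None for k in FREQ_DOMAIN}
        else:
            td = _time_domain(window.samples, names)
            fd = _freq_domain(window.samples, window.fs)
        out.update({f"{channel}_{k}": v for k, v in td.items()})
        out.update({f"{channel}_{k}": v for k, v in fd.items()})

    if eda_window.x_max > eda_window.x_min:
        out.update({f"eda_{k}": v for k, v in _physio_eda(eda_window.samples, eda_window.fs).items()})
    else:
        out.update({f"eda_{k}": None for k in PHYSIO_EDA})

    if beats is None:
        try:
            beats = detect_beats(ppg_window)
        except InsufficientBeatsError:
            beats = []
    physio = _physio_pulse(ppg_window, beats)
    for k, v in physio.items():
        out["bpnn50" if k == "bpnn50" else f"ppg_{k}"] = v
    return out
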