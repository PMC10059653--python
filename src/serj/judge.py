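"""The core judgment engine: adaptive thresholds and the quadrant rule tree.

Emotional trend lives in the valence–arousal plane; its four quadrants are
HAPV (high arousal, positive valence), HANV, LANV and LAPV.  Per 10-s
calculation segment the engine evaluates two rule branches:

EDA branch
    1. If the normalized EDA ``range`` is not above the stream threshold
       ``x_th``, the branch yields nothing.
    2. Otherwise, if the window maximum precedes the minimum
       (``n_max <= n_min``) the trend is **LAPV**.
    3. Otherwise, if the normalized EDA ``1dmean`` exceeds its ``x_th`` the
       trend is **HANV**; else nothing.

Pulse branch
    1. If the normalized ``BpNN50`` is not above its ``x_th``, nothing.
    2. Otherwise, if the normalized pulse ``range`` exceeds its ``x_th`` the
       trend is **LANV**.
    3. Otherwise, if the normalized pulse ``1dmean`` exceeds its ``x_th`` the
       trend is **HAPV**; else nothing.

Each feature stream carries its own threshold ``x_th``: the mean of the
min–max-normalized stream values over a reference (calibration) span,

    x_th = (1/n) * sum_i (x_i - x_min) / (x_max - x_min).

Normalization parameters are frozen from that span; later values are clipped
into [0, 1].  All comparisons are strict, so boundary equality falls to the
"otherwise" arm.  When both branches yield a quadrant the conflict resolves by
the fixed priority HANV > LANV > LAPV > HAPV (negative-valence states drive
the adaptation policy; HAPV triggers nothing).  Every decision records a rule
trace sufficient to replay it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from serj.errors import DegenerateThresholdError, InvalidArgumentError


class EmotionQuadrant(str, enum.Enum):
    """Valence–arousal quadrant; (arousal, valence) signs follow the V-A plane."""

    HAPV = "HAPV"  # (+, +)
    HANV = "HANV"  # (+, -)
    LANV = "LANV"  # (-, -)
    LAPV = "LAPV"  # (-, +)
    UNDECIDED = "UNDECIDED"

    @property
    def arousal_sign(self) -> int:
        return {"HAPV": 1, "HANV": 1, "LANV": -1, "LAPV": -1}.get(self.value, 0)

    @property
    def valence_sign(self) -> int:
        return {"HAPV": 1, "HANV": -1, "LANV": -1, "LAPV": 1}.get(self.value, 0)


#: Conflict resolution when both rule branches yield a quadrant.
PRIORITY: tuple[EmotionQuadrant, ...] = (
    EmotionQuadrant.HANV,
    EmotionQuadrant.LANV,
    EmotionQuadrant.LAPV,
    EmotionQuadrant.HAPV,
)

#: Names of the gated feature streams, in evaluation order.
JUDGE_FEATURES = ("eda_range", "eda_1dmean", "bpnn50", "pulse_range", "pulse_1dmean")


@dataclass
class FeatureStream:
    """A named feature over windows with frozen normalization and threshold."""

    name: str
    channel: str
    x_min: float
    x_max: float
    x_th: float

    def normalize(self, value: float) -> float:
        """Min–max normalize with the frozen span, clipping into [0, 1]."""
        z = (value - self.x_min) / (self.x_max - self.x_min)
        return float(np.clip(z, 0.0, 1.0))


def compute_threshold(values, name: str = "", channel: str = "") -> FeatureStream:
    """Build a stream from its reference-span values.

    ``x_th`` is the mean of the min–max-normalized values.  A constant span
    admits no normalization and raises :class:`DegenerateThresholdError`.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise InvalidArgumentError("reference span needs at least 2 values")
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise DegenerateThresholdError(f"stream {name!r}: constant reference span")
    x_th = float(np.mean((v - lo) / (hi - lo)))
    return FeatureStream(name=name, channel=channel, x_min=lo, x_max=hi, x_th=x_th)


@dataclass
class EmotionDecision:
    """Outcome for one window, with an auditable trace of every rule tested."""

    window: int
    quadrant: EmotionQuadrant
    branch: str  # "eda" | "pulse" | "both" | "none"
    rule_trace: list[tuple[str, float, float, bool]] = field(default_factory=list)
    partial: bool = False  # pulse features were unavailable

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "quadrant": self.quadrant.value,
            "branch": self.branch,
            "partial": self.partial,
            "rule_trace": [list(t) for t in self.rule_trace],
        }


@dataclass
class WindowFeatures:
    """The per-window raw feature values the rule tree consumes."""

    window: int
    eda_range: float
    eda_1dmean: float
    n_max: int
    n_min: int
    bpnn50: float | None  # None when too few beats were detected
    pulse_range: float | None
    pulse_1dmean: float | None


def judge_window(
    feats: WindowFeatures,
    streams: dict[str, FeatureStream],
    priority: tuple[EmotionQuadrant, ...] = PRIORITY,
) -> EmotionDecision:
    """Apply both rule branches to one window and resolve conflicts."""
    trace: list[tuple[str, float, float, bool]] = []

    def test(stream_name: str, value: float) -> bool:
        s = streams[stream_name]
        z = s.normalize(value)
        outcome = z > s.x_th
        trace.append((f"{stream_name}>x_th", z, s.x_th, outcome))
        return outcome

    # EDA branch
    eda_result: EmotionQuadrant | None = None
    if test("eda_range", feats.eda_range):
        ordered = feats.n_max <= feats.n_min
        trace.append(("n_max<=n_min", float(feats.n_max), float(feats.n_min), ordered))
        if ordered:
            eda_result = EmotionQuadrant.LAPV
        elif test("eda_1dmean", feats.eda_1dmean):
            eda_result = EmotionQuadrant.HANV

    # Pulse branch
    pulse_result: EmotionQuadrant | None = None
    partial = feats.bpnn50 is None
    if not partial:
        if test("bpnn50", feats.bpnn50):
            if test("pulse_range", feats.pulse_range):
                pulse_result = EmotionQuadrant.LANV
            elif test("pulse_1dmean", feats.pulse_1dmean):
                pulse_result = EmotionQuadrant.HAPV

    candidates = [q for q in (eda_result, pulse_result) if q is not None]
    if not candidates:
        quadrant, branch = EmotionQuadrant.UNDECIDED, "none"
    elif len(candidates) == 1:
        quadrant = candidates[0]
        branch = "eda" if eda_result is not None else "pulse"
    else:
        quadrant = min(candidates, key=priority.index)
        branch = "both"
    return EmotionDecision(
        window=feats.window, quadrant=quadrant, branch=branch, rule_trace=trace, partial=partial
    )


def build_streams(
    calibration: list[WindowFeatures],
) -> dict[str, FeatureStream]:
    """Freeze per-feature normalization and thresholds from a calibration span."""
    channel = {
        "eda_range": "eda",
        "eda_1dmean": "eda",
        "bpnn50": "ppg",
        "pulse_range": "ppg",
        "pulse_1dmean": "ppg",
    }
    streams = {}
    for name in JUDGE_FEATURES:
        vals = [getattr(f, name) for f in calibration]
        vals = [v for v in vals if v is not None]
        if len(vals) < 2:
            raise InvalidArgumentError(
                f"stream {name!r}: fewer than 2 usable calibration values"
            )
        streams[name] = compute_threshold(vals, name=name, channel=channel[name])
    return streams


def judge_feature_windows(
    feature_windows: list[WindowFeatures],
    calibration_windows: int = 4,
    priority: tuple[EmotionQuadrant, ...] = PRIORITY,
) -> list[EmotionDecision]:
    """Judge a whole session given its per-window features.

    The first ``calibration_windows`` windows only seed the thresholds and are
    emitted as UNDECIDED; every later window receives a rule-tree decision.
    """
    if calibration_windows < 2:
        raise InvalidArgumentError("calibration_windows must be >= 2")
    if len(feature_windows) < calibration_windows + 1:
        raise InvalidArgumentError(
            f"need at least {calibration_windows + 1} windows, got {len(feature_windows)}"
        )
    streams = build_streams(feature_windows[:calibration_windows])
    decisions = [
        EmotionDecision(window=f.window, quadrant=EmotionQuadrant.UNDECIDED, branch="none")
        for f in feature_windows[:calibration_windows]
    ]
    for f in feature_windows[calibration_windows:]:
        decisions.append(judge_window(f, streams, priority))
    return decisions
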