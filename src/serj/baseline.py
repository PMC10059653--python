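"""Conventional machine-learning baseline and the head-to-head comparison.

Approach 1 is a support-vector machine over the full feature catalog with a
stratified 70/30 train/validation split.  Approach 2 is the rule-based judge.
:func:`compare_approaches` runs both on the same windows of a labeled session
and reports accuracy, confusion counts and per-quadrant activation counts
(through the adaptation policy, so the comparison is in the same currency as
the reference activation tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from serj import adaptation as adapt
from serj.errors import InvalidArgumentError, StratificationError
from serj.judge import EmotionQuadrant
from serj.pipeline import feature_table, judge_session
from serj.synth import SyntheticSession

_LABELS = ("HAPV", "HANV", "LANV", "LAPV")


@dataclass
class BaselineModel:
    """A fitted SVM pipeline plus its split bookkeeping."""

    pipeline: Pipeline
    classes: list[str]
    train_fraction: float
    seed: int
    validation_accuracy: float

    def predict(self, table: pd.DataFrame) -> list[EmotionQuadrant]:
        pred = self.pipeline.predict(table.to_numpy(dtype=float))
        return [EmotionQuadrant(p) for p in pred]


def train_baseline(
    table: pd.DataFrame,
    labels,
    split: float = 0.7,
    seed: int = 0,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
    min_per_class: int = 10,
) -> BaselineModel:
    """Fit the SVM on a stratified ``split`` fraction of the windows."""
    if not 0.0 < split < 1.0:
        raise InvalidArgumentError("split must be in (0, 1)")
    y = np.asarray([EmotionQuadrant(l).value for l in labels])
    if len(y) != len(table):
        raise InvalidArgumentError("one label per window required")
    counts = pd.Series(y).value_counts()
    if (counts < min_per_class).any():
        worst = counts.idxmin()
        raise StratificationError(
            f"class {worst} has {counts.min()} windows; need >= {min_per_class}"
        )
    X = table.to_numpy(dtype=float)
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, train_size=split, random_state=seed, stratify=y
    )
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="mean")),
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C, gamma=gamma, random_state=seed)),
        ]
    )
    pipe.fit(X_tr, y_tr)
    acc = float(np.mean(pipe.predict(X_va) == y_va))
    return BaselineModel(
        pipeline=pipe,
        classes=sorted(set(y)),
        train_fraction=split,
        seed=seed,
        validation_accuracy=acc,
    )


def _confusion(y_true: list[str], y_pred: list[str]) -> pd.DataFrame:
    idx = list(_LABELS) + ["UNDECIDED"]
    cm = pd.DataFrame(0, index=idx, columns=idx)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    return cm


@dataclass
class ComparisonResult:
    """Approach 1 (SVM) vs Approach 2 (rule-based judge) on shared windows.

    ``activations`` counts fired events whose triggering decision matches the
    ground-truth quadrant of that window (an event fired on a misjudged
    window does not activate the subject's actual emotion); ``events_total``
    counts all fired events regardless.
    """

    n_windows: int
    split: str
    accuracy: dict[str, float]
    confusion: dict[str, pd.DataFrame]
    activations: dict[str, dict[str, int]]
    events_total: dict[str, int] = field(default_factory=dict)
    decisions: dict[str, list[str]] = field(default_factory=dict)

    def total_activations(self, approach: str) -> int:
        return sum(self.activations[approach].values())


def compare_approaches(
    session: SyntheticSession,
    model: BaselineModel | None,
    calibration_windows: int = 4,
    persistence: int = 1,
    refractory: int = 1,
) -> ComparisonResult:
    """Evaluate both approaches on the post-calibration windows of a session."""
    if model is None:
        raise InvalidArgumentError("baseline model must be trained before comparison")
    decisions = judge_session(session, calibration_windows=calibration_windows)
    table = feature_table(session)
    n = min(len(decisions), len(session.labels), len(table))
    if n <= calibration_windows:
        raise InvalidArgumentError("no post-calibration windows to compare on")
    idx = range(calibration_windows, n)
    truth = [session.labels[i].value for i in idx]

    judged = [decisions[i].quadrant.value for i in idx]
    svm = [q.value for q in model.predict(table.iloc[list(idx)])]

    result = ComparisonResult(
        n_windows=len(truth),
        split=f"cross-session SVM (train fraction {model.train_fraction}, seed {model.seed})",
        accuracy={
            "approach1_svm": float(np.mean([p == t for p, t in zip(svm, truth)])),
            "approach2_rules": float(np.mean([p == t for p, t in zip(judged, truth)])),
        },
        confusion={
            "approach1_svm": _confusion(truth, svm),
            "approach2_rules": _confusion(truth, judged),
        },
        activations={},
        decisions={"approach1_svm": svm, "approach2_rules": judged, "truth": truth},
    )
    truth_at = {i: session.labels[i].value for i in idx}
    for name, stream in (("approach1_svm", svm), ("approach2_rules", judged)):
        dec = [
            adapt.DecisionLike(window=i, quadrant=EmotionQuadrant(q))
            for i, q in zip(idx, stream)
        ]
        events, _ = adapt.policy_step(dec, persistence=persistence, refractory=refractory)
        counts = {q: 0 for q in ("HANV", "LAPV", "LANV")}
        for e in events:
            if truth_at.get(e.window) == e.quadrant.value:
                counts[e.quadrant.value] += 1
        result.activations[name] = counts
        result.events_total[name] = len(events)
    return result
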