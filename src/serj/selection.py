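"""Optimal-feature selection: PCA loading-weight cut, then Pearson screening.

Stage 1 standardizes the feature table, runs PCA, keeps enough components to
reach a target explained-variance fraction, and scores each feature by its
weight in the retained principal components — its communality, the fraction
of the feature's variance the retained components explain,
``sum_k lambda_k * loading_{f,k}^2``.  Features scoring above a weight
threshold survive; the default threshold 0.5 keeps features whose variance is
majority-explained by the retained subspace (``weight_threshold="mean"`` uses
the mean score instead).  The communality is used rather than a single
largest loading because features that share a strong label-driven direction
split that direction's loading among themselves; the communality credits
each of them with the shared variance.

Stage 2 correlates each surviving feature with a one-vs-rest indicator of each
quadrant (Pearson r with its two-sided significance P) and keeps a feature for
a quadrant when ``|r| >= r_min`` and ``P < alpha``.  The union over quadrants
is the final optimal subset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from serj.errors import InvalidArgumentError
from serj.judge import EmotionQuadrant

QUADRANTS = (
    EmotionQuadrant.HAPV,
    EmotionQuadrant.HANV,
    EmotionQuadrant.LANV,
    EmotionQuadrant.LAPV,
)


@dataclass
class SelectionReport:
    """Everything the two-stage selection produced, serializable to JSON."""

    loadings: pd.DataFrame  # feature × retained component
    explained_variance: list[float]
    weight_threshold: float
    weights: dict[str, float]
    subset_pca: list[str]
    correlations: pd.DataFrame  # (feature, quadrant) → r, p
    subset_final: list[str]
    per_quadrant: dict[str, list[str]] = field(default_factory=dict)
    dropped_constant: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "explained_variance": self.explained_variance,
                "weight_threshold": self.weight_threshold,
                "weights": self.weights,
                "subset_pca": self.subset_pca,
                "correlations": {
                    f"{f}|{q}": {"r": float(r), "p": float(p)}
                    for (f, q), (r, p) in self.correlations[["r", "p"]].iterrows()
                },
                "subset_final": self.subset_final,
                "per_quadrant": self.per_quadrant,
                "dropped_constant": self.dropped_constant,
            },
            indent=2,
        )


def _clean_table(table: pd.DataFrame, impute: str = "drop") -> tuple[pd.DataFrame, list[str]]:
    """Drop constant columns; handle absent values by row-drop or column-mean."""
    df = table.astype(float)
    if impute == "drop":
        df = df.dropna(axis=0, how="any")
    elif impute == "mean":
        df = df.fillna(df.mean())
    else:
        raise InvalidArgumentError(f"unknown missing-value policy {impute!r}")
    constant = [c for c in df.columns if df[c].nunique() <= 1 or not np.isfinite(df[c]).all()]
    if constant:
        warnings.warn(f"excluding {len(constant)} constant/non-finite feature column(s)")
        df = df.drop(columns=constant)
    return df, constant


def pca_subset(
    table: pd.DataFrame,
    variance_target: float = 0.9,
    weight_threshold: float | str = 0.5,
    impute: str = "mean",
) -> SelectionReport:
    """Stage 1: retain features with above-threshold weight (communality).

    ``weight_threshold="mean"`` uses the mean weight across features instead
    of an absolute cut.  Returns a partial report (correlation fields empty).
    """
    df, dropped = _clean_table(table, impute)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 windows and 2 usable features")
    z = (df - df.mean()) / df.std(ddof=1)
    pca = PCA()
    pca.fit(z.to_numpy())
    evr = pca.explained_variance_ratio_
    n_keep = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
    n_keep = min(n_keep, len(evr))
    loadings = pd.DataFrame(
        pca.components_[:n_keep].T,
        index=df.columns,
        columns=[f"PC{i + 1}" for i in range(n_keep)],
    )
    lam = pca.explained_variance_[:n_keep]
    # communality of each (unit-variance) feature under the retained components
    weights = pd.Series((lam[None, :] * loadings.to_numpy() ** 2).sum(axis=1), index=df.columns)
    thr = float(weights.mean()) if weight_threshold == "mean" else float(weight_threshold)
    subset = [f for f in df.columns if weights[f] > thr]
    return SelectionReport(
        loadings=loadings,
        explained_variance=[float(v) for v in evr[:n_keep]],
        weight_threshold=thr,
        weights={f: float(w) for f, w in weights.items()},
        subset_pca=subset,
        correlations=pd.DataFrame(columns=["r", "p"]),
        subset_final=[],
        dropped_constant=dropped,
    )


def pcc_screen(
    table: pd.DataFrame,
    labels,
    report: SelectionReport,
    alpha: float = 0.05,
    r_min: float = 0.3,
) -> SelectionReport:
    """Stage 2: Pearson screening of the PCA subset against quadrant indicators."""
    labels = [EmotionQuadrant(l) for l in labels]
    if len(labels) != len(table):
        raise InvalidArgumentError("one label per window required")
    df, _ = _clean_table(table[report.subset_pca], impute="mean")
    y = pd.Series([l.value for l in labels], index=table.index).loc[df.index]

    rows = []
    per_quadrant: dict[str, list[str]] = {}
    for q in QUADRANTS:
        indicator = (y == q.value).astype(float)
        if indicator.sum() == 0:
            warnings.warn(f"quadrant {q.value} absent from labels; skipped")
            continue
        if indicator.sum() < 3:
            warnings.warn(f"quadrant {q.value} has fewer than 3 windows")
        kept = []
        for f in df.columns:
            x = df[f]
            if x.std(ddof=0) == 0:
                continue
            r, p = stats.pearsonr(x, indicator)
            rows.append({"feature": f, "quadrant": q.value, "r": float(r), "p": float(p)})
            if abs(r) >= r_min and p < alpha:
                kept.append(f)
        per_quadrant[q.value] = kept
    corr = pd.DataFrame(rows).set_index(["feature", "quadrant"]) if rows else pd.DataFrame(
        columns=["r", "p"]
    )
    final = [f for f in report.subset_pca if any(f in v for v in per_quadrant.values())]
    report.correlations = corr
    report.subset_final = final
    report.per_quadrant = per_quadrant
    return report


def select_optimal_features(
    table: pd.DataFrame,
    labels,
    variance_target: float = 0.9,
    weight_threshold: float | str = 0.5,
    alpha: float = 0.05,
    r_min: float = 0.3,
) -> SelectionReport:
    """Run both stages and return the completed report."""
    report = pca_subset(table, variance_target=variance_target, weight_threshold=weight_threshold)
    return pcc_screen(table, labels, report, alpha=alpha, r_min=r_min)
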