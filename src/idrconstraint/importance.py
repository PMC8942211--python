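"""Permutation feature importance for intolerant-vs-tolerant IDR separation.

Each IDR is described by the number of annotation records of each of the 25
feature classes overlapping it. A 100-tree random forest (Gini criterion)
separates mutation-intolerant from mutation-tolerant regions; feature
importance is the mean drop in average precision (in percentage points of
AP) over repeated shuffles of one feature column. The intolerant class is
the positive class: with a ~34:533 imbalance, average precision — not
accuracy — is the meaningful score. Importance is evaluated on the training
cohort by default (the published protocol); a held-out split is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .annotation_model import FEATURE_CLASSES, DisorderRegion, FeatureAnnotation

#: A feature is flagged important when shuffling it costs at least this many
#: percentage points of average precision.
IMPORTANT_DROP_PP = 5.0


@dataclass(frozen=True)
class ImportanceResult:
    feature_class: str
    mean_drop: float  # percentage points of average precision
    sd_drop: float
    rank: int
    important: bool


def feature_counts_per_idr(
    region: DisorderRegion, features: Sequence[FeatureAnnotation]
) -> np.ndarray:
    """Count of annotation records per class overlapping >= 1 region residue,
    in canonical feature order."""
    index = {k: i for i, k in enumerate(FEATURE_CLASSES)}
    counts = np.zeros(len(FEATURE_CLASSES), dtype=np.int64)
    for f in features:
        if f.accession != region.accession:
            continue
        if f.start <= region.end and f.end >= region.start:
            counts[index[f.feature_class]] += 1
    return counts


def build_matrix(
    regions: Sequence[DisorderRegion],
    features: Sequence[FeatureAnnotation],
    labels: dict[str, str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature-count matrix and binary labels (1 = intolerant) for regions
    present in ``labels`` with an intolerant/tolerant overall call."""
    by_acc: dict[str, list[FeatureAnnotation]] = {}
    for f in features:
        by_acc.setdefault(f.accession, []).append(f)
    X_rows, y_rows, ids = [], [], []
    for r in regions:
        label = labels.get(r.region_id)
        if label not in ("intolerant", "tolerant"):
            continue
        X_rows.append(feature_counts_per_idr(r, by_acc.get(r.accession, ())))
        y_rows.append(1 if label == "intolerant" else 0)
        ids.append(r.region_id)
    if not X_rows:
        raise ValueError("no labelled regions")
    return np.asarray(X_rows), np.asarray(y_rows), ids


def average_precision(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AP = sum_k (R_k - R_{k-1}) * P_k over descending score thresholds.

    Tied scores form a single threshold group: precision and recall are
    evaluated after the whole group is admitted.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be 1-D and equal length")
    n_pos = float(y.sum())
    if n_pos == 0:
        raise ValueError("average precision requires at least one positive label")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    n_seen = np.arange(1, y.size + 1)
    # last index of each tied-score group
    group_end = np.nonzero(np.diff(s_sorted, append=np.nan) != 0)[0]
    ap = 0.0
    prev_recall = 0.0
    for k in group_end:
        recall = tp[k] / n_pos
        precision = tp[k] / n_seen[k]
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


@dataclass
class TrainedClassifier:
    model: RandomForestClassifier
    baseline_ap: float

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class (intolerant) probability."""
        return self.model.predict_proba(X)[:, 1]


def train_classifier(
    X: np.ndarray, y: np.ndarray, seed: int, n_estimators: int = 100
) -> TrainedClassifier:
    """Fit the 100-tree Gini random forest; errors on single-class input."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = RandomForestClassifier(
        n_estimators=n_estimators, criterion="gini", random_state=seed
    )
    model.fit(X, y)
    return TrainedClassifier(model=model, baseline_ap=average_precision(y, model.predict_proba(X)[:, 1]))


def permutation_importance(
    clf: TrainedClassifier,
    X: np.ndarray,
    y: np.ndarray,
    repeats: int = 10,
    seed: int = 0,
) -> list[ImportanceResult]:
    """Mean/sd drop in average precision over ``repeats`` shuffles per column.

    Drops are in percentage points of AP and may be negative (not clipped).
    Results are ranked by descending mean drop (ties broken by canonical
    feature order); ranks are a permutation of 1..25.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    baseline = average_precision(y, clf.scores(X))
    drops = np.zeros((len(FEATURE_CLASSES), repeats))
    for j in range(len(FEATURE_CLASSES)):
        for r in range(repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            drops[j, r] = 100.0 * (baseline - average_precision(y, clf.scores(Xp)))
    mean_drop = drops.mean(axis=1)
    sd_drop = drops.std(axis=1, ddof=0)
    order = np.argsort(-mean_drop, kind="stable")
    rank = np.empty(len(FEATURE_CLASSES), dtype=int)
    rank[order] = np.arange(1, len(FEATURE_CLASSES) + 1)
    return [
        ImportanceResult(
            feature_class=FEATURE_CLASSES[j],
            mean_drop=float(mean_drop[j]),
            sd_drop=float(sd_drop[j]),
            rank=int(rank[j]),
            important=bool(mean_drop[j] >= IMPORTANT_DROP_PP),
        )
        for j in range(len(FEATURE_CLASSES))
    ]


def importance_to_frame(results: Sequence[ImportanceResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "feature_class": r.feature_class,
                "mean_drop": r.mean_drop,
                "sd_drop": r.sd_drop,
                "rank": r.rank,
                "important": r.important,
            }
            for r in sorted(results, key=lambda r: r.rank)
        ]
    )
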