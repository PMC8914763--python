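"""Nearest-neighbor classification and the repeated-split evaluation harness.

A feature vector is assigned the class (0 = no lesion, 1 = lesion) of its
single nearest training vector in Euclidean distance over the eight features,
optionally z-scored per feature with training-set statistics.  Evaluation
repeatedly draws random class-balanced training splits, classifies the
held-out members, and pools the confusion counts and continuous scores over
all repetitions into one report with sensitivity, specificity, accuracy, and
an ROC curve with its area.

The ROC score of a test case is the signed nearest-neighbor margin
``d(nearest class-0 neighbor) - d(nearest class-1 neighbor)``: positive means
lesion-leaning, and thresholding at zero reproduces the 1-NN label.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .exceptions import ProtocolError, ThermasymError, UndefinedMetricError
from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "LabeledDataset",
    "ConfusionMatrix",
    "ClassificationReport",
    "knn_classify",
    "evaluate",
    "metrics",
    "roc_curve",
    "feature_ttest",
]


@dataclasses.dataclass
class LabeledDataset:
    """Feature vectors with binary class labels (0 = NT, 1 = T)."""

    vectors: list[FeatureVector]
    labels: np.ndarray
    feature_order: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.vectors) != len(self.labels):
            raise ProtocolError("vectors and labels must have equal length")
        if not np.all(np.isin(self.labels, (0, 1))):
            raise ProtocolError("labels must be 0 (NT) or 1 (T)")

    def matrix(self) -> np.ndarray:
        return np.array(
            [[getattr(v, name) for name in self.feature_order] for v in self.vectors],
            dtype=float,
        )

    def __len__(self) -> int:
        return len(self.vectors)


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with the lesion class T as positive."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ProtocolError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )


@dataclasses.dataclass(frozen=True)
class ClassificationReport:
    """Pooled evaluation results of one repeated-split protocol run."""

    confusion: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    roc_points: np.ndarray  # (m, 2) of (false-positive rate, true-positive rate)
    auc: float
    n_repeats: int


def _nearest(dist: np.ndarray) -> int:
    """Index of the minimum distance; ties go to the lowest training-row index."""
    return int(np.argmin(dist))


def knn_classify(
    test_vec: FeatureVector | np.ndarray,
    train: LabeledDataset,
    config: PipelineConfig | None = None,
    train_matrix: np.ndarray | None = None,
) -> tuple[int, float]:
    """Classify one vector by its single nearest training neighbor.

    Returns ``(label, score)`` where ``score = d(nearest NT) - d(nearest T)``
    is positive when the vector is lesion-leaning; the label equals
    ``score > 0`` except for exact ties, which the lowest-index rule decides.

    ``train_matrix`` lets callers pass pre-standardized training features; the
    test vector must then be standardized consistently by the caller.
    """
    config = config or PipelineConfig()
    if config.k_neighbors != 1:
        raise ProtocolError("only the single-nearest-neighbor rule (k = 1) is supported")
    x = test_vec.as_array() if isinstance(test_vec, FeatureVector) else np.asarray(test_vec, float)
    m = train.matrix() if train_matrix is None else train_matrix
    labels = train.labels
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise ProtocolError("training set must contain both classes")
    dist = np.sqrt(((m - x) ** 2).sum(axis=1))
    nn = _nearest(dist)
    d_nt = dist[labels == 0].min()
    d_t = dist[labels == 1].min()
    return int(labels[nn]), float(d_nt - d_t)


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Sensitivity, specificity, and accuracy of a confusion matrix."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no true T cases")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no true NT cases")
    if cm.total == 0:
        raise UndefinedMetricError("accuracy undefined: no test cases")
    return (
        cm.tp / (cm.tp + cm.fn),
        cm.tn / (cm.tn + cm.fp),
        (cm.tp + cm.tn) / cm.total,
    )


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC points and area by sweeping every distinct score threshold.

    Predicts positive at score >= threshold; the curve runs from (0, 0) to
    (1, 1) and the trapezoidal area equals the Mann-Whitney concordance
    statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.count_nonzero(labels == 1))
    n_neg = int(np.count_nonzero(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ProtocolError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # keep only the last point of each tied-score run
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def _standardizer(train_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train_matrix.mean(axis=0)
    sd = train_matrix.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)  # constant feature carries no distance
    return mean, sd

def evaluate(
    dataset: LabeledDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> ClassificationReport:
    """Repeated class-balanced split evaluation with pooled results.

    Each of ``n_repeats`` repetitions draws ``n_train_per_class`` random
    members per class for training and tests on the remainder;
    standardization statistics come from the training portion only.
    Confusion counts and scores are pooled over all repetitions and the
    metrics and ROC/AUC computed from the pool.  Deterministic given ``seed``.
    """
    config = config or PipelineConfig()
    labels = dataset.labels
    idx_nt = np.flatnonzero(labels == 0)
    idx_t = np.flatnonzero(labels == 1)
    need = config.n_train_per_class + 1
    if len(idx_nt) < need or len(idx_t) < need:
        raise ProtocolError(
            f"need at least {need} members per class "
            f"(got {len(idx_nt)} NT, {len(idx_t)} T)"
        )
    full = dataset.matrix()
    rng = np.random.default_rng(seed)
    cm = ConfusionMatrix()
    pooled_scores: list[float] = []
    pooled_truth: list[int] = []
    for _ in range(config.n_repeats):
        train_idx = np.r_[
            rng.choice(idx_nt, size=config.n_train_per_class, replace=False),
            rng.choice(idx_t, size=config.n_train_per_class, replace=False),
        ]
        test_idx = np.setdiff1d(np.arange(len(dataset)), train_idx)
        train_m = full[train_idx]
        if config.standardize_features:
            mean, sd = _standardizer(train_m)
        else:
            mean, sd = np.zeros(full.shape[1]), np.ones(full.shape[1])
        train_set = LabeledDataset(
            vectors=[dataset.vectors[i] for i in train_idx],
            labels=labels[train_idx],
            feature_order=dataset.feature_order,
        )
        train_std = (train_m - mean) / sd
        tp = tn = fp = fn = 0
        for i in test_idx:
            pred, score = knn_classify(
                (full[i] - mean) / sd, train_set, config, train_matrix=train_std
            )
            truth = labels[i]
            if truth == 1:
                tp += pred == 1
                fn += pred == 0
            else:
                tn += pred == 0
                fp += pred == 1
            pooled_scores.append(score)
            pooled_truth.append(int(truth))
        cm = cm + ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
    sens, spec, acc = metrics(cm)
    points, auc = roc_curve(pooled_scores, pooled_truth)
    return ClassificationReport(
        confusion=cm,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        roc_points=points,
        auc=auc,
        n_repeats=config.n_repeats,
    )


def feature_ttest(
    nt_values: Sequence[float], t_values: Sequence[float]
) -> tuple[float, float, bool]:
    """Welch two-sample t-test between the groups for one feature.

    Returns (t statistic, two-sided p value, significant at 0.05).  The
    unequal-variance form is used because group spreads of asymmetry features
    routinely differ by an order of magnitude.
    """
    nt_values = np.asarray(nt_values, dtype=float)
    t_values = np.asarray(t_values, dtype=float)
    if len(nt_values) < 2 or len(t_values) < 2:
        raise ProtocolError("t-test needs at least 2 values per group")
    if nt_values.std() == 0 and t_values.std() == 0:
        if nt_values.mean() == t_values.mean():
            raise ThermasymError("t statistic undefined: zero variance and equal means")
    res = stats.ttest_ind(t_values, nt_values, equal_var=False)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < 0.05)
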