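"""From-scratch k-nearest-neighbour classification of valence feature rows.

The protocol is a stratified 70/30 split (70% of each class drawn at random
into the training set), Euclidean distance in the raw 6-D feature space
(no scaling), and k = 2.  A 1-1 vote tie at k = 2 is resolved by the single
nearest neighbour, which makes k = 2 behave as a distance-weighted 1-NN;
equal distances are broken by the lower training-row index.

Because a single 30%-holdout contains only 18 rows in the full design,
:func:`evaluate_repeated` re-splits and re-classifies many times with
independent seeded splits and pools the test predictions, reporting the
confusion matrix as percent of true-class instances (each row sums to 100).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, ParameterError
from .evaluate import ConfusionMatrix, metrics_report
from .features import LabeledFeatureMatrix


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split parameters."""

    train_fraction: float = 0.7
    seed: int = 0
    n_repeats: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")


@dataclass(frozen=True)
class KnnSpec:
    """kNN parameters: neighbourhood size (Euclidean metric is fixed)."""

    k: int = 2

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")


def euclidean(x, y) -> float:
    """Euclidean distance between two equal-length feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def split(
    m: LabeledFeatureMatrix, spec: SplitSpec, rng: np.random.Generator | None = None
) -> tuple[LabeledFeatureMatrix, LabeledFeatureMatrix]:
    """Stratified split: round(train_fraction * n) rows of each class to train.

    Train and test are disjoint and exhaustive; both preserve the original
    row order.  Reproducible from ``spec.seed`` when ``rng`` is not given.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = np.asarray(m.labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(set(m.labels)):
        members = np.flatnonzero(labels == cls)
        if members.size < 2:
            raise DataError(f"class {cls!r} has fewer than 2 members")
        perm = rng.permutation(members)
        n_train = int(round(spec.train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return m.subset(sorted(train_idx)), m.subset(sorted(test_idx))


def knn_predict(train: LabeledFeatureMatrix, query, spec: KnnSpec) -> str:
    """Label of ``query`` by majority vote among its k nearest training rows.

    Vote ties are broken by the nearest neighbour's label; distance ties by
    the lower training-row index.
    """
    if train.n_rows == 0:
        raise DataError("empty training set")
    if spec.k > train.n_rows:
        raise ParameterError(f"k={spec.k} exceeds training size {train.n_rows}")
    q = np.asarray(query, dtype=float)
    if q.shape != (train.X.shape[1],):
        raise ParameterError("query dimension does not match the training matrix")
    dists = np.sqrt(np.sum((train.X - q) ** 2, axis=1))
    order = np.argsort(dists, kind="stable")  # stable: lower index wins ties
    top = order[: spec.k]
    votes = Counter(train.labels[i] for i in top)
    best = votes.most_common()
    if len(best) > 1 and best[0][1] == best[1][1]:
        return train.labels[top[0]]
    return best[0][0]


@dataclass
class EvaluationResult:
    """Pooled outcome of repeated split-and-classify runs."""

    counts: ConfusionMatrix
    percent: ConfusionMatrix
    metrics: dict
    n_repeats: int
    predictions_per_repeat: int
    per_repeat_accuracy: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion_counts": {
                "tp": self.counts.tp, "fp": self.counts.fp,
                "fn": self.counts.fn, "tn": self.counts.tn,
            },
            "confusion_percent": {
                "tp": self.percent.tp, "fp": self.percent.fp,
                "fn": self.percent.fn, "tn": self.percent.tn,
            },
            "positive_class": self.counts.positive_class,
            "n_repeats": self.n_repeats,
            "predictions_per_repeat": self.predictions_per_repeat,
            **self.metrics,
        }


def evaluate_repeated(
    m: LabeledFeatureMatrix,
    split_spec: SplitSpec,
    knn_spec: KnnSpec,
    positive_class: str = "positive",
) -> EvaluationResult:
    """Repeatedly split, classify the held-out rows, and pool the outcomes.

    Each repeat uses an independent child seed of ``split_spec.seed``.  The
    pooled counts are reported both raw and as percent of true-class
    instances, together with accuracy, sensitivity and both specificity
    variants computed from the pooled counts.
    """
    classes = sorted(set(m.labels))
    if len(classes) != 2:
        raise DataError(f"repeated evaluation needs exactly 2 classes, got {classes}")
    if positive_class not in classes:
        raise DataError(f"positive class {positive_class!r} not among {classes}")
    negative_class = next(c for c in classes if c != positive_class)

    children = np.random.SeedSequence(split_spec.seed).spawn(split_spec.n_repeats)
    tp = fp = fn = tn = 0
    per_repeat_accuracy = []
    n_test = None
    for child in children:
        rng = np.random.default_rng(child)
        train, test = split(m, split_spec, rng)
        n_test = test.n_rows
        correct = 0
        for row, true_label in zip(test.X, test.labels):
            pred = knn_predict(train, row, knn_spec)
            if true_label == positive_class:
                if pred == positive_class:
                    tp += 1
                else:
                    fp += 1
            else:
                if pred == positive_class:
                    fn += 1
                else:
                    tn += 1
            correct += pred == true_label
        per_repeat_accuracy.append(100.0 * correct / test.n_rows)

    counts = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, positive_class=positive_class)
    n_pos = tp + fp
    n_neg = fn + tn
    percent = ConfusionMatrix(
        tp=100.0 * tp / n_pos if n_pos else 0.0,
        fp=100.0 * fp / n_pos if n_pos else 0.0,
        fn=100.0 * fn / n_neg if n_neg else 0.0,
        tn=100.0 * tn / n_neg if n_neg else 0.0,
        positive_class=positive_class,
    )
    return EvaluationResult(
        counts=counts,
        percent=percent,
        metrics=metrics_report(counts),
        n_repeats=split_spec.n_repeats,
        predictions_per_repeat=n_test or 0,
        per_repeat_accuracy=per_repeat_accuracy,
    )
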