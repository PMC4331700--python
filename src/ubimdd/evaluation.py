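"""Negative sampling, cross-validation, and performance metrics.

The evaluation protocol: negatives are sampled per subgroup
at a fixed negative:positive ratio, models are assessed by stratified
five-fold cross-validation, and performance is reported as sensitivity,
specificity, accuracy, the Matthews correlation coefficient, and ROC
AUC.  Per-subgroup reports are combined by unweighted macro-averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .fragment_io import FragmentSet, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    """SEN/SPE/ACC as fractions in [0, 1], MCC in [-1, 1], optional AUC."""

    sen: float
    spe: float
    acc: float
    mcc: float
    auc: float | None = None

    def as_percent_row(self) -> str:
        auc = "" if self.auc is None else f"\t{100 * self.auc:.2f}"
        return (
            f"{100 * self.sen:.2f}\t{100 * self.spe:.2f}\t"
            f"{100 * self.acc:.2f}\t{self.mcc:.4f}" + auc
        )


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """SEN = TP/(TP+FN), SPE = TN/(TN+FP), ACC = (TP+TN)/total, and

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    with MCC defined as 0 when any denominator factor vanishes.
    """
    if counts.total == 0:
        raise ValidationError("cannot compute metrics from all-zero counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError(
            "sensitivity/specificity need at least one item of each class"
        )
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return MetricsReport(sen=sen, spe=spe, acc=acc, mcc=float(mcc), auc=auc)


def confusion_from_predictions(
    predictions: Sequence[bool], labels: Sequence[bool]
) -> ConfusionCounts:
    """Tally a confusion matrix from parallel prediction/label sequences."""
    if len(predictions) != len(labels):
        raise ValidationError("predictions and labels differ in length")
    preds = np.asarray(predictions, dtype=bool)
    labs = np.asarray(labels, dtype=bool)
    return ConfusionCounts(
        tp=int((preds & labs).sum()),
        fp=int((preds & ~labs).sum()),
        tn=int((~preds & ~labs).sum()),
        fn=int((~preds & labs).sum()),
    )


def sample_negatives(
    pool: FragmentSet, n_positives: int, ratio: float = 2.08, seed: int = 0
) -> FragmentSet:
    """Uniform sample of ``round(n_positives * ratio)`` negatives.

    Round-half-to-even; sampling is without replacement and reproducible
    from the seed.  Input order is preserved in the sample.
    """
    if ratio <= 0:
        raise ValidationError("ratio must be positive")
    size = round(n_positives * ratio)
    if size > len(pool):
        raise ValidationError(
            f"need {size} negatives but the pool holds only {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pool), size=size, replace=False))
    return pool.subset(idx.tolist())


def kfold_split(
    fragment_set: FragmentSet, k: int = 5, seed: int = 0
) -> list[FragmentSet]:
    """Label-stratified k-fold partition with seed-shuffled assignment.

    Within each label, fold sizes differ by at most one; folds are
    pairwise disjoint and their union is the input.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(fragment_set) < k:
        raise ValidationError(f"cannot split {len(fragment_set)} items into {k} folds")
    rng = np.random.default_rng(seed)
    fold_indices: list[list[int]] = [[] for _ in range(k)]
    for label_match in (True, False):
        indices = [
            i for i, f in enumerate(fragment_set) if f.is_positive == label_match
        ]
        if not indices:
            continue
        order = rng.permutation(len(indices))
        shuffled = [indices[i] for i in order]
        base, extra = divmod(len(shuffled), k)
        start = 0
        for fold in range(k):
            size = base + (1 if fold < extra else 0)
            fold_indices[fold].extend(shuffled[start: start + size])
            start += size
    return [fragment_set.subset(sorted(ix)) for ix in fold_indices]


def roc_auc(
    scores_pos: Sequence[float], scores_neg: Sequence[float]
) -> float:
    """Area under the ROC curve of the two score samples.

    Equals the probability that a random positive outscores a random
    negative, counting ties as one half.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("need non-empty positive and negative score lists")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(labels, np.concatenate([pos, neg])))


def macro_average(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Unweighted arithmetic mean of each metric across reports.

    AUC is averaged only when present in every report.
    """
    if not reports:
        raise ValidationError("cannot average an empty report list")
    aucs = [r.auc for r in reports]
    auc = float(np.mean(aucs)) if all(a is not None for a in aucs) else None
    return MetricsReport(
        sen=float(np.mean([r.sen for r in reports])),
        spe=float(np.mean([r.spe for r in reports])),
        acc=float(np.mean([r.acc for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        auc=auc,
    )


def cross_validate_model(
    positives: FragmentSet,
    negatives: FragmentSet,
    k: int = 5,
    seed: int = 0,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    objective: str = "accuracy",
) -> MetricsReport:
    """Stratified k-fold cross-validation of one profile HMM.

    Per fold: a model is trained on the training-fold positives, its
    threshold selected on the training fold, and the held-out fold
    scored.  Confusion counts are pooled across folds; AUC is computed
    from the pooled held-out scores.
    """
    from . import phmm  # local import; phmm depends on this module

    combined = FragmentSet(list(positives) + list(negatives))
    folds = kfold_split(combined, k=k, seed=seed)
    total = ConfusionCounts(tp=0, fp=0, tn=0, fn=0)
    held_pos: list[np.ndarray] = []
    held_neg: list[np.ndarray] = []
    for fold_idx, test in enumerate(folds):
        train = FragmentSet(
            f
            for other_idx, fold in enumerate(folds)
            if other_idx != fold_idx
            for f in fold
        )
        model = phmm.build_profile_hmm(
            train.positives(), pseudocount=pseudocount, background=background
        )
        thresholded = phmm.select_threshold(
            model, train.positives(), train.negatives(), objective=objective
        )
        scores = phmm.bit_scores(model, test)
        labels = np.array([f.is_positive for f in test])
        preds = scores > thresholded.threshold
        total = total + confusion_from_predictions(preds, labels)
        held_pos.append(scores[labels])
        held_neg.append(scores[~labels])
    auc = roc_auc(np.concatenate(held_pos), np.concatenate(held_neg))
    return compute_metrics(total, auc=auc)
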