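"""Performance metrics and the two resampling-aware evaluation protocols.

Seven metrics are reported throughout: recall, specificity, precision,
accuracy, Matthews correlation coefficient, F1 and ROC AUC.  The two
protocols are

* **repeated k-fold cross-validation** (default 10 folds x 3 repeats):
  folds are disjoint and near-equal; the k-1 training folds are randomly
  under-sampled to 1:1 before fitting while the held-out fold is *never*
  resampled; the mean over all k x repeats folds is the CV result.
* **repeated independent test** (default 5 repeats): per repeat the full
  training set is under-sampled under a derived seed, a model is fitted
  and scored on the untouched test set; the mean over repeats is the
  test result.

Per-repeat seeds derive as ``base_seed + repeat_index`` so the resampling
randomness the protocols average over is enumerable and reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from . import classify
from .encoders import EncoderSpec, encode_dataset, feature_matrix
from .imbalance import ResampleSpec, undersample_indices
from .peptide_io import Dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The seven performance metrics; AUC is None when undefined."""

    rec: float
    spe: float
    pre: float
    acc: float
    mcc: float
    f1: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(labels, predictions) -> ConfusionCounts:
    """Exact confusion-matrix counts from binary label/prediction vectors."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, what: str) -> float:
    """num/den with the 0/0 -> 0 convention (logged)."""
    if den == 0:
        logger.warning("%s is 0/0 on a degenerate confusion matrix; reporting 0", what)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricSet:
    """Threshold-based metrics from confusion counts (AUC left unset).

    Rec = TP/(TP+FN), Spe = TN/(TN+FP), Pre = TP/(TP+FP),
    Acc = (TP+TN)/total, F1 = 2*Rec*Pre/(Rec+Pre), and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    Any 0/0 — including the MCC denominator — returns 0 by convention.
    """
    rec = _ratio(c.tp, c.tp + c.fn, "recall")
    spe = _ratio(c.tn, c.tn + c.fp, "specificity")
    pre = _ratio(c.tp, c.tp + c.fp, "precision")
    acc = _ratio(c.tp + c.tn, c.total, "accuracy")
    f1 = _ratio(2 * rec * pre, rec + pre, "F1")
    mcc_den = np.sqrt(float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, mcc_den, "MCC")
    return MetricSet(rec=rec, spe=spe, pre=pre, acc=acc, mcc=mcc, f1=f1)


def auc(labels, scores) -> float:
    """ROC AUC via the rank (Mann-Whitney) statistic with half-credit ties.

    Equals P(score_pos > score_neg) + 0.5 * P(tie), which is exactly the
    trapezoidal area under the ROC curve swept over all thresholds.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties with half credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(labels, scores) -> np.ndarray:
    """(FPR, TPR) points of the empirical ROC curve, threshold-sorted."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((1 - y).sum()), 1)
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep only the last point of each tied-score run, plus the origin
    keep = np.r_[np.diff(s) != 0, True]
    pts = np.column_stack([fps[keep] / n_neg, tps[keep] / n_pos])
    return np.vstack([[0.0, 0.0], pts])


def evaluate_scores(labels, scores, threshold: float = 0.5) -> MetricSet:
    """Full metric set from labels and continuous scores."""
    m = metrics_from_counts(
        confusion_counts(labels, np.asarray(scores) >= threshold))
    try:
        a = auc(labels, scores)
    except ValueError:
        a = None
    return MetricSet(**{**m.as_dict(), "auc": a})


@dataclass
class FoldResult:
    repeat: int
    fold: int
    metrics: MetricSet
    n_test: int = 0
    n_pos_test: int = 0


@dataclass
class CVResult:
    """Per-fold metrics plus their arithmetic mean and a protocol echo."""

    folds: list[FoldResult]
    mean: MetricSet
    protocol: dict = field(default_factory=dict)


def _mean_metrics(metric_sets: Sequence[MetricSet]) -> MetricSet:
    vals = {}
    for name in ("rec", "spe", "pre", "acc", "mcc", "f1"):
        vals[name] = float(np.mean([getattr(m, name) for m in metric_sets]))
    aucs = [m.auc for m in metric_sets if m.auc is not None]
    if len(aucs) < len(metric_sets):
        warnings.warn("AUC missing on some folds (single-class hold-out); "
                      "mean AUC computed over the defined folds only")
    vals["auc"] = float(np.mean(aucs)) if aucs else None
    return MetricSet(**vals)


def _fit_and_score(X, y, train_idx, test_idx, model_spec, resample, seed):
    """One protocol step: optionally under-sample train, fit, score test."""
    if resample.strategy == "none":
        sel = train_idx
    else:
        sub = undersample_indices(y[train_idx], seed)
        sel = train_idx[sub]
    model = classify.train(X[sel], y[sel], model_spec)
    scores = classify.predict_scores(model, X[test_idx])
    return evaluate_scores(y[test_idx], scores)


def cross_validate(
    dataset: Dataset,
    encoder: EncoderSpec,
    model: classify.ModelSpec,
    resample: ResampleSpec | None = None,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
    stratified: bool = True,
    embed_fn=None,
) -> CVResult:
    """Repeated k-fold cross-validation with under-sampling inside the loop.

    Folds are reshuffled per repeat under ``seed + repeat``; resampling
    applies only to the combined k-1 training folds (seed
    ``seed + repeat * k + fold``), never to the held-out fold.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    y = np.asarray(dataset.labels(), dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes in the dataset")
    resample = resample or ResampleSpec()
    X, _names = feature_matrix(encode_dataset(dataset, encoder, embed_fn))

    folds: list[FoldResult] = []
    for rep in range(repeats):
        splitter_cls = StratifiedKFold if stratified else KFold
        splitter = splitter_cls(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold_i, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
            m = _fit_and_score(X, y, train_idx, test_idx, model, resample,
                               seed=seed + rep * k + fold_i)
            folds.append(FoldResult(rep, fold_i, m, n_test=len(test_idx),
                                    n_pos_test=int(y[test_idx].sum())))
    return CVResult(
        folds=folds,
        mean=_mean_metrics([f.metrics for f in folds]),
        protocol={"k": k, "repeats": repeats, "seed": seed,
                  "stratified": stratified, "resample": resample.strategy,
                  "model": model.algorithm, "n": len(dataset)},
    )


def independent_test(
    train_set: Dataset,
    test_set: Dataset,
    encoder: EncoderSpec,
    model: classify.ModelSpec,
    resample: ResampleSpec | None = None,
    repeats: int = 5,
    seed: int = 0,
    embed_fn=None,
) -> CVResult:
    """Repeated independent test: under-sample the full training set per
    repeat, fit, and score the unresampled test set; report the mean.

    Overlapping sequences between train and test are warned about (not
    an error) since identity leakage inflates every metric.
    """
    overlap = {p.sequence for p in train_set} & {p.sequence for p in test_set}
    if overlap:
        warnings.warn(f"{len(overlap)} sequences appear in both train and test sets")
    resample = resample or ResampleSpec()
    Xtr, _ = feature_matrix(encode_dataset(train_set, encoder, embed_fn))
    Xte, _ = feature_matrix(encode_dataset(test_set, encoder, embed_fn))
    ytr = np.asarray(train_set.labels(), dtype=int)
    yte = np.asarray(test_set.labels(), dtype=int)

    all_idx = np.arange(len(ytr))
    folds = []
    for rep in range(repeats):
        if resample.strategy == "none":
            sel = all_idx
        else:
            sel = all_idx[undersample_indices(ytr, seed + rep)]
        fitted = classify.train(Xtr[sel], ytr[sel], model)
        scores = classify.predict_scores(fitted, Xte)
        folds.append(FoldResult(rep, 0, evaluate_scores(yte, scores),
                                n_test=len(yte), n_pos_test=int(yte.sum())))
    return CVResult(
        folds=folds,
        mean=_mean_metrics([f.metrics for f in folds]),
        protocol={"repeats": repeats, "seed": seed, "resample": resample.strategy,
                  "model": model.algorithm,
                  "n_train": len(train_set), "n_test": len(test_set)},
    )
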