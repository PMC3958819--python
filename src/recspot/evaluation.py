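"""Prediction-quality metrics and cross-validation protocols.

Metrics over a 2x2 confusion table (hotspot = positive class):

    Sn  = TP / (TP + FN)                      sensitivity
    Sp  = TN / (TN + FP)                      specificity
    Acc = (TP + TN) / N                       accuracy
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Each of Sn/Sp/Acc is also expressible through the miss counts: with N+
total hotspots, N- total coldspots, N-+ hotspots called coldspot and N+-
coldspots called hotspot, Sn = 1 - N-+/N+ and Sp = 1 - N+-/N-.  Both
formulations are computed and cross-asserted.

The jackknife (leave-one-out) test trains on all samples but one and
predicts the held-out sample, for every sample, with hyperparameters held
fixed across folds; it yields a unique, seed-free outcome for a given
dataset.  Stratified K-fold is provided as the cheaper subsampling
alternative; with folds = n it degenerates to the jackknife exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from recspot import classifier
from recspot.classifier import COLDSPOT, DEFAULT_C, DEFAULT_GAMMA, HOTSPOT


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table; hotspot (+1) is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_pos(self) -> int:
        """Total hotspot samples (N+)."""
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        """Total coldspot samples (N-)."""
        return self.tn + self.fp

    @property
    def n_pos_as_neg(self) -> int:
        """Hotspots predicted coldspot (N-+); equals FN."""
        return self.fn

    @property
    def n_neg_as_pos(self) -> int:
        """Coldspots predicted hotspot (N+-); equals FP."""
        return self.fp

    @classmethod
    def from_labels(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "ConfusionCounts":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            tp=int(((yt == HOTSPOT) & (yp == HOTSPOT)).sum()),
            tn=int(((yt == COLDSPOT) & (yp == COLDSPOT)).sum()),
            fp=int(((yt == COLDSPOT) & (yp == HOTSPOT)).sum()),
            fn=int(((yt == HOTSPOT) & (yp == COLDSPOT)).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy and Matthews correlation."""

    sn: float
    sp: float
    acc: float
    mcc: float
    mcc_defined: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Compute Sn, Sp, Acc and MCC from a confusion table.

    Requires at least one sample in each class.  When any marginal of the
    MCC denominator is zero, MCC is undefined; it is reported as 0.0 with
    ``mcc_defined=False``.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    n_pos, n_neg = counts.n_pos, counts.n_neg
    if n_pos < 1 or n_neg < 1:
        raise ValueError("Sn/Sp require at least one sample of each class")
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    # Miss-count formulation must agree with the ratio formulation.
    assert math.isclose(sn, 1 - counts.n_pos_as_neg / n_pos, abs_tol=1e-12)
    assert math.isclose(sp, 1 - counts.n_neg_as_pos / n_neg, abs_tol=1e-12)
    assert math.isclose(
        acc, 1 - (counts.n_pos_as_neg + counts.n_neg_as_pos) / (n_pos + n_neg),
        abs_tol=1e-12,
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return MetricSet(sn=sn, sp=sp, acc=acc, mcc=0.0, mcc_defined=False)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


@dataclass
class EvaluationResult:
    """Aggregated cross-validation outcome with per-sample detail.

    ``metrics`` is None when every sample of one class failed its fold
    (degenerate datasets only); the per-sample ``error`` column says why.
    """

    counts: ConfusionCounts
    metrics: Optional[MetricSet]
    predictions: pd.DataFrame  # columns: id, true, predicted, score, error

    def to_json(self, sink: Union[str, Path]) -> None:
        payload = {
            "counts": asdict(self.counts),
            "metrics": self.metrics.as_dict() if self.metrics is not None else None,
            "n": int(len(self.predictions)),
        }
        Path(sink).write_text(json.dumps(payload, indent=2) + "\n")

    def predictions_to_tsv(self, sink: Union[str, Path]) -> None:
        self.predictions.to_csv(sink, sep="\t", index=False)


def _loo_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    ids: Sequence[str],
    C: float,
    gamma: float,
) -> EvaluationResult:
    rows = []
    y_true_ok, y_pred_ok = [], []
    n = len(y)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            model = classifier.train(X[mask], y[mask], C=C, gamma=gamma,
                                     lam=X.shape[1] - 64)
            label, score = classifier.predict(model, X[i : i + 1])[0]
            rows.append((ids[i], int(y[i]), label, score, ""))
            y_true_ok.append(int(y[i]))
            y_pred_ok.append(label)
        except ValueError as exc:
            # e.g. the training fold lost its only sample of one class
            rows.append((ids[i], int(y[i]), None, None, str(exc)))
        finally:
            mask[i] = True
    predictions = pd.DataFrame(
        rows, columns=["id", "true", "predicted", "score", "error"]
    )
    counts = ConfusionCounts.from_labels(y_true_ok, y_pred_ok)
    metric_set = (
        metrics(counts) if counts.n_pos >= 1 and counts.n_neg >= 1 else None
    )
    return EvaluationResult(counts=counts, metrics=metric_set, predictions=predictions)


def jackknife(
    X: np.ndarray,
    y: Sequence[int],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    ids: Optional[Sequence[str]] = None,
) -> EvaluationResult:
    """Leave-one-out evaluation with fixed hyperparameters.

    Every sample is predicted by a model trained on all the others.  The
    protocol involves no randomness, so the outcome is unique for a given
    dataset and (C, gamma).  A fold whose training split degenerates to a
    single class is surfaced per sample in the ``error`` column and
    excluded from the aggregated counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) < 3:
        raise ValueError("jackknife needs at least 3 samples")
    if ids is None:
        ids = [str(i) for i in range(len(y))]
    return _loo_evaluate(X, y, list(ids), C, gamma)


def kfold(
    X: np.ndarray,
    y: Sequence[int],
    folds: int,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    ids: Optional[Sequence[str]] = None,
) -> EvaluationResult:
    """Stratified K-fold evaluation with fixed hyperparameters.

    Fold assignment is stratified and derived from ``seed``.  With
    ``folds`` equal to the sample count the split degenerates to
    leave-one-out and the result equals :func:`jackknife` exactly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds ({folds}) cannot exceed sample count ({n})")
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    ids = list(ids)
    if folds == n:
        return _loo_evaluate(X, y, ids, C, gamma)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = [None] * n
    y_true_ok, y_pred_ok = [], []
    for train_idx, test_idx in skf.split(X, y):
        model = classifier.train(X[train_idx], y[train_idx], C=C, gamma=gamma,
                                 lam=X.shape[1] - 64)
        for i, (label, score) in zip(test_idx, classifier.predict(model, X[test_idx])):
            rows[i] = (ids[i], int(y[i]), label, score, "")
            y_true_ok.append(int(y[i]))
            y_pred_ok.append(label)
    predictions = pd.DataFrame(
        rows, columns=["id", "true", "predicted", "score", "error"]
    )
    counts = ConfusionCounts.from_labels(y_true_ok, y_pred_ok)
    return EvaluationResult(counts=counts, metrics=metrics(counts), predictions=predictions)
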