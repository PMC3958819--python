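"""RBF-kernel SVM over encoded feature vectors.

Labels are +1 for recombination hotspots and -1 for coldspots.  The SVM is
scikit-learn's ``SVC`` (the libsvm engine) with an RBF kernel; defaults
C=32, gamma=0.5.  Hyperparameters can be re-optimized on a conventional
log2 grid with K-fold cross-validation; ties are broken toward the
smallest C, then the smallest gamma, so the search is deterministic.

Before training, each feature is rescaled to [0, 1] by the min-max
transform fitted on the training set (the standard libsvm preprocessing
step).  This matters: the raw encoded components live on very different
scales (composition entries are O(1e-3..1e-2), correlation-tier entries
O(0.1)), and without rescaling all pairwise squared distances are ~1e-4,
at which point an RBF kernel with gamma of order 1 is numerically constant
and the SVM degenerates to (anti-)majority voting under leave-one-out.
The fitted offsets/spans are stored in the model and applied to queries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from recspot.features import DEFAULT_LAMBDA, DEFAULT_WEIGHT, kmer_order

HOTSPOT = 1
COLDSPOT = -1

DEFAULT_C = 32.0
DEFAULT_GAMMA = 0.5

#: Conventional libsvm-style log2 grids.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))

_FORMAT_VERSION = 1


def _validate_xy(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)} labels")
    if len(X) < 2:
        raise ValueError("need at least 2 training samples")
    labels = set(np.unique(y).tolist())
    if not labels <= {HOTSPOT, COLDSPOT}:
        raise ValueError(f"labels must be +1 (hotspot) / -1 (coldspot), got {labels}")
    if len(labels) < 2:
        raise ValueError("training data contains a single class")
    return X, y.astype(int)


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span = np.where(span == 0, 1.0, span)  # constant feature maps to 0
    return lo, span


@dataclass
class TrainedModel:
    """A fitted hotspot/coldspot SVM with its encoding parameters."""

    svc: SVC
    C: float
    gamma: float
    lam: int
    weight: float
    kmer_order: tuple[str, ...]
    fingerprint: str
    scale_offset: np.ndarray = None
    scale_span: np.ndarray = None
    format_version: int = _FORMAT_VERSION

    @property
    def n_features(self) -> int:
        return 64 + self.lam

    def predict(self, X: np.ndarray) -> list[tuple[int, float]]:
        return predict(self, X)

    def save(self, path: Union[str, Path]) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise ValueError(f"{path} does not contain a trained model")
        if model.format_version != _FORMAT_VERSION:
            raise ValueError(
                f"model format version {model.format_version} not supported"
            )
        return model


def train(
    X: np.ndarray,
    y: Sequence[int],
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    lam: int | None = None,
    weight: float = DEFAULT_WEIGHT,
) -> TrainedModel:
    """Fit an RBF-kernel SVM on encoded vectors.

    Deterministic for fixed inputs and hyperparameters (no random
    subsampling is involved in fitting).  ``lam`` and ``weight`` are the
    encoding parameters recorded for provenance; X must have 64+lam
    columns (``lam`` is inferred from the matrix when omitted).
    """
    X, y = _validate_xy(X, np.asarray(y))
    if lam is None:
        lam = X.shape[1] - 64
        if lam < 1:
            raise ValueError(
                f"cannot infer lambda from a {X.shape[1]}-column matrix; "
                "expected 64 + lambda columns"
            )
    elif X.shape[1] != 64 + lam:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match 64 + lambda ({64 + lam})"
        )
    offset, span = _fit_scaler(X)
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    svc.fit((X - offset) / span, y)
    return TrainedModel(
        svc=svc,
        C=C,
        gamma=gamma,
        lam=lam,
        weight=weight,
        kmer_order=kmer_order(3),
        fingerprint=_fingerprint(X, y),
        scale_offset=offset,
        scale_span=span,
    )


def predict(model: TrainedModel, X: np.ndarray) -> list[tuple[int, float]]:
    """Predict labels and decision scores for encoded vectors.

    A positive decision score means hotspot; a score of exactly 0 is
    resolved to coldspot (conservative, deterministic tie-break).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.n_features})"
        )
    scores = model.svc.decision_function((X - model.scale_offset) / model.scale_span)
    # decision_function is positive toward classes_[1]; orient toward +1.
    if model.svc.classes_[1] != HOTSPOT:
        scores = -scores
    labels = np.where(scores > 0, HOTSPOT, COLDSPOT)
    return [(int(l), float(s)) for l, s in zip(labels, scores)]


@dataclass
class GridSearchResult:
    """Outcome of an exhaustive (C, gamma) grid search."""

    best_C: float
    best_gamma: float
    best_accuracy: float
    table: pd.DataFrame = field(repr=False)  # columns: C, gamma, cv_accuracy

    def to_tsv(self, sink: Union[str, Path]) -> None:
        self.table.to_csv(sink, sep="\t", index=False)


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Exhaustive K-fold CV accuracy over a (C, gamma) grid.

    Fold assignment is stratified and fixed by ``seed`` so every grid point
    sees identical splits.  The maximizer is returned; ties break toward
    the smallest C, then the smallest gamma.
    """
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be nonempty")
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    X, y = _validate_xy(X, np.asarray(y))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    best = None  # (accuracy, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            correct = 0
            for train_idx, test_idx in splits:
                offset, span = _fit_scaler(X[train_idx])
                svc = SVC(kernel="rbf", C=C, gamma=gamma)
                svc.fit((X[train_idx] - offset) / span, y[train_idx])
                pred = svc.predict((X[test_idx] - offset) / span)
                correct += int((pred == y[test_idx]).sum())
            acc = correct / len(y)
            rows.append((C, gamma, acc))
            if best is None or acc > best[0]:
                best = (acc, C, gamma)
    table = pd.DataFrame(rows, columns=["C", "gamma", "cv_accuracy"])
    return GridSearchResult(
        best_C=best[1], best_gamma=best[2], best_accuracy=best[0], table=table
    )
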