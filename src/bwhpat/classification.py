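"""Channel-wise kNN classification with stratified 10-fold and LOSO CV.

The study protocol is a 1-nearest-neighbor classifier with city-block (L1)
distance on z-scored features, evaluated by stratified tenfold
cross-validation; features are standardized inside each fold using training
statistics only.  Leave-one-subject-out (LOSO) CV uses one fold per subject.

Accuracy is the fraction of correct held-out predictions; F1 is the one-vs-
rest harmonic mean of precision and recall, macro-averaged over the classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

__all__ = ["KnnConfig", "ChannelOutcome", "knn_cv", "loso_cv", "compute_metrics"]


@dataclass(frozen=True)
class KnnConfig:
    """kNN protocol: k=1, L1 distance, no weighting, standardized features."""

    k: int = 1
    distance: str = "cityblock"
    standardize: bool = True
    folds: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")


@dataclass
class ChannelOutcome:
    """Held-out predictions and summary metrics for one (channel, case) run."""

    predictions: np.ndarray
    y: np.ndarray
    accuracy: float
    f1: float
    confusion: np.ndarray
    classes: np.ndarray
    channel: int | None = None
    case: int | None = None


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)   # constant features contribute no distance
    return (train - mu) / sd, (test - mu) / sd


def _knn_predict(train_X: np.ndarray, train_y: np.ndarray,
                 test_X: np.ndarray, cfg: KnnConfig) -> np.ndarray:
    d = cdist(test_X, train_X, metric=cfg.distance)
    if cfg.k == 1:
        return train_y[np.argmin(d, axis=1)]
    nn = np.argpartition(d, cfg.k - 1, axis=1)[:, : cfg.k]
    out = np.empty(test_X.shape[0], dtype=train_y.dtype)
    for i, row in enumerate(nn):
        labels, counts = np.unique(train_y[row], return_counts=True)
        out[i] = labels[np.argmax(counts)]   # vote ties -> smallest label
    return out


def _cv_outcome(X: np.ndarray, y: np.ndarray, folds: list[tuple[np.ndarray, np.ndarray]],
                cfg: KnnConfig, channel: int | None, case: int | None) -> ChannelOutcome:
    pred = np.empty_like(y)
    for tr, te in folds:
        tr_X, te_X = X[tr], X[te]
        if cfg.standardize:
            tr_X, te_X = _standardize(tr_X, te_X)
        pred[te] = _knn_predict(tr_X, y[tr], te_X, cfg)
    acc, f1, conf, classes = compute_metrics(pred, y)
    return ChannelOutcome(predictions=pred, y=y, accuracy=acc, f1=f1,
                          confusion=conf, classes=classes,
                          channel=channel, case=case)


def knn_cv(X: np.ndarray, y: np.ndarray, cfg: KnnConfig | None = None,
           channel: int | None = None, case: int | None = None) -> ChannelOutcome:
    """Stratified k-fold CV; every sample is predicted exactly once."""
    cfg = cfg or KnnConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < cfg.folds:
        lacking = classes[counts < cfg.folds]
        raise ValueError(
            f"class(es) {lacking.tolist()} have fewer than {cfg.folds} samples; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.rng_seed)
    folds = [(tr, te) for tr, te in skf.split(X, y)]
    return _cv_outcome(X, y, folds, cfg, channel, case)


def loso_cv(X: np.ndarray, y: np.ndarray, subject_ids: np.ndarray,
            cfg: KnnConfig | None = None,
            channel: int | None = None, case: int | None = None) -> ChannelOutcome:
    """Leave-one-subject-out CV: one fold per subject."""
    cfg = cfg or KnnConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subject_ids = np.asarray(subject_ids)
    if subject_ids.size != y.size:
        raise ValueError("subject_ids must align with labels")
    subjects = np.unique(subject_ids)
    if subjects.size < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    idx = np.arange(y.size)
    folds = [(idx[subject_ids != s], idx[subject_ids == s]) for s in subjects]
    return _cv_outcome(X, y, folds, cfg, channel, case)


def compute_metrics(pred: np.ndarray, y: np.ndarray
                    ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(accuracy, macro F1, confusion matrix, class labels).

    The confusion matrix is indexed [true, predicted] over the sorted union
    of labels; accuracy equals its trace over its total.
    """
    pred = np.asarray(pred)
    y = np.asarray(y)
    if pred.size != y.size:
        raise ValueError(f"{pred.size} predictions but {y.size} labels")
    if y.size == 0:
        raise ValueError("empty inputs")
    classes = np.unique(np.concatenate([y, pred]))
    k = classes.size
    lut = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y, pred):
        conf[lut[t], lut[p]] += 1
    accuracy = float(np.trace(conf) / conf.sum())
    f1s = []
    for i, c in enumerate(classes):
        if not np.any(y == c):
            continue                      # no support: class not in truth
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return accuracy, float(np.mean(f1s)), conf, classes
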