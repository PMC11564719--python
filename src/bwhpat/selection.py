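"""Iterative neighborhood component analysis (INCA) feature selection.

NCA learns one nonnegative relevance weight per feature by maximizing the
expected leave-one-out accuracy of a soft nearest-neighbor rule under a
weighted city-block metric d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|, with an
L2 penalty on the weights.  Features are ranked by descending learned w_r^2.

INCA then evaluates the nested candidate subsets made of the top-x ranked
features for x = stv..fnv (defaults 50..500, i.e. a 451-point loss curve),
scoring each by the stratified 10-fold CV misclassification rate of the
1-NN/L1 classifier, and keeps the subset with minimum loss (ties toward
fewer features).  The same fold assignment is reused for every candidate
size so the loss curve is comparable point to point.

Numerical notes: features are z-scored before NCA; soft-neighbor
probabilities use a stable softmax and distances are divided by their mean
at initialization (a fixed length scale), keeping the exponentials in a
responsive regime at any dimensionality.  The weight optimization is a
deterministic full-batch gradient ascent run for ``nca_iterations`` steps
(default: half the number of segments, rounded up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classification import KnnConfig, knn_cv

__all__ = ["IncaConfig", "IncaResult", "nca_rank", "inca_select"]


@dataclass(frozen=True)
class IncaConfig:
    """INCA protocol parameters."""

    stv: int = 50                  # smallest candidate subset size
    fnv: int = 500                 # largest candidate subset size
    nca_iterations: int | None = None   # None -> ceil(n_samples / 2)
    cv_folds: int = 10
    rng_seed: int = 0
    learning_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.stv <= self.fnv:
            raise ValueError(f"need 1 <= stv <= fnv, got stv={self.stv}, fnv={self.fnv}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")


@dataclass
class IncaResult:
    """Ranking, loss curve over candidate sizes and the chosen subset."""

    index: np.ndarray          # full ranking permutation (0-based column ids)
    loss: np.ndarray           # misclassification rate per size stv..fnv
    idx: int                   # 0-based argmin position in the loss curve
    sfeat_indices: np.ndarray  # selected column ids (size idx + stv)
    weights: np.ndarray        # final NCA feature weights


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def nca_rank(X: np.ndarray, y: np.ndarray, cfg: IncaConfig | None = None,
             return_weights: bool = False):
    """Rank features by descending NCA weight; deterministic.

    Returns the ranking permutation (0-based feature indices, best first),
    or ``(ranking, weights)`` when ``return_weights`` is set.
    """
    cfg = cfg or IncaConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("NCA needs at least 2 classes")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features are constant")

    Z = _zscore(X).astype(np.float32)
    # pairwise per-feature absolute differences, condensed over i<j
    iu, ju = np.triu_indices(n, k=1)
    A = np.abs(Z[iu] - Z[ju])                      # (n_pairs, p) float32
    same = (y[iu] == y[ju])

    w = np.ones(p, dtype=np.float64)
    lam = 1.0 / n
    d0 = A @ (w**2).astype(np.float32)
    scale = float(d0.mean()) or 1.0

    n_iter = cfg.nca_iterations or int(np.ceil(n / 2))
    eye = np.eye(n, dtype=bool)
    same_sq = np.zeros((n, n), dtype=bool)
    same_sq[iu, ju] = same
    same_sq |= same_sq.T

    for _ in range(n_iter):
        d = (A @ (w**2).astype(np.float32)).astype(np.float64) / scale
        D = np.zeros((n, n))
        D[iu, ju] = d
        D += D.T
        # stable softmax of -D over j != i
        D[eye] = np.inf
        M = -D + D.min(axis=1, keepdims=True)
        K = np.exp(M)
        P = K / K.sum(axis=1, keepdims=True)       # p_ij
        p_i = (P * same_sq).sum(axis=1)
        # coefficient of a_ijr in dF/d(w_r^2): p_i * p_ij - [same] * p_ij
        Cm = P * p_i[:, None] - P * same_sq
        c_cond = (Cm[iu, ju] + Cm[ju, iu]).astype(np.float32)
        grad = (2.0 * w / scale) * (A.T @ c_cond).astype(np.float64) / n
        grad -= 2.0 * lam * w
        w += cfg.learning_rate * grad
    ranking = np.argsort(-(w**2), kind="stable")
    if return_weights:
        return ranking, w
    return ranking


def inca_select(X: np.ndarray, y: np.ndarray,
                cfg: IncaConfig | None = None) -> IncaResult:
    """NCA ranking plus minimum-CV-loss choice among nested top-x subsets."""
    cfg = cfg or IncaConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if cfg.fnv > p:
        raise ValueError(
            f"fnv={cfg.fnv} exceeds the {p} available features; lower fnv"
        )
    ranking, w = nca_rank(X, y, cfg, return_weights=True)
    top = ranking[: cfg.fnv]
    Xr = X[:, top]                       # columns in rank order

    sizes = np.arange(cfg.stv, cfg.fnv + 1)
    errors = np.zeros(sizes.size, dtype=np.int64)
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                          random_state=cfg.rng_seed)
    for tr, te in skf.split(Xr, y):
        tr_X, te_X = Xr[tr], Xr[te]
        mu = tr_X.mean(axis=0)
        sd = tr_X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        tr_X = (tr_X - mu) / sd
        te_X = (te_X - mu) / sd
        # per-feature L1 contributions, cumulative over the ranked columns:
        # contrib[:, :, x-1].  A prefix sum turns every nested subset's
        # distance matrix into one slice.
        contrib = np.abs(te_X[:, None, :] - tr_X[None, :, :])
        cum = np.cumsum(contrib, axis=2)
        dist = cum[:, :, sizes - 1]                 # (n_te, n_tr, n_sizes)
        nn = np.argmin(dist, axis=1)                # ties -> lowest train index
        pred = y[tr][nn]                            # (n_te, n_sizes)
        errors += (pred != y[te][:, None]).sum(axis=0)
    loss = errors / n
    idx = int(np.argmin(loss))            # ties -> smaller subset
    return IncaResult(index=ranking, loss=loss, idx=idx,
                      sfeat_indices=top[: idx + cfg.stv].copy(), weights=w)


def selected_cv_outcome(X: np.ndarray, y: np.ndarray, result: IncaResult,
                        cfg: IncaConfig | None = None,
                        channel: int | None = None, case: int | None = None):
    """Re-evaluate the winning subset with the classification-module kNN.

    Uses the same fold seed as the selection loop, so the outcome's error
    rate reproduces the stored minimum loss.
    """
    cfg = cfg or IncaConfig()
    knn_cfg = KnnConfig(folds=cfg.cv_folds, rng_seed=cfg.rng_seed)
    return knn_cv(np.asarray(X, dtype=float)[:, result.sfeat_indices], y,
                  knn_cfg, channel=channel, case=case)
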