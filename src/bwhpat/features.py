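"""Multilevel feature extraction.

Every input series (the raw EEG segment and its 10 TQWT subbands) yields a
270-vector: 256 BWHPat histogram bins followed by 14 statistical moments.
The 11 per-input vectors are concatenated into a 2970-feature row; rows over
all segments of one channel form the feature matrix handed to selection.

The 14 moments, in order: Tsallis entropy, Shannon entropy, Renyi entropy,
Sure entropy, log-energy entropy, energy, Higuchi fractal dimension,
standard deviation, variance, range, mean, median, minimum, maximum.

Entropy conventions (the upstream extractor leaves them open, so they are
fixed here and collected in :class:`MomentConfig`): probabilities are the
energy-normalized p_i = x_i^2 / sum(x^2) with 0*log(0) := 0; Renyi order 2;
Tsallis order 2; Sure threshold tau = 2; log-energy entropy uses an epsilon
guard for log(0).  Higuchi uses k_max = 10 with a least-squares slope of
log(curve length) against log(1/k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .pattern import N_BINS, bwhpat_features
from .tqwt import TqwtParams, tqwt_decompose

__all__ = [
    "MomentConfig",
    "FeatureVector",
    "FeatureMatrix",
    "N_STAT_FEATURES",
    "N_INPUT_FEATURES",
    "N_INPUTS",
    "N_TOTAL_FEATURES",
    "STAT_FEATURE_NAMES",
    "statistical_features",
    "lbp_features",
    "extract_input_features",
    "extract_segment_features",
    "build_feature_matrix",
    "feature_names",
]

N_STAT_FEATURES = 14
N_INPUT_FEATURES = N_BINS + N_STAT_FEATURES   # 270
N_INPUTS = 11                                 # raw + 10 subbands
N_TOTAL_FEATURES = N_INPUT_FEATURES * N_INPUTS  # 2970

STAT_FEATURE_NAMES = (
    "tsallis", "shannon", "renyi", "sure", "log_energy", "energy", "higuchi",
    "std", "var", "range", "mean", "median", "min", "max",
)


@dataclass(frozen=True)
class MomentConfig:
    """Tunables of the statistical moment block."""

    renyi_order: float = 2.0
    tsallis_order: float = 2.0
    sure_threshold: float = 2.0
    log_eps: float = 1e-12
    higuchi_kmax: int = 10


_DEFAULT_MOMENTS = MomentConfig()


def _higuchi_fd(x: np.ndarray, kmax: int) -> float:
    """Higuchi fractal dimension: slope of log L(k) vs log(1/k)."""
    n = x.size
    kmax = max(2, min(kmax, n // 2))
    ks = np.arange(1, kmax + 1)
    if _fast.HAVE_NUMBA:
        lengths = _fast._higuchi_lengths(x, kmax)
    else:
        lengths = np.empty(ks.size)
        offsets = np.arange(n)
        for i, k in enumerate(ks):
            # lag-k abs differences, accumulated per curve offset m = idx mod k
            d = np.abs(x[k:] - x[:-k])
            m = offsets[: n - k] % k
            sums = np.bincount(m, weights=d, minlength=k)
            n_diffs = np.bincount(m, minlength=k)
            valid = n_diffs > 0
            lm = sums[valid] * (n - 1) / (n_diffs[valid] * k) / k
            lengths[i] = lm.sum() / k
    pos = lengths > 0
    if pos.sum() < 2:
        return 0.0
    slope = np.polyfit(np.log(1.0 / ks[pos]), np.log(lengths[pos]), 1)[0]
    return float(slope)


def statistical_features(signal: np.ndarray,
                         cfg: MomentConfig = _DEFAULT_MOMENTS) -> np.ndarray:
    """The 14 statistical moments of a series, in the documented order."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("statistical features need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    x2 = x * x
    energy = float(x2.sum())
    if energy > 0:
        p = x2 / energy
        p_nz = p[p > 0]
        shannon = float(-np.sum(p_nz * np.log(p_nz)))
        sum_p_alpha = float(np.sum(p_nz**cfg.renyi_order))
        renyi = float(np.log(sum_p_alpha) / (1.0 - cfg.renyi_order))
        sum_p_q = float(np.sum(p_nz**cfg.tsallis_order))
        tsallis = float((1.0 - sum_p_q) / (cfg.tsallis_order - 1.0))
    else:
        shannon = renyi = tsallis = 0.0
    sure = float(np.sum(np.minimum(x2, cfg.sure_threshold**2)))
    log_energy = float(np.sum(np.log(x2 + cfg.log_eps)))
    higuchi = _higuchi_fd(x, cfg.higuchi_kmax)

    return np.array([
        tsallis, shannon, renyi, sure, log_energy, energy, higuchi,
        float(x.std(ddof=1)), float(x.var(ddof=1)), float(np.ptp(x)),
        float(x.mean()), float(np.median(x)), float(x.min()), float(x.max()),
    ])


def lbp_features(signal: np.ndarray) -> np.ndarray:
    """Classic 1-D local binary pattern histogram (ablation baseline).

    Nine-sample sliding windows; the eight neighbors of the center sample are
    signum-compared against it (>= maps to 1) and packed MSB-first, giving a
    256-bin count histogram over the lng-8 windows.
    """
    import warnings

    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 9:
        warnings.warn(
            "signal shorter than one 9-sample LBP window; returning an "
            "all-zero histogram",
            stacklevel=2,
        )
        return np.zeros(N_BINS)
    win = np.lib.stride_tricks.sliding_window_view(x, 9)
    center = win[:, 4]
    neighbors = win[:, [0, 1, 2, 3, 5, 6, 7, 8]]
    bits = neighbors >= center[:, None]
    codes = bits @ (2 ** np.arange(7, -1, -1))
    return np.bincount(codes, minlength=N_BINS).astype(float)


@dataclass
class FeatureVector:
    """The 11 per-input 270-vectors and their 2970-long concatenation."""

    f: list[np.ndarray]
    provenance: list[str] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return np.concatenate(self.f)


def extract_input_features(series: np.ndarray,
                           moments: MomentConfig = _DEFAULT_MOMENTS) -> np.ndarray:
    """[BWHPat 256 | statistical 14] for one input series."""
    return np.concatenate([bwhpat_features(series),
                           statistical_features(series, moments)])


def extract_segment_features(signal: np.ndarray,
                             params: TqwtParams | None = None,
                             moments: MomentConfig = _DEFAULT_MOMENTS) -> FeatureVector:
    """Features of the raw segment and its J+1 wavelet subbands, in order."""
    params = params or TqwtParams()
    bands = tqwt_decompose(signal, params)
    inputs = [np.asarray(signal, dtype=float).ravel()] + list(bands.bands)
    names = ["raw"] + [f"band{s:02d}" for s in range(1, len(bands.bands) + 1)]
    vecs = [extract_input_features(s, moments) for s in inputs]
    return FeatureVector(f=vecs, provenance=names)


@dataclass
class FeatureMatrix:
    """Per-segment feature rows with aligned labels."""

    X: np.ndarray                 # (n_segments, 2970)
    y: np.ndarray                 # labels in {1, 2, 3}
    subject_ids: np.ndarray | None = None
    channel: int | None = None    # 1-based channel index
    case: int | None = None
    columns: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[0] != self.y.size:
            raise ValueError(
                f"{self.X.shape[0]} feature rows but {self.y.size} labels"
            )
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")


def feature_names(n_bands: int = 10) -> list[str]:
    """Provenance-encoding column names (raw first, then bands 1..n)."""
    names = []
    for inp in ["raw"] + [f"band{s:02d}" for s in range(1, n_bands + 1)]:
        names += [f"{inp}_bwh_bin{i:03d}" for i in range(N_BINS)]
        names += [f"{inp}_stat_{m}" for m in STAT_FEATURE_NAMES]
    return names


def build_feature_matrix(segments: list[np.ndarray],
                         labels: np.ndarray,
                         params: TqwtParams | None = None,
                         subject_ids: np.ndarray | None = None,
                         channel: int | None = None,
                         case: int | None = None) -> FeatureMatrix:
    """One 2970-feature row per segment, rows in input order."""
    labels = np.asarray(labels)
    if len(segments) == 0:
        raise ValueError("no segments given")
    if len(segments) != labels.size:
        raise ValueError(
            f"{len(segments)} segments but {labels.size} labels"
        )
    params = params or TqwtParams()
    rows = [extract_segment_features(s, params).X for s in segments]
    X = np.vstack(rows)
    return FeatureMatrix(X=X, y=labels,
                         subject_ids=None if subject_ids is None else np.asarray(subject_ids),
                         channel=channel, case=case,
                         columns=feature_names(params.J + 1))
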