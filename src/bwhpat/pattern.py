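"""Black-white hole pattern (BWHPat): a self-organizing 1-D textural descriptor.

Each overlapping 69-sample window of a signal is laid out as five regions
mimicking a black-hole/white-hole sketch: a 5x5 "black hole" matrix ``b``, a
3x3 "event horizon" ``eb``, a single central "singularity" value ``C``, a
second 3x3 event horizon ``ew`` and a 5x5 "white hole" matrix ``w``.  Fourteen
candidate binary comparison patterns are defined over these regions; for each
window the pattern whose group (mean, std) lies closest (Euclidean distance)
to the whole-signal (mean, std) is selected, its eight signum comparisons are
packed MSB-first into a byte, and the byte stream is histogrammed into a
256-bin feature vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _fast

__all__ = [
    "BLOCK_LEN",
    "N_PATTERNS",
    "BwhBlock",
    "GlobalStats",
    "PatternSelection",
    "MapSignal",
    "extract_blocks",
    "split_block",
    "signum_compare",
    "binary_pattern",
    "group_stats",
    "global_stats",
    "select_pattern",
    "map_value",
    "bwhpat_transform",
    "bwhpat_features",
]

BLOCK_LEN = 69          # 25 + 9 + 1 + 9 + 25
N_PATTERNS = 14
N_BINS = 256

# --- window layout (0-based offsets into the 69-sample block) -----------------
_VB = slice(0, 25)      # black-hole vector
_VEB = slice(25, 34)    # event horizon of the black hole
_C_IDX = 34             # singularity
_VEW = slice(35, 44)    # event horizon of the white hole
_VW = slice(44, 69)     # white-hole vector

# centers after row-major 5x5 / 3x3 fill
_CB_IDX = 12            # b(3,3)
_CW_IDX = 56            # w(3,3)
_cb_IDX = 29            # eb(2,2)
_cw_IDX = 39            # ew(2,2)

# The eight compared cells of a 5x5 matrix: outer-ring corners and edge
# midpoints in row-major order -- (1,1),(1,3),(1,5),(3,1),(3,5),(5,1),(5,3),(5,5).
_RING5 = np.array([0, 2, 4, 10, 14, 20, 22, 24])
# The eight non-center cells of a 3x3 matrix, row-major.
_RING3 = np.array([0, 1, 2, 3, 5, 6, 7, 8])

_B8 = _RING5
_W8 = 44 + _RING5
_EB8 = 25 + _RING3
_EW8 = 35 + _RING3


def _rep(i: int) -> np.ndarray:
    return np.full(8, i)


# operand index pairs (left, right) for the 14 patterns; bit r is left>=right
_PATTERN_OPERANDS: list[tuple[np.ndarray, np.ndarray]] = [
    (_B8, _rep(_CB_IDX)),    # 1: b vs its center
    (_W8, _rep(_CW_IDX)),    # 2: w vs its center
    (_EB8, _rep(_cb_IDX)),   # 3: eb vs its center
    (_EW8, _rep(_cw_IDX)),   # 4: ew vs its center
    (_B8, _rep(_C_IDX)),     # 5-8: regions vs singularity
    (_W8, _rep(_C_IDX)),
    (_EB8, _rep(_C_IDX)),
    (_EW8, _rep(_C_IDX)),
    (_B8, _W8),              # 9: hole vs hole
    (_EB8, _EW8),            # 10: horizon vs horizon
    (_B8, _EB8),             # 11-14: hole vs event horizon pairings
    (_W8, _EW8),
    (_B8, _EW8),
    (_W8, _EB8),
]

# Statistic groups: unions of contiguous block ranges [lo, hi).  Groups 1-4 are
# the bare matrices, 5-8 append the singularity, 9-14 concatenate two regions.
_GROUP_RANGES: list[list[tuple[int, int]]] = [
    [(0, 25)],                # b
    [(44, 69)],               # w
    [(25, 34)],               # eb
    [(35, 44)],               # ew
    [(0, 25), (34, 35)],      # (b, C)
    [(44, 69), (34, 35)],     # (w, C)
    [(25, 35)],               # (eb, C) -- contiguous
    [(34, 44)],               # (ew, C) -- contiguous
    [(0, 25), (44, 69)],      # (b, w)
    [(25, 34), (35, 44)],     # (eb, ew)
    [(0, 34)],                # (b, eb) -- contiguous
    [(35, 69)],               # (w, ew) -- contiguous
    [(0, 25), (35, 44)],      # (b, ew)
    [(25, 34), (44, 69)],     # (w, eb)
]

_BIT_WEIGHTS = 2 ** np.arange(7, -1, -1)  # MSB first: 128, 64, ..., 1


@dataclass
class BwhBlock:
    """One 69-sample window split into the five hole/horizon regions."""

    bl: np.ndarray
    vb: np.ndarray = field(init=False)
    veb: np.ndarray = field(init=False)
    C: float = field(init=False)
    vew: np.ndarray = field(init=False)
    vw: np.ndarray = field(init=False)
    b: np.ndarray = field(init=False)
    w: np.ndarray = field(init=False)
    eb: np.ndarray = field(init=False)
    ew: np.ndarray = field(init=False)
    Cb: float = field(init=False)
    Cw: float = field(init=False)
    cb: float = field(init=False)
    cw: float = field(init=False)

    def __post_init__(self) -> None:
        bl = np.asarray(self.bl, dtype=float).ravel()
        if bl.size != BLOCK_LEN:
            raise ValueError(f"block must hold exactly {BLOCK_LEN} values, got {bl.size}")
        if not np.all(np.isfinite(bl)):
            raise ValueError("block contains non-finite values")
        self.bl = bl
        self.vb = bl[_VB]
        self.veb = bl[_VEB]
        self.C = float(bl[_C_IDX])
        self.vew = bl[_VEW]
        self.vw = bl[_VW]
        self.b = self.vb.reshape(5, 5)           # row-major fill
        self.w = self.vw.reshape(5, 5)
        self.eb = self.veb.reshape(3, 3)
        self.ew = self.vew.reshape(3, 3)
        self.Cb = float(self.b[2, 2])
        self.Cw = float(self.w[2, 2])
        self.cb = float(self.eb[1, 1])
        self.cw = float(self.ew[1, 1])


@dataclass(frozen=True)
class GlobalStats:
    """Whole-signal mean and sample standard deviation (n-1 denominator)."""

    mean: float
    std: float
    lng: int


@dataclass(frozen=True)
class PatternSelection:
    """Outcome of the distance-based pattern choice for one block."""

    distances: np.ndarray      # 14 Euclidean distances in (mean, std) space
    idt: int                   # chosen pattern index, 1-based
    bf: np.ndarray             # the 8 selected bits
    group_means: np.ndarray
    group_stds: np.ndarray


@dataclass(frozen=True)
class MapSignal:
    """Coded map signal and per-pattern usage diagnostics."""

    map: np.ndarray            # length lng-68, values in [0, 255]
    pattern_usage: np.ndarray  # 14 counts, sums to len(map)


def extract_blocks(signal: np.ndarray) -> list[BwhBlock]:
    """Stride-1 overlapping 69-sample blocks; block g holds signal[g:g+69]."""
    x = _as_signal(signal)
    if x.size < BLOCK_LEN:
        raise ValueError(
            f"signal of length {x.size} is shorter than one {BLOCK_LEN}-sample block"
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, BLOCK_LEN)
    return [BwhBlock(wd.copy()) for wd in windows]


def split_block(bl: np.ndarray) -> BwhBlock:
    return BwhBlock(np.asarray(bl))


def signum_compare(x: float, c: float) -> int:
    """1 if x >= c else 0 (equality maps to 1)."""
    if not (np.isfinite(x) and np.isfinite(c)):
        raise ValueError("signum_compare requires finite inputs")
    return int(x >= c)


def binary_pattern(block: BwhBlock, e: int) -> np.ndarray:
    """Eight signum bits of the e-th candidate pattern (e in 1..14)."""
    if not 1 <= e <= N_PATTERNS:
        raise ValueError(f"pattern index must be in 1..{N_PATTERNS}, got {e}")
    left, right = _PATTERN_OPERANDS[e - 1]
    return (block.bl[left] >= block.bl[right]).astype(np.uint8)


def group_stats(block: BwhBlock, e: int) -> tuple[float, float]:
    """(mean, sample std) over all elements of statistic group e (1..14)."""
    if not 1 <= e <= N_PATTERNS:
        raise ValueError(f"group index must be in 1..{N_PATTERNS}, got {e}")
    vals = np.concatenate([block.bl[lo:hi] for lo, hi in _GROUP_RANGES[e - 1]])
    return float(vals.mean()), float(vals.std(ddof=1))


def global_stats(signal: np.ndarray) -> GlobalStats:
    x = _as_signal(signal)
    if x.size < 1:
        raise ValueError("empty signal")
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return GlobalStats(mean=float(x.mean()), std=sd, lng=int(x.size))


def select_pattern(block: BwhBlock, gs: GlobalStats) -> PatternSelection:
    """Pick the pattern whose group (mean, std) is nearest the signal's.

    Ties resolve to the lowest pattern index.
    """
    means = np.empty(N_PATTERNS)
    stds = np.empty(N_PATTERNS)
    for e in range(1, N_PATTERNS + 1):
        means[e - 1], stds[e - 1] = group_stats(block, e)
    dist = np.sqrt((gs.mean - means) ** 2 + (gs.std - stds) ** 2)
    idt = int(np.argmin(dist)) + 1
    return PatternSelection(
        distances=dist,
        idt=idt,
        bf=binary_pattern(block, idt),
        group_means=means,
        group_stds=stds,
    )


def map_value(bf: np.ndarray) -> int:
    """MSB-first byte value of the eight bits: sum bf[z] * 2^(8-z)."""
    bits = np.asarray(bf)
    if bits.shape != (8,) or not np.isin(bits, (0, 1)).all():
        raise ValueError("bf must be 8 binary entries")
    return int(bits @ _BIT_WEIGHTS)


def _as_signal(signal: np.ndarray) -> np.ndarray:
    x = np.asarray(signal, dtype=float).ravel()
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return x


# the five base regions of the window, [lo, hi)
_BASE_RANGES = ((0, 25), (25, 34), (34, 35), (35, 44), (44, 69))
# each statistic group as a combination of base regions (b, eb, C, ew, w)
_GROUP_BASES = (
    (0,), (4,), (1,), (3,),
    (0, 2), (4, 2), (1, 2), (3, 2),
    (0, 4), (1, 3), (0, 1), (4, 3), (0, 3), (4, 1),
)
_GROUP_COUNTS = np.array(
    [sum(_BASE_RANGES[b][1] - _BASE_RANGES[b][0] for b in bases)
     for bases in _GROUP_BASES], dtype=float)

# flat argument arrays for the fused kernel
_BASE_LO = np.array([lo for lo, _ in _BASE_RANGES], dtype=np.int64)
_BASE_HI = np.array([hi for _, hi in _BASE_RANGES], dtype=np.int64)
_GROUP_B0 = np.array([b[0] for b in _GROUP_BASES], dtype=np.int64)
_GROUP_B1 = np.array([b[1] if len(b) > 1 else -1 for b in _GROUP_BASES],
                     dtype=np.int64)
_LEFT_OPS = np.stack([left for left, _ in _PATTERN_OPERANDS]).astype(np.int64)
_RIGHT_OPS = np.stack([right for _, right in _PATTERN_OPERANDS]).astype(np.int64)


def _group_moments(x: np.ndarray, n_blocks: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block group means/stds for all 14 groups via prefix sums.

    Returns arrays of shape (14, n_blocks).  Sample std (n-1 denominator),
    with tiny negative variances from cancellation clipped to zero.
    """
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    base1 = np.empty((5, n_blocks))
    base2 = np.empty((5, n_blocks))
    for i, (lo, hi) in enumerate(_BASE_RANGES):
        base1[i] = c1[hi:hi + n_blocks] - c1[lo:lo + n_blocks]
        base2[i] = c2[hi:hi + n_blocks] - c2[lo:lo + n_blocks]
    s1 = np.empty((N_PATTERNS, n_blocks))
    s2 = np.empty((N_PATTERNS, n_blocks))
    for e, bases in enumerate(_GROUP_BASES):
        if len(bases) == 1:
            s1[e] = base1[bases[0]]
            s2[e] = base2[bases[0]]
        else:
            np.add(base1[bases[0]], base1[bases[1]], out=s1[e])
            np.add(base2[bases[0]], base2[bases[1]], out=s2[e])
    cnt = _GROUP_COUNTS[:, None]
    means = s1 / cnt
    var = np.maximum(s2 - s1 * means, 0.0) / (cnt - 1.0)
    return means, np.sqrt(var)


def bwhpat_transform(signal: np.ndarray) -> MapSignal:
    """Code every 69-sample block of the signal into a byte (the map signal).

    The whole-signal (mean, std) reference of the pattern selection is
    computed once over the full input; selection is per block.  Signals
    shorter than one block yield an empty map with a warning.
    """
    x = _as_signal(signal)
    if x.size < BLOCK_LEN:
        warnings.warn(
            f"signal shorter than {BLOCK_LEN} samples; returning an empty "
            "map signal",
            stacklevel=2,
        )
        return MapSignal(map=np.empty(0, dtype=np.int16),
                         pattern_usage=np.zeros(N_PATTERNS, dtype=np.int64))
    gs = global_stats(x)
    if _fast.HAVE_NUMBA:
        mval, usage = _fast._transform_kernel(
            x, gs.mean, gs.std, _BASE_LO, _BASE_HI, _GROUP_B0, _GROUP_B1,
            _GROUP_COUNTS, _LEFT_OPS, _RIGHT_OPS, _BIT_WEIGHTS)
        return MapSignal(map=mval, pattern_usage=usage)
    return _transform_numpy(x, gs)


def _transform_numpy(x: np.ndarray, gs: GlobalStats) -> MapSignal:
    """Pure-numpy map-signal computation (reference path)."""
    n_blocks = x.size - BLOCK_LEN + 1
    means, stds = _group_moments(x, n_blocks)
    d2 = (gs.mean - means) ** 2 + (gs.std - stds) ** 2
    idt0 = np.argmin(d2, axis=0)          # 0-based; ties -> lowest index
    starts = np.arange(n_blocks)
    mval = np.empty(n_blocks, dtype=np.int16)
    for e in np.unique(idt0):
        sel = starts[idt0 == e]
        left, right = _PATTERN_OPERANDS[e]
        bits = x[sel[:, None] + left] >= x[sel[:, None] + right]
        mval[idt0 == e] = bits @ _BIT_WEIGHTS
    usage = np.bincount(idt0, minlength=N_PATTERNS).astype(np.int64)
    return MapSignal(map=mval, pattern_usage=usage)


def bwhpat_features(signal: np.ndarray, normalize: bool = False) -> np.ndarray:
    """256-bin histogram of the map signal (raw counts by default)."""
    ms = bwhpat_transform(signal)
    hist = np.bincount(ms.map, minlength=N_BINS).astype(float)
    if normalize and ms.map.size:
        hist /= ms.map.size
    return hist
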