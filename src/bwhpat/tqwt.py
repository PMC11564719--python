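"""Tunable Q-factor wavelet transform (TQWT).

An over-complete, perfectly reconstructing wavelet decomposition implemented
as a frequency-domain two-channel filter bank iterated on the lowpass branch.
The transform is parameterized by the quality factor Q, the redundancy r and
the number of levels J; it yields J highpass subbands plus one final lowpass
subband.  The filters use the Daubechies-type transition function

    theta(w) = 0.5 * (1 + cos w) * sqrt(2 - cos w),   |w| <= pi,

which satisfies theta(w)^2 + theta(pi - w)^2 = 1, so analysis followed by
synthesis is exact up to floating-point rounding.  Subband lengths follow the
radix-2 scaling scheme: at level j the lowpass output has 2*round(alpha^j*N/2)
samples and the highpass output 2*round(beta*alpha^(j-1)*N/2), where
beta = 2/(Q+1) and alpha = 1 - beta/r.

Odd-length inputs are zero-padded by one sample before analysis; the pad is
recorded and dropped on reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TqwtParams", "WaveletBands", "tqwt_decompose", "tqwt_reconstruct"]


@dataclass(frozen=True)
class TqwtParams:
    """TQWT parameters.  Defaults (Q=1, r=3, J=9) give 10 subbands."""

    Q: float = 1.0
    r: float = 3.0
    J: int = 9

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError(f"Q must be >= 1, got {self.Q}")
        if self.r <= 1:
            raise ValueError(f"redundancy r must be > 1, got {self.r}")
        if self.J < 1:
            raise ValueError(f"number of levels J must be >= 1, got {self.J}")

    @property
    def beta(self) -> float:
        return 2.0 / (self.Q + 1.0)

    @property
    def alpha(self) -> float:
        return 1.0 - self.beta / self.r


@dataclass
class WaveletBands:
    """Ordered subbands: J highpass bands (fine to coarse), lowpass last."""

    bands: list[np.ndarray]
    parent_length: int       # padded (even) analysis length
    original_length: int     # caller's signal length before padding
    params: TqwtParams = field(default_factory=TqwtParams)

    def __len__(self) -> int:
        return len(self.bands)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.bands[i]


def _subband_lengths(n: int, params: TqwtParams) -> list[tuple[int, int]]:
    """Per level j=1..J the (lowpass, highpass) output lengths, with checks."""
    alpha, beta = params.alpha, params.beta
    out = []
    n_in = n
    for j in range(1, params.J + 1):
        n0 = 2 * int(round(alpha**j * n / 2.0))
        n1 = 2 * int(round(beta * alpha ** (j - 1) * n / 2.0))
        # analysis needs a nonnegative passband, transition band and stopband
        if n0 < 4 or n1 < 4 or n1 > n_in or n0 + n1 < n_in + 2:
            raise ValueError(
                f"signal of length {n} is too short for J={params.J} levels: "
                f"level {j} would need lowpass/highpass lengths {n0}/{n1} "
                f"from {n_in} samples"
            )
        out.append((n0, n1))
        n_in = n0
    return out


def _transition(t: int) -> np.ndarray:
    v = np.arange(1, t + 1) * np.pi / (t + 1)
    return 0.5 * (1.0 + np.cos(v)) * np.sqrt(2.0 - np.cos(v))


def _afb(X: np.ndarray, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-domain analysis filter bank: spectrum X -> (lowpass, highpass)."""
    n = X.size
    p = (n - n1) // 2                 # lowpass passband bins per side
    t = (n0 + n1 - n) // 2 - 1        # transition bins per side
    trans = _transition(t)

    v0 = np.zeros(n0, dtype=complex)
    v0[0] = X[0]
    v0[1 : p + 1] = X[1 : p + 1]
    v0[p + 1 : p + t + 1] = X[p + 1 : p + t + 1] * trans
    # lowpass Nyquist bin carries nothing: that frequency goes to the highpass
    if p > 0:
        v0[n0 - p :] = X[n - p :]
    v0[n0 - p - t : n0 - p] = X[n - p - t : n - p] * trans[::-1]

    v1 = np.zeros(n1, dtype=complex)
    v1[1 : t + 1] = X[p + 1 : p + t + 1] * trans[::-1]
    v1[t + 1 : n1 // 2 + 1] = X[p + t + 1 : n // 2 + 1]
    v1[n1 // 2 + 1 : n1 - t] = X[n // 2 + 1 : n - p - t]
    v1[n1 - t :] = X[n - p - t : n - p] * trans
    return v0, v1


def _sfb(v0: np.ndarray, v1: np.ndarray, n: int) -> np.ndarray:
    """Synthesis filter bank: exact inverse of :func:`_afb`."""
    n0, n1 = v0.size, v1.size
    p = (n - n1) // 2
    t = (n0 + n1 - n) // 2 - 1
    trans = _transition(t)

    X = np.zeros(n, dtype=complex)
    X[0] = v0[0]
    X[1 : p + 1] = v0[1 : p + 1]
    X[p + 1 : p + t + 1] = v0[p + 1 : p + t + 1] * trans + v1[1 : t + 1] * trans[::-1]
    X[p + t + 1 : n // 2 + 1] = v1[t + 1 : n1 // 2 + 1]
    X[n // 2 + 1 : n - p - t] = v1[n1 // 2 + 1 : n1 - t]
    X[n - p - t : n - p] = v0[n0 - p - t : n0 - p] * trans[::-1] + v1[n1 - t :] * trans
    if p > 0:
        X[n - p :] = v0[n0 - p :]
    return X


def tqwt_decompose(signal: np.ndarray, params: TqwtParams | None = None) -> WaveletBands:
    """Decompose a real 1-D signal into J+1 TQWT subbands."""
    params = params or TqwtParams()
    x = np.asarray(signal, dtype=float).ravel()
    orig_len = x.size
    if orig_len < 2:
        raise ValueError("signal must have at least 2 samples")
    if orig_len % 2:
        x = np.concatenate([x, [0.0]])
    n = x.size
    lengths = _subband_lengths(n, params)

    X = np.fft.fft(x) / np.sqrt(n)
    bands: list[np.ndarray] = []
    for n0, n1 in lengths:
        X, W = _afb(X, n0, n1)
        bands.append(np.fft.ifft(W).real * np.sqrt(n1))
    bands.append(np.fft.ifft(X).real * np.sqrt(lengths[-1][0]))
    return WaveletBands(bands=bands, parent_length=n,
                        original_length=orig_len, params=params)


def tqwt_reconstruct(bands: WaveletBands, params: TqwtParams | None = None) -> np.ndarray:
    """Invert :func:`tqwt_decompose`; perfect reconstruction to ~1e-12."""
    params = params or bands.params
    n = bands.parent_length
    lengths = _subband_lengths(n, params)
    if len(bands.bands) != params.J + 1:
        raise ValueError(
            f"expected {params.J + 1} subbands, got {len(bands.bands)}"
        )
    for (n0, n1), w in zip(lengths, bands.bands):
        if w.size != n1:
            raise ValueError("subband lengths inconsistent with parameters")
    if bands.bands[-1].size != lengths[-1][0]:
        raise ValueError("lowpass subband length inconsistent with parameters")

    low = bands.bands[-1]
    X = np.fft.fft(low) / np.sqrt(low.size)
    for j in range(params.J - 1, -1, -1):
        n0, n1 = lengths[j]
        n_out = lengths[j - 1][0] if j > 0 else n
        W = np.fft.fft(bands.bands[j]) / np.sqrt(n1)
        X = _sfb(X, W, n_out)
    x = np.fft.ifft(X).real * np.sqrt(n)
    return x[: bands.original_length]
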