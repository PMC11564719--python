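"""Fused numba kernel for the BWHPat map-signal computation.

Implements exactly the same arithmetic as the numpy path in
:mod:`bwhpat.pattern` (prefix-sum group moments, squared-distance argmin with
lowest-index ties, signum bits of the winning pattern) in a single pass over
the blocks.  Falls back silently when numba is unavailable; a parity test
asserts bit-identical output against the numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f
        return deco


@njit(cache=True)
def _higuchi_lengths(x, kmax):  # pragma: no cover
    n = x.size
    lengths = np.zeros(kmax)
    for k in range(1, kmax + 1):
        lk = 0.0
        for m in range(k):
            s = 0.0
            cnt = 0
            i = m
            while i + k < n:
                s += abs(x[i + k] - x[i])
                cnt += 1
                i += k
            if cnt > 0:
                lk += s * (n - 1) / (cnt * k) / k
        lengths[k - 1] = lk / k
    return lengths


@njit(cache=True)
def _transform_kernel(x, mu_sig, sd_sig, base_lo, base_hi, group_b0, group_b1,
                      counts, left, right, weights):  # pragma: no cover
    n = x.size
    n_blocks = n - 68
    c1 = np.empty(n + 1)
    c2 = np.empty(n + 1)
    c1[0] = 0.0
    c2[0] = 0.0
    for i in range(n):
        c1[i + 1] = c1[i] + x[i]
        c2[i + 1] = c2[i] + x[i] * x[i]
    mval = np.empty(n_blocks, np.int16)
    usage = np.zeros(14, np.int64)
    for g in range(n_blocks):
        best = np.inf
        bi = 0
        for e in range(14):
            b0 = group_b0[e]
            s1 = c1[g + base_hi[b0]] - c1[g + base_lo[b0]]
            s2 = c2[g + base_hi[b0]] - c2[g + base_lo[b0]]
            b1 = group_b1[e]
            if b1 >= 0:
                s1 = s1 + (c1[g + base_hi[b1]] - c1[g + base_lo[b1]])
                s2 = s2 + (c2[g + base_hi[b1]] - c2[g + base_lo[b1]])
            cnt = counts[e]
            mu = s1 / cnt
            var = s2 - s1 * mu
            if var < 0.0:
                var = 0.0
            var = var / (cnt - 1.0)
            dm = mu_sig - mu
            ds = sd_sig - np.sqrt(var)
            d = dm * dm + ds * ds
            if d < best:
                best = d
                bi = e
        usage[bi] += 1
        v = 0
        for r in range(8):
            if x[g + left[bi, r]] >= x[g + right[bi, r]]:
                v += weights[r]
        mval[g] = v
    return mval, usage
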