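"""Numba kernels: affine-gap local alignment score and minimizer sketches.

The alignment is a plain Smith-Waterman score computation with affine gap
costs (a gap of length L costs ``gap_open + L * gap_extend``, the long-read
mapper convention).  Sequences are 2-bit encoded with N mapped to 4; N never
matches anything, scoring as a mismatch against every base.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i

_RC = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0, C=1, G=2, T=3, other=4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _RC[codes][::-1]


@njit(cache=True)
def sw_score(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    """Best local alignment score; linear memory, score-only."""
    n, m = q.shape[0], t.shape[0]
    NEG = -(10**9)
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        diag = 0
        F = NEG
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = E[j] + gap_extend
            eo = H[j] + gap_open + gap_extend
            E[j] = e if e > eo else eo
            f = F + gap_extend
            fo = H[j - 1] + gap_open + gap_extend
            F = f if f > fo else fo
            s = match if (qi == t[j - 1] and qi < 4 and t[j - 1] < 4) else mismatch
            h = diag + s
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _kmer_hashes(codes, k):  # pragma: no cover - jitted
    """Rolling k-mer integer values, mixed through a 64-bit finalizer.

    Positions whose k-mer contains a non-ACGT code get hash 2^63-1 (never a
    window minimum in practice and excluded from sketches).
    """
    n = codes.shape[0]
    out = np.full(max(n - k + 1, 0), np.int64(2**63 - 1), dtype=np.int64)
    if n < k:
        return out
    mask = np.int64((1 << (2 * k)) - 1)
    v = np.int64(0)
    bad = 0  # bases since last N
    for i in range(n):
        c = codes[i]
        v = ((v << 2) | np.int64(c & 3)) & mask
        if c >= 4:
            bad = k
        elif bad > 0:
            bad -= 1
        if i >= k - 1 and bad == 0:
            h = np.uint64(v)
            h = (h ^ (h >> np.uint64(33))) * np.uint64(0xFF51AFD7ED558CCD)
            h = (h ^ (h >> np.uint64(33))) * np.uint64(0xC4CEB9FE1A85EC53)
            h = h ^ (h >> np.uint64(33))
            out[i - k + 1] = np.int64(h >> np.uint64(1))  # keep non-negative
    return out


@njit(cache=True)
def _window_minima(hashes, w):  # pragma: no cover - jitted
    n = hashes.shape[0]
    sentinel = np.int64(2**63 - 1)
    out = np.empty(n, dtype=np.int64)
    cnt = 0
    for start in range(max(n - w + 1, 1)):
        lo = sentinel
        for j in range(start, min(start + w, n)):
            if hashes[j] < lo:
                lo = hashes[j]
        if lo != sentinel and (cnt == 0 or out[cnt - 1] != lo):
            out[cnt] = lo
            cnt += 1
    return out[:cnt]


def minimizer_sketch(codes: np.ndarray, k: int = 15, w: int = 10) -> frozenset[int]:
    """Set of window-minimum k-mer hashes of the sequence (one strand)."""
    return frozenset(_window_minima(_kmer_hashes(codes, k), w).tolist())
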