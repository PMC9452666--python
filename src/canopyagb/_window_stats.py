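"""Sliding-window co-occurrence statistics (numba-accelerated inner loop).

For every pixel, the 8 texture statistics of the symmetric, normalised GLCM of
the centred ``win x win`` window are required.  Rebuilding each window's
co-occurrence histogram from scratch is O(win^2) per pixel; instead the
histogram and every moment the statistics need are maintained incrementally as
the window slides along a row, so each step only inserts/removes the pair
column entering/leaving the window.

All statistics are exact (not approximations of the per-window GLCM): the
incremental accumulators track sums over the *ordered* co-occurrence entries
(each unordered pair counted in both directions, i.e. the symmetric GLCM), and
the per-pixel statistics are closed-form functions of those sums.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: output order of the statistic planes
STAT_ORDER = ("Mea", "Var", "Hom", "Con", "Dis", "Ent", "Sec", "Cor")

_VAR_EPS = 1e-12


@njit(cache=True)
def _window_stats_kernel(qp, H, W, win, dr, dc, L, clog, out):  # pragma: no cover - jit
    # relative pair ranges inside a win x win window for offset (dr, dc)
    a0 = max(0, -dr)
    a1 = win - 1 - max(0, dr)
    b0 = max(0, -dc)
    b1 = win - 1 - max(0, dc)
    cnt = np.zeros(L * L, dtype=np.int64)
    log2n_cache = np.empty(4 * win * win + 1, dtype=np.float64)
    log2n_cache[0] = 0.0
    for n in range(1, 4 * win * win + 1):
        log2n_cache[n] = np.log2(n)
    for y in range(H):
        # rebuild state for the leftmost window of this row
        cnt[:] = 0
        N = 0
        s_i = 0
        s_i2 = 0
        s_ij = 0
        s_ab = 0
        s_sq = 0
        s_hom = 0.0
        E = 0.0
        S2 = 0
        for a in range(a0, a1 + 1):
            for b in range(b0, b1 + 1):
                i = qp[y + a, b]
                j = qp[y + a + dr, b + dc]
                N += 2
                s_i += i + j
                s_i2 += i * i + j * j
                s_ij += 2 * i * j
                d = i - j if i >= j else j - i
                s_ab += 2 * d
                s_sq += 2 * d * d
                s_hom += 2.0 / (1.0 + d * d)
                c1 = i * L + j
                c2 = j * L + i
                c = cnt[c1]
                E += clog[c + 1] - clog[c]
                S2 += 2 * c + 1
                cnt[c1] = c + 1
                c = cnt[c2]
                E += clog[c + 1] - clog[c]
                S2 += 2 * c + 1
                cnt[c2] = c + 1
        for x in range(W):
            if x > 0:
                # slide: drop the leaving pair column, insert the entering one
                for a in range(a0, a1 + 1):
                    # leaving pairs: window x-1, relative col b0
                    i = qp[y + a, (x - 1) + b0]
                    j = qp[y + a + dr, (x - 1) + b0 + dc]
                    N -= 2
                    s_i -= i + j
                    s_i2 -= i * i + j * j
                    s_ij -= 2 * i * j
                    d = i - j if i >= j else j - i
                    s_ab -= 2 * d
                    s_sq -= 2 * d * d
                    s_hom -= 2.0 / (1.0 + d * d)
                    c1 = i * L + j
                    c2 = j * L + i
                    c = cnt[c1]
                    E += clog[c - 1] - clog[c]
                    S2 -= 2 * c - 1
                    cnt[c1] = c - 1
                    c = cnt[c2]
                    E += clog[c - 1] - clog[c]
                    S2 -= 2 * c - 1
                    cnt[c2] = c - 1
                    # entering pairs: window x, relative col b1
                    i = qp[y + a, x + b1]
                    j = qp[y + a + dr, x + b1 + dc]
                    N += 2
                    s_i += i + j
                    s_i2 += i * i + j * j
                    s_ij += 2 * i * j
                    d = i - j if i >= j else j - i
                    s_ab += 2 * d
                    s_sq += 2 * d * d
                    s_hom += 2.0 / (1.0 + d * d)
                    c1 = i * L + j
                    c2 = j * L + i
                    c = cnt[c1]
                    E += clog[c + 1] - clog[c]
                    S2 += 2 * c + 1
                    cnt[c1] = c + 1
                    c = cnt[c2]
                    E += clog[c + 1] - clog[c]
                    S2 += 2 * c + 1
                    cnt[c2] = c + 1
            n = float(N)
            mean = s_i / n
            var = s_i2 / n - mean * mean
            out[0, y, x] = mean
            out[1, y, x] = var
            out[2, y, x] = s_hom / n
            out[3, y, x] = s_sq / n
            out[4, y, x] = s_ab / n
            out[5, y, x] = log2n_cache[N] - E / n
            out[6, y, x] = S2 / (n * n)
            cov = s_ij / n - mean * mean
            out[7, y, x] = cov / var if var > _VAR_EPS else 1.0


def window_texture_stats(gray: np.ndarray, window: int, offset: tuple, levels: int) -> np.ndarray:
    """Per-pixel symmetric-GLCM statistics over centred reflect-padded windows.

    Returns an ``(8, H, W)`` float array in :data:`STAT_ORDER` order.
    """
    gray = np.ascontiguousarray(gray, dtype=np.int64)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    dr, dc = int(offset[0]), int(offset[1])
    if abs(dr) >= window or abs(dc) >= window:
        raise ValueError(f"offset {offset} exceeds the {window}x{window} window")
    if gray.min() < 0 or gray.max() >= levels:
        raise ValueError("gray values must lie in 0..levels-1")
    H, W = gray.shape
    r = window // 2
    qp = np.pad(gray, r, mode="reflect")
    out = np.empty((8, H, W), dtype=np.float64)
    # c*log2(c) lookup, enough for every count in a window (<= 2*win^2 ordered entries)
    counts = np.arange(2 * window * window + 2, dtype=np.float64)
    clog = np.zeros_like(counts)
    nz = counts > 0
    clog[nz] = counts[nz] * np.log2(counts[nz])
    _window_stats_kernel(qp, H, W, window, dr, dc, levels, clog, out)
    return out
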