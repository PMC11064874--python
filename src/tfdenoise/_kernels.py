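"""Numba kernels for non-local means filtering.

Both kernels are exact transcriptions of the patch-weighted average

    s_hat(m) = (1/Z(m)) * sum_{n in N(m)} w(m, n) y(n),
    w(m, n)  = exp(-d2(m, n) / (2 L lambda^2)),

with ``d2`` the sum of squared differences over the (2P+1)-wide patch
(mirror-padded at the borders) and ``N(m)`` the (2Q+1)-wide search window
truncated at the borders.  They exploit two exact identities for speed:
``d2`` is symmetric in (m, n), so each unordered pixel pair is visited once
and accumulated at both ends, and patch sums over a fixed offset are sliding
window sums.
"""

import numpy as np
from numba import njit


@njit(fastmath=True)
def nlm2d(plane, P, Q, lam):
    rows, cols = plane.shape
    L = (2 * P + 1) ** 2
    inv = 1.0 / (2.0 * L * lam * lam)
    width = 2 * P + 1
    # mirror pad by P (reflect, edge not repeated)
    padded = np.empty((rows + 2 * P, cols + 2 * P), np.float64)
    for r in range(rows + 2 * P):
        rr = r - P
        if rr < 0:
            rr = -rr
        elif rr >= rows:
            rr = 2 * rows - 2 - rr
        for c in range(cols + 2 * P):
            cc = c - P
            if cc < 0:
                cc = -cc
            elif cc >= cols:
                cc = 2 * cols - 2 - cc
            padded[r, c] = plane[rr, cc]
    acc = plane.astype(np.float64).copy()  # self term: w(m, m) = 1
    z = np.ones((rows, cols), np.float64)
    tmp = np.empty((rows + 2 * P, cols), np.float64)
    colsum = np.empty(cols, np.float64)
    for a in range(0, Q + 1):
        bstart = 1 if a == 0 else -Q
        for b in range(bstart, Q + 1):
            r0 = 0 if a >= 0 else -a
            r1 = rows - a
            c0 = 0 if b >= 0 else -b
            c1 = cols if b <= 0 else cols - b
            nc = c1 - c0
            # horizontal sliding patch sums of squared diffs
            for i in range(r1 - r0 + 2 * P):
                pr = r0 + i
                s = 0.0
                for jj in range(width):
                    d = padded[pr, c0 + jj] - padded[pr + a, c0 + jj + b]
                    s += d * d
                tmp[i, 0] = s
                for c in range(c0 + 1, c1):
                    d_in = padded[pr, c + 2 * P] - padded[pr + a, c + 2 * P + b]
                    d_out = padded[pr, c - 1] - padded[pr + a, c - 1 + b]
                    s += d_in * d_in - d_out * d_out
                    tmp[i, c - c0] = s
            # vertical sliding sums fused with symmetric accumulation
            for jj in range(nc):
                s = 0.0
                for i in range(width):
                    s += tmp[i, jj]
                colsum[jj] = s
            for jj in range(nc):
                c = c0 + jj
                w = np.exp(-colsum[jj] * inv)
                acc[r0, c] += w * plane[r0 + a, c + b]
                z[r0, c] += w
                acc[r0 + a, c + b] += w * plane[r0, c]
                z[r0 + a, c + b] += w
            for r in range(r0 + 1, r1):
                i = r - r0
                for jj in range(nc):
                    c = c0 + jj
                    s = colsum[jj] + tmp[i + 2 * P, jj] - tmp[i - 1, jj]
                    colsum[jj] = s
                    w = np.exp(-s * inv)
                    acc[r, c] += w * plane[r + a, c + b]
                    z[r, c] += w
                    acc[r + a, c + b] += w * plane[r, c]
                    z[r + a, c + b] += w
    return acc / z


@njit(fastmath=True)
def nlm1d(x, P, Q, lam):
    n = x.size
    L = 2 * P + 1
    inv = 1.0 / (2.0 * L * lam * lam)
    padded = np.empty(n + 2 * P, np.float64)
    for i in range(n + 2 * P):
        j = i - P
        if j < 0:
            j = -j
        elif j >= n:
            j = 2 * n - 2 - j
        padded[i] = x[j]
    acc = x.astype(np.float64).copy()
    z = np.ones(n, np.float64)
    for off in range(1, Q + 1):
        # sliding patch distance between m and m + off
        s = 0.0
        for jj in range(L):
            d = padded[jj] - padded[jj + off]
            s += d * d
        m = 0
        w = np.exp(-s * inv)
        acc[m] += w * x[m + off]
        z[m] += w
        acc[m + off] += w * x[m]
        z[m + off] += w
        for m in range(1, n - off):
            d_in = padded[m + 2 * P] - padded[m + 2 * P + off]
            d_out = padded[m - 1] - padded[m - 1 + off]
            s += d_in * d_in - d_out * d_out
            w = np.exp(-s * inv)
            acc[m] += w * x[m + off]
            z[m] += w
            acc[m + off] += w * x[m]
            z[m + off] += w
    return acc / z
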