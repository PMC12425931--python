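"""Numba-compiled inner loops for the hot layers.

Pure-NumPy fallbacks live in :mod:`mdwcnet.nn`; these kernels compute the
same quantities (verified by the layer-level gradient checks) but avoid the
large temporaries that slice-based NumPy implementations need.  Import is
optional: if numba is unavailable, ``HAVE_NUMBA`` is False and the layers
keep their NumPy paths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


@njit(cache=False, fastmath=True)
def dw_fwd(xp, w, d, out):
    n, c, h, wd = out.shape
    k = w.shape[1]
    for nn in range(n):
        for cc in range(c):
            for y in range(h):
                orow = out[nn, cc, y]
                for i in range(k):
                    xrow = xp[nn, cc, y + i * d]
                    for j in range(k):
                        wv = w[cc, i, j]
                        off = j * d
                        for x in range(wd):
                            orow[x] += wv * xrow[x + off]


@njit(cache=False, fastmath=True)
def dw_bwd(xp, w, g, d, gxp, gw):
    # weight gradient: plain reduction of xp (shifted) against g
    n, c, h, wd = g.shape
    k = w.shape[1]
    for cc in range(c):
        acc = np.zeros((k, k), dtype=np.float64)
        for nn in range(n):
            for y in range(h):
                grow = g[nn, cc, y]
                for i in range(k):
                    xrow = xp[nn, cc, y + i * d]
                    for j in range(k):
                        off = j * d
                        s = 0.0
                        for x in range(wd):
                            s += xrow[x + off] * grow[x]
                        acc[i, j] += s
        for i in range(k):
            for j in range(k):
                gw[cc, i, j] += acc[i, j]
    # input gradient: transpose of dw_fwd, a stride-1 accumulation into the
    # padded buffer
    for nn in range(n):
        for cc in range(c):
            for y in range(h):
                grow = g[nn, cc, y]
                for i in range(k):
                    gxrow = gxp[nn, cc, y + i * d]
                    for j in range(k):
                        wv = w[cc, i, j]
                        off = j * d
                        for x in range(wd):
                            gxrow[x + off] += wv * grow[x]


@njit(cache=False, fastmath=True)
def up2_fwd(x, out):
    n, c, h, w = x.shape
    for nn in range(n):
        for cc in range(c):
            for oy in range(2 * h):
                iy = oy >> 1
                if oy & 1:
                    y0, y1 = iy, min(iy + 1, h - 1)
                    wy0 = np.float32(0.75)
                else:
                    y0, y1 = max(iy - 1, 0), iy
                    wy0 = np.float32(0.25)
                wy1 = np.float32(1.0) - wy0
                r0 = x[nn, cc, y0]
                r1 = x[nn, cc, y1]
                orow = out[nn, cc, oy]
                for ox in range(2 * w):
                    ix = ox >> 1
                    if ox & 1:
                        x0, x1 = ix, min(ix + 1, w - 1)
                        wx0 = np.float32(0.75)
                    else:
                        x0, x1 = max(ix - 1, 0), ix
                        wx0 = np.float32(0.25)
                    wx1 = np.float32(1.0) - wx0
                    orow[ox] = wy0 * (wx0 * r0[x0] + wx1 * r0[x1]) + wy1 * (
                        wx0 * r1[x0] + wx1 * r1[x1]
                    )


@njit(cache=False, fastmath=True)
def up2_bwd(g, gx):
    n, c, h, w = gx.shape
    for nn in range(n):
        for cc in range(c):
            for oy in range(2 * h):
                iy = oy >> 1
                if oy & 1:
                    y0, y1 = iy, min(iy + 1, h - 1)
                    wy0 = np.float32(0.75)
                else:
                    y0, y1 = max(iy - 1, 0), iy
                    wy0 = np.float32(0.25)
                wy1 = np.float32(1.0) - wy0
                grow = g[nn, cc, oy]
                g0 = gx[nn, cc, y0]
                g1 = gx[nn, cc, y1]
                for ox in range(2 * w):
                    ix = ox >> 1
                    if ox & 1:
                        x0, x1 = ix, min(ix + 1, w - 1)
                        wx0 = np.float32(0.75)
                    else:
                        x0, x1 = max(ix - 1, 0), ix
                        wx0 = np.float32(0.25)
                    wx1 = np.float32(1.0) - wx0
                    gv = grow[ox]
                    g0[x0] += wy0 * wx0 * gv
                    g0[x1] += wy0 * wx1 * gv
                    g1[x0] += wy1 * wx0 * gv
                    g1[x1] += wy1 * wx1 * gv


@njit(cache=False, fastmath=True)
def pool2_fwd(x, y, idx):
    n, c, h2, w2 = y.shape
    for nn in range(n):
        for cc in range(c):
            for i in range(h2):
                r0 = x[nn, cc, 2 * i]
                r1 = x[nn, cc, 2 * i + 1]
                for j in range(w2):
                    best = r0[2 * j]
                    bi = 0
                    v = r0[2 * j + 1]
                    if v > best:
                        best, bi = v, 1
                    v = r1[2 * j]
                    if v > best:
                        best, bi = v, 2
                    v = r1[2 * j + 1]
                    if v > best:
                        best, bi = v, 3
                    y[nn, cc, i, j] = best
                    idx[nn, cc, i, j] = bi


@njit(cache=False, fastmath=True)
def pool2_bwd(g, idx, gx):
    n, c, h2, w2 = g.shape
    for nn in range(n):
        for cc in range(c):
            for i in range(h2):
                for j in range(w2):
                    bi = idx[nn, cc, i, j]
                    gx[nn, cc, 2 * i + (bi >> 1), 2 * j + (bi & 1)] = g[nn, cc, i, j]
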