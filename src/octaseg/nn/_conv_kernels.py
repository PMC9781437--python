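"""Direct 3x3 convolution kernels (numba JIT, single CPU).

Direct slice accumulation beats im2col materialisation at the small
channel counts this package trains with; the im2col path in tensor.py
remains the generic fallback for other kernel sizes or when numba is
unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco


@njit(fastmath=True)
def conv3x3_fwd(xp: np.ndarray, w: np.ndarray) -> np.ndarray:
    """xp is the already-padded input [B,C,H+2,W+2]; w is [Cout,C,3,3]."""
    B, C, Hp, Wp = xp.shape
    Cout = w.shape[0]
    H, W = Hp - 2, Wp - 2
    out = np.zeros((B, Cout, H, W), np.float32)
    for b in range(B):
        for co in range(Cout):
            acc = out[b, co]
            for ci in range(C):
                xc = xp[b, ci]
                for di in range(3):
                    for dj in range(3):
                        wv = w[co, ci, di, dj]
                        for i in range(H):
                            xr = xc[i + di]
                            ar = acc[i]
                            for j in range(W):
                                ar[j] += wv * xr[j + dj]
    return out


@njit(fastmath=True)
def conv3x3_gradw(xp: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Weight gradient: correlate padded input [B,C,H+2,W+2] with g [B,Cout,H,W]."""
    B, C, Hp, Wp = xp.shape
    Cout = g.shape[1]
    H, W = g.shape[2], g.shape[3]
    gw = np.zeros((Cout, C, 3, 3), np.float32)
    for b in range(B):
        for co in range(Cout):
            gc = g[b, co]
            for ci in range(C):
                xc = xp[b, ci]
                for di in range(3):
                    for dj in range(3):
                        acc = np.float32(0.0)
                        for i in range(H):
                            xr = xc[i + di]
                            gr = gc[i]
                            for j in range(W):
                                acc += gr[j] * xr[j + dj]
                        gw[co, ci, di, dj] += acc
    return gw
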