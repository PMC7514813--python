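"""Numba-compiled memory-movement kernels for the CNN engine.

Only data rearrangement lives here (im2col / col2im / max-pool); all
arithmetic-heavy products run in BLAS via numpy matmul.  Row layout of
the column matrix is channel-major — row index ``c*k*k + ky*k + kx`` —
matching a row-major reshape of an (F, C, k, k) weight tensor.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "im2col",
    "col2im",
    "col2im_t",
    "maxpool_forward",
    "maxpool_backward",
    "sgd_update",
]


@njit(cache=True)
def sgd_update(
    w: np.ndarray, g: np.ndarray, v: np.ndarray, lr: float, mu: float, wd: float
) -> None:
    """Fused classical-momentum step on flat float32 views."""
    for i in range(w.size):
        vi = mu * v[i] - lr * (g[i] + wd * w[i])
        v[i] = vi
        w[i] += vi


@njit(cache=True)
def im2col(x_pad: np.ndarray, k: int, out_h: int, out_w: int) -> np.ndarray:
    n, c = x_pad.shape[0], x_pad.shape[1]
    cols = np.empty((n, c * k * k, out_h * out_w), dtype=np.float32)
    for ni in range(n):
        for ci in range(c):
            for dy in range(k):
                for dx in range(k):
                    row = (ci * k + dy) * k + dx
                    for y in range(out_h):
                        base = y * out_w
                        for x in range(out_w):
                            cols[ni, row, base + x] = x_pad[ni, ci, dy + y, dx + x]
    return cols


@njit(cache=True)
def col2im(dcols: np.ndarray, n: int, c: int, h: int, w: int, k: int) -> np.ndarray:
    """Fold column gradients back onto the (padded) input and crop."""
    p = k // 2
    dx_pad = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
    for ni in range(n):
        for ci in range(c):
            for dy in range(k):
                for dxo in range(k):
                    row = (ci * k + dy) * k + dxo
                    for y in range(h):
                        base = y * w
                        for x in range(w):
                            dx_pad[ni, ci, dy + y, dxo + x] += dcols[ni, row, base + x]
    return dx_pad[:, :, p : p + h, p : p + w]


@njit(cache=True)
def col2im_t(dcols_t: np.ndarray, n: int, c: int, h: int, w: int, k: int) -> np.ndarray:
    """Like :func:`col2im` but for a (C*k*k, n, h*w) gradient layout."""
    p = k // 2
    dx_pad = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
    for ci in range(c):
        for dy in range(k):
            for dxo in range(k):
                row = (ci * k + dy) * k + dxo
                for ni in range(n):
                    for y in range(h):
                        base = y * w
                        for x in range(w):
                            dx_pad[ni, ci, dy + y, dxo + x] += dcols_t[row, ni, base + x]
    return dx_pad[:, :, p : p + h, p : p + w]


@njit(cache=True)
def maxpool_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2/stride-2 max pool; returns (pooled, winner index 0..3).

    The winner is the first maximal element of the window in row-major
    order, so ties resolve deterministically to a single element.
    """
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    out = np.empty((n, c, h2, w2), dtype=np.float32)
    arg = np.empty((n, c, h2, w2), dtype=np.uint8)
    for ni in range(n):
        for ci in range(c):
            for y in range(h2):
                for xx in range(w2):
                    a = x[ni, ci, 2 * y, 2 * xx]
                    b = x[ni, ci, 2 * y, 2 * xx + 1]
                    cc = x[ni, ci, 2 * y + 1, 2 * xx]
                    d = x[ni, ci, 2 * y + 1, 2 * xx + 1]
                    best = a
                    which = 0
                    if b > best:
                        best = b
                        which = 1
                    if cc > best:
                        best = cc
                        which = 2
                    if d > best:
                        best = d
                        which = 3
                    out[ni, ci, y, xx] = best
                    arg[ni, ci, y, xx] = which
    return out, arg


@njit(cache=True)
def maxpool_backward(
    dout: np.ndarray, arg: np.ndarray, h: int, w: int
) -> np.ndarray:
    n, c, h2, w2 = dout.shape
    dx = np.zeros((n, c, h, w), dtype=np.float32)
    for ni in range(n):
        for ci in range(c):
            for y in range(h2):
                for xx in range(w2):
                    which = arg[ni, ci, y, xx]
                    dy = which // 2
                    dxo = which % 2
                    dx[ni, ci, 2 * y + dy, 2 * xx + dxo] = dout[ni, ci, y, xx]
    return dx
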