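"""Low-level array operations for the network layers.

Convolutions are implemented with an im2col/col2im pair built on
``numpy.lib.stride_tricks.sliding_window_view``; transposed convolution is
the adjoint of the forward convolution, so both share the same two
primitives.  Everything here works for 2 or 3 spatial dimensions and is
shape-exact: stride-2 layers halve every axis (even sizes required), which
keeps the encoder/decoder spatial arithmetic invertible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv_forward",
    "conv_backward_input",
    "conv_backward_weight",
    "avg_pool",
    "avg_pool_backward",
    "upsample_matrix",
    "resize_linear",
    "resize_linear_adjoint",
]


def _pad(x: np.ndarray, pad: int, ndim_spatial: int) -> np.ndarray:
    if pad == 0:
        return x
    cfg = [(0, 0), (0, 0)] + [(pad, pad)] * ndim_spatial
    return np.pad(x, cfg)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(N, C, *S) -> (N, out_positions, C * k**d) column matrix."""
    d = x.ndim - 2
    xp = _pad(x, pad, d)
    win = sliding_window_view(xp, (k,) * d, axis=tuple(range(2, 2 + d)))
    # win: (N, C, *outfull, *k); subsample by stride
    sl = (slice(None), slice(None)) + (slice(None, None, stride),) * d
    win = win[sl]
    out_spatial = win.shape[2 : 2 + d]
    n, c = x.shape[:2]
    cols = win.reshape(n, c, int(np.prod(out_spatial)), k**d)
    cols = cols.transpose(0, 2, 1, 3).reshape(n, int(np.prod(out_spatial)), c * k**d)
    return np.ascontiguousarray(cols), out_spatial


def conv_out_shape(spatial: tuple, k: int, stride: int, pad: int) -> tuple:
    return tuple((s + 2 * pad - k) // stride + 1 for s in spatial)


def conv_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int, pad: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlation of (N, Cin, *S) with (Cout, Cin, *K).

    Returns (output, cached column matrix) — the cache is reused by the
    weight-gradient pass.
    """
    cout = w.shape[0]
    k = w.shape[2]
    cols, out_spatial = _im2col(x, k, stride, pad)
    wmat = w.reshape(cout, -1)
    y = cols @ wmat.T  # (N, P, Cout)
    if b is not None:
        y = y + b
    n = x.shape[0]
    y = y.transpose(0, 2, 1).reshape(n, cout, *out_spatial)
    return np.ascontiguousarray(y), cols


def conv_backward_weight(
    cols: np.ndarray, dy: np.ndarray, w_shape: tuple
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients (dW, db) given the cached columns and output gradient."""
    n, cout = dy.shape[:2]
    dyf = dy.reshape(n, cout, -1)  # (N, Cout, P)
    dw = np.einsum("ncp,npk->ck", dyf, cols, optimize=True)
    db = dyf.sum(axis=(0, 2))
    return dw.reshape(w_shape), db


def conv_backward_input(
    dy: np.ndarray, w: np.ndarray, x_spatial: tuple, stride: int, pad: int
) -> np.ndarray:
    """dL/dx by scatter-add (col2im) of the column-space gradient."""
    n, cout = dy.shape[:2]
    cin = w.shape[1]
    k = w.shape[2]
    d = len(x_spatial)
    dyf = dy.reshape(n, cout, -1).transpose(0, 2, 1)  # (N, P, Cout)
    dcols = dyf @ w.reshape(cout, -1)  # (N, P, Cin*k^d)
    padded = tuple(s + 2 * pad for s in x_spatial)
    dxp = np.zeros((n, cin) + padded, dtype=dy.dtype)
    out_spatial = conv_out_shape(x_spatial, k, stride, pad)
    p_total = int(np.prod(out_spatial))
    dcols = dcols.reshape((n, p_total, cin) + (k,) * d)
    # iterate over the (small) kernel taps, vectorized over batch/positions
    grids = np.meshgrid(*[np.arange(o) * stride for o in out_spatial], indexing="ij")
    base = [g.ravel() for g in grids]  # per-position origin, length P
    for taps in np.ndindex(*(k,) * d):
        sl = (slice(None), slice(None), slice(None)) + taps
        patch = dcols[sl]  # (N, P, Cin)
        idx = tuple(base[a] + taps[a] for a in range(d))
        np.add.at(
            dxp.transpose(0, *range(2, 2 + d), 1),
            (slice(None),) + idx,
            patch,
        )
    if pad:
        core = (slice(None), slice(None)) + tuple(slice(pad, -pad) for _ in range(d))
        return np.ascontiguousarray(dxp[core])
    return dxp


def avg_pool(x: np.ndarray) -> np.ndarray:
    """2x average pooling along every spatial axis (even sizes)."""
    d = x.ndim - 2
    out = x
    for ax in range(2, 2 + d):
        s = out.shape
        if s[ax] % 2:
            raise ValueError(f"odd spatial size {s[ax]} on axis {ax} for 2x pooling")
        shp = s[:ax] + (s[ax] // 2, 2) + s[ax + 1 :]
        out = out.reshape(shp).mean(axis=ax + 1)
    return out


def avg_pool_backward(dy: np.ndarray) -> np.ndarray:
    d = dy.ndim - 2
    out = dy
    for ax in range(2, 2 + d):
        out = np.repeat(out, 2, axis=ax)
    return out / (2.0**d)


_matrix_cache: dict[tuple, np.ndarray] = {}


def upsample_matrix(n_in: int, n_out: int, dtype=np.float64) -> np.ndarray:
    """Dense 1D linear-interpolation matrix (n_out x n_in), align_corners=False.

    Output sample i is taken at source coordinate (i + 0.5) * n_in / n_out - 0.5,
    edge-clamped — the convention used by the standard deep-learning resizers.
    """
    key = (n_in, n_out, np.dtype(dtype).name)
    if key in _matrix_cache:
        return _matrix_cache[key]
    m = np.zeros((n_out, n_in), dtype=dtype)
    for i in range(n_out):
        src = (i + 0.5) * n_in / n_out - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1.0 - frac
        m[i, hi_c] += frac
    _matrix_cache[key] = m
    return m


def resize_linear(x: np.ndarray, out_spatial: tuple) -> np.ndarray:
    """Separable linear resize of (N, C, *S) to (N, C, *out_spatial)."""
    d = x.ndim - 2
    out = x
    for ax in range(d):
        m = upsample_matrix(out.shape[2 + ax], out_spatial[ax], out.dtype)
        out = np.moveaxis(np.tensordot(m, out, axes=([1], [2 + ax])), 0, 2 + ax)
    return np.ascontiguousarray(out)


def resize_linear_adjoint(dy: np.ndarray, in_spatial: tuple) -> np.ndarray:
    """Adjoint of :func:`resize_linear` (gradient of the resize)."""
    d = dy.ndim - 2
    out = dy
    for ax in range(d):
        m = upsample_matrix(in_spatial[ax], out.shape[2 + ax], out.dtype)
        out = np.moveaxis(np.tensordot(m.T, out, axes=([1], [2 + ax])), 0, 2 + ax)
    return np.ascontiguousarray(out)
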