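"""Low-level 3D convolution primitives on NumPy.

All tensors are channel-first without a batch axis: ``(C, D, H, W)`` in
float32. Convolutions are evaluated as im2col + BLAS matmul, chunked along
the first spatial axis so the column buffer stays within a fixed memory
budget (large 144^3 inputs would otherwise need a multi-GB buffer).

``conv3d_backward_input`` doubles as the forward pass of the stride-2
transposed convolution (they are adjoint linear maps), which is how the
decoder's up-sampling is implemented.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

# column-buffer budget in elements (~256 MB at float32)
_COL_BUDGET = 64_000_000


def _slab_rows(out_d: int, row_cols: int) -> int:
    """How many output z-slices fit in the column budget (>= 1)."""
    return max(1, int(_COL_BUDGET // max(1, row_cols)))


def _out_shape(in_shape, k: int, stride: int, pad: int):
    return tuple((d + 2 * pad - k) // stride + 1 for d in in_shape)


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))


def _im2col_slab(xp: np.ndarray, k: int, stride: int, d0: int, d1: int, ho: int, wo: int) -> np.ndarray:
    """Columns for output slices [d0, d1): shape ((d1-d0)*ho*wo, C*k^3)."""
    C = xp.shape[0]
    nd = d1 - d0
    s0, s1, s2, s3 = xp.strides
    base = xp[:, d0 * stride:, :, :]
    view = np.lib.stride_tricks.as_strided(
        base,
        shape=(C, k, k, k, nd, ho, wo),
        strides=(s0, s1, s2, s3, s1 * stride, s2 * stride, s3 * stride),
        writeable=False,
    )
    return view.transpose(4, 5, 6, 0, 1, 2, 3).reshape(nd * ho * wo, C * k**3)


def conv3d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray | None,
                   stride: int = 1, pad: int | None = None) -> np.ndarray:
    """Cross-correlation of ``x (Cin,D,H,W)`` with ``W (Cout,Cin,k,k,k)``."""
    cout, cin, k = W.shape[0], W.shape[1], W.shape[2]
    if pad is None:
        pad = k // 2
    if k == 1 and stride == 1:
        y = np.tensordot(W.reshape(cout, cin), x, axes=(1, 0))
        if b is not None:
            y += b[:, None, None, None]
        return np.ascontiguousarray(y, dtype=DTYPE)
    xp = _pad_spatial(np.ascontiguousarray(x, dtype=DTYPE), pad)
    do, ho, wo = _out_shape(x.shape[1:], k, stride, pad)
    Wm = W.reshape(cout, cin * k**3).astype(DTYPE, copy=False)
    y = np.empty((cout, do, ho, wo), dtype=DTYPE)
    step = _slab_rows(do, ho * wo * cin * k**3)
    for d0 in range(0, do, step):
        d1 = min(d0 + step, do)
        cols = _im2col_slab(xp, k, stride, d0, d1, ho, wo)
        y[:, d0:d1] = (cols @ Wm.T).T.reshape(cout, d1 - d0, ho, wo)
    if b is not None:
        y += b.astype(DTYPE)[:, None, None, None]
    return y


def _col2im_add(gxp: np.ndarray, g: np.ndarray, k: int, stride: int,
                d0: int, d1: int, ho: int, wo: int) -> None:
    """Scatter-add column gradients for output slices [d0, d1) into padded gxp."""
    C = gxp.shape[0]
    nd = d1 - d0
    g7 = g.reshape(nd, ho, wo, C, k, k, k)
    for a in range(k):
        za = d0 * stride + a
        for bb in range(k):
            for c in range(k):
                gxp[:, za:za + nd * stride:stride,
                    bb:bb + ho * stride:stride,
                    c:c + wo * stride:stride] += g7[:, :, :, :, a, bb, c].transpose(3, 0, 1, 2)


def conv3d_backward_input(gy: np.ndarray, W: np.ndarray, in_shape,
                          stride: int = 1, pad: int | None = None) -> np.ndarray:
    """Gradient w.r.t. the conv input; also the transposed-conv forward map.

    ``in_shape`` is the (unpadded) spatial shape of the conv input. For the
    stride-2 transposed convolution the caller passes the *output* (fine)
    shape here and ``gy`` is the coarse input.
    """
    cout, cin, k = W.shape[0], W.shape[1], W.shape[2]
    if pad is None:
        pad = k // 2
    if k == 1 and stride == 1:
        return np.ascontiguousarray(
            np.tensordot(W.reshape(cout, cin), gy, axes=(0, 0)), dtype=DTYPE)
    do, ho, wo = gy.shape[1:]
    Wm = W.reshape(cout, cin * k**3).astype(DTYPE, copy=False)
    gxp = np.zeros((cin,) + tuple(d + 2 * pad for d in in_shape), dtype=DTYPE)
    gym = gy.reshape(cout, -1)
    step = _slab_rows(do, ho * wo * cin * k**3)
    for d0 in range(0, do, step):
        d1 = min(d0 + step, do)
        sl = gy[:, d0:d1].reshape(cout, -1).T.astype(DTYPE, copy=False)
        gcols = sl @ Wm
        _col2im_add(gxp, gcols, k, stride, d0, d1, ho, wo)
    if pad == 0:
        return gxp
    D, H, Wd = in_shape
    return np.ascontiguousarray(gxp[:, pad:pad + D, pad:pad + H, pad:pad + Wd])


def conv3d_backward_weights(x: np.ndarray, gy: np.ndarray, k: int,
                            stride: int = 1, pad: int | None = None):
    """Gradients (gW, gb) of a conv with input ``x`` and output grad ``gy``."""
    cin, cout = x.shape[0], gy.shape[0]
    if pad is None:
        pad = k // 2
    gb = gy.sum(axis=(1, 2, 3)).astype(DTYPE)
    if k == 1 and stride == 1:
        gW = (gy.reshape(cout, -1) @ x.reshape(cin, -1).T).reshape(cout, cin, 1, 1, 1)
        return gW.astype(DTYPE), gb
    do, ho, wo = gy.shape[1:]
    xp = _pad_spatial(np.ascontiguousarray(x, dtype=DTYPE), pad)
    gWm = np.zeros((cout, cin * k**3), dtype=DTYPE)
    step = _slab_rows(do, ho * wo * cin * k**3)
    for d0 in range(0, do, step):
        d1 = min(d0 + step, do)
        cols = _im2col_slab(xp, k, stride, d0, d1, ho, wo)
        sl = gy[:, d0:d1].reshape(cout, -1)
        gWm += sl @ cols
    return gWm.astype(DTYPE).reshape(cout, cin, k, k, k), gb


# ---------------------------------------------------------------------------
# Trilinear x2 up-sampling (separable, replicate edges) and its exact adjoint


def _upsample2_axis(x: np.ndarray, axis: int) -> np.ndarray:
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    y = np.empty(x.shape[:-1] + (2 * n,), dtype=x.dtype)
    y[..., 0::2] = 0.75 * x + 0.25 * prev
    y[..., 1::2] = 0.75 * x + 0.25 * nxt
    return np.moveaxis(y, -1, axis)


def _upsample2_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    gx = (0.75 * (ge + go)).copy()
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., 0] += 0.25 * ge[..., 0]
    gx[..., 1:] += 0.25 * go[..., :-1]
    gx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(gx, -1, axis)


def upsample2_trilinear(x: np.ndarray) -> np.ndarray:
    """Double every spatial axis of ``(C, D, H, W)`` by linear interpolation."""
    for ax in (1, 2, 3):
        x = _upsample2_axis(x, ax)
    return np.ascontiguousarray(x, dtype=DTYPE)


def upsample2_trilinear_adjoint(g: np.ndarray) -> np.ndarray:
    for ax in (3, 2, 1):
        g = _upsample2_axis_adjoint(g, ax)
    return np.ascontiguousarray(g, dtype=DTYPE)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the class (first) axis."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return (e / e.sum(axis=0, keepdims=True)).astype(DTYPE)
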