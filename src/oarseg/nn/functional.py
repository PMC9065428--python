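"""Differentiable 3D network primitives.

All activations are channel-major arrays ``(C, X, Y, Z)`` (batch size is
always one).  Convolutions are stride-1 and zero-padded to preserve shape
("same"); down-sampling is a separate 2x2x2 max-pool; up-sampling is either
a stride-2 2x2x2 transpose convolution or trilinear interpolation.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .tape import Tensor

__all__ = [
    "conv3d",
    "conv_transpose3d",
    "max_pool3d",
    "upsample_trilinear2x",
    "instance_norm",
    "softmax_channels",
]


def _offsets(k: int):
    return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]


def _conv3d_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Stride-1 'same' convolution as one GEMM per kernel offset."""
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    sx, sy, sz = x.shape[1:]
    n = sx * sy * sz
    if k == 1:
        out = w.reshape(co, ci) @ x.reshape(ci, n)
    else:
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        out = np.zeros((co, n), dtype=x.dtype)
        wmat = w.reshape(co, ci, k**3)
        for i, (a, bb, c) in enumerate(_offsets(k)):
            xs = xp[:, a : a + sx, bb : bb + sy, c : c + sz].reshape(ci, n)
            out += wmat[:, :, i] @ xs
    if b is not None:
        out += b[:, None]
    return out.reshape(co, sx, sy, sz)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Zero-padded stride-1 convolution; kernel must be cubic with odd size.

    ``weight`` has shape ``(C_out, C_in, k, k, k)``, ``bias`` ``(C_out,)``.
    """
    co, ci, k = weight.shape[0], weight.shape[1], weight.shape[2]
    if x.shape[0] != ci:
        raise ValueError(f"input has {x.shape[0]} channels, kernel expects {ci}")
    out_data = _conv3d_raw(x.data, weight.data, None if bias is None else bias.data)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, parents=parents)
    sp = x.shape[1:]
    p = k // 2

    def bwd(g):
        gmat = g.reshape(co, -1)  # (Co, N)
        if weight.requires_grad:
            if k == 1:
                gw = (gmat @ x.data.reshape(ci, -1).T).reshape(co, ci, 1, 1, 1)
            else:
                sx, sy, sz = sp
                n = sx * sy * sz
                xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
                gw = np.empty((co, ci, k**3), dtype=g.dtype)
                for i, (a, bb, c) in enumerate(_offsets(k)):
                    xs = xp[:, a : a + sx, bb : bb + sy, c : c + sz].reshape(ci, n)
                    gw[:, :, i] = gmat @ xs.T
                gw = gw.reshape(co, ci, k, k, k)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=1))
        if x.requires_grad:
            # dX = conv(g, W swapped+flipped), same padding
            wT = np.ascontiguousarray(
                weight.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
            )
            x._accum(_conv3d_raw(g.reshape(co, *sp), wT, None))

    out._backward = bwd
    return out


def conv_transpose3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-2 transpose convolution with a 2x2x2 kernel (doubles each dim).

    ``weight`` has shape ``(C_in, C_out, 2, 2, 2)`` (torch convention).
    """
    ci, co = weight.shape[0], weight.shape[1]
    if x.shape[0] != ci:
        raise ValueError(f"input has {x.shape[0]} channels, kernel expects {ci}")
    X, Y, Z = x.shape[1:]
    # out[o, 2i+a, 2j+b, 2k+c] = sum_i w[i,o,a,b,c] * x[i, i,j,k]
    tmp = np.tensordot(weight.data, x.data, axes=([0], [0]))  # (Co,2,2,2,X,Y,Z)
    out_data = np.ascontiguousarray(
        tmp.transpose(0, 4, 1, 5, 2, 6, 3)
    ).reshape(co, 2 * X, 2 * Y, 2 * Z)
    if bias is not None:
        out_data += bias.data[:, None, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        g6 = g.reshape(co, X, 2, Y, 2, Z, 2).transpose(0, 2, 4, 6, 1, 3, 5)  # (Co,2,2,2,X,Y,Z)
        if weight.requires_grad:
            gw = np.tensordot(x.data, g6, axes=([1, 2, 3], [4, 5, 6]))  # (Ci,Co,2,2,2)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(1, 2, 3)))
        if x.requires_grad:
            gx = np.tensordot(weight.data, g6, axes=([1, 2, 3, 4], [0, 1, 2, 3]))
            x._accum(gx)

    out._backward = bwd
    return out


def max_pool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling; every spatial dim must be even."""
    c, X, Y, Z = x.shape
    if X % 2 or Y % 2 or Z % 2:
        raise ValueError(f"spatial dims must be even for 2x pooling, got {(X, Y, Z)}")
    blocks = np.ascontiguousarray(
        x.data.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2).transpose(0, 1, 3, 5, 2, 4, 6)
    ).reshape(c, X // 2, Y // 2, Z // 2, 8)
    idx = blocks.argmax(axis=-1)
    out = Tensor(np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def bwd(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gx = gb.reshape(c, X // 2, Y // 2, Z // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        x._accum(np.ascontiguousarray(gx).reshape(c, X, Y, Z))

    out._backward = bwd
    return out


@lru_cache(maxsize=None)
def _upsample_matrix(n_in: int) -> np.ndarray:
    """Dense (2*n_in, n_in) trilinear factor-2 interpolation matrix.

    Output centre ``i`` maps to input coordinate ``(i + 0.5)/2 - 0.5``
    (edge-clamped), matching the usual align_corners=False convention.
    """
    n_out = 2 * n_in
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[i, lo_c] += 1.0 - frac
        m[i, hi_c] += frac
    return m


def _apply_axis_matrix(data: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
    moved = np.moveaxis(data, axis, -1)
    out = moved @ m.T
    return np.moveaxis(out, -1, axis)


def upsample_trilinear2x(x: Tensor) -> Tensor:
    """Trilinear interpolation doubling every spatial dimension."""
    mats = [_upsample_matrix(n).astype(x.data.dtype) for n in x.shape[1:]]
    data = x.data
    for ax, m in enumerate(mats, start=1):
        data = _apply_axis_matrix(data, m, ax)
    out = Tensor(data, parents=(x,))

    def bwd(g):
        for ax, m in reversed(list(enumerate(mats, start=1))):
            g = _apply_axis_matrix(g, m.T, ax)
        x._accum(g)

    out._backward = bwd
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalisation over the spatial axes with affine rescale."""
    axes = (1, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gb = gamma.data[:, None, None, None]
    out = Tensor(xhat * gb + beta.data[:, None, None, None], parents=(x, gamma, beta))
    n = float(np.prod([x.shape[a] for a in axes]))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gh = g * gb
            gx = (
                gh
                - gh.mean(axis=axes, keepdims=True)
                - xhat * (gh * xhat).mean(axis=axes, keepdims=True)
            ) * inv
            x._accum(gx)

    out._backward = bwd
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax across the channel axis (axis 0), numerically stabilised."""
    z = x.data - x.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)
    out = Tensor(p, parents=(x,))

    def bwd(g):
        x._accum(p * (g - (g * p).sum(axis=0, keepdims=True)))

    out._backward = bwd
    return out
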