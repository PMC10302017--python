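"""N-dimensional convolution and friends, composed from autograd primitives.

Convolutions are lowered to a cached gather (im2col) followed by a single
2-D matmul; transposed convolutions are a zero-insertion scatter followed by
a convolution with the spatially flipped, in/out-swapped kernel.  Because
every step is an autograd primitive, all of these are twice differentiable.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    add,
    matmul,
    reshape,
    scatter_add,
    take,
    transpose,
)

_IDX_CACHE: dict = {}


def _tuplize(v, nd):
    if isinstance(v, (tuple, list)):
        if len(v) != nd:
            raise ValueError("parameter length mismatch")
        return tuple(int(x) for x in v)
    return (int(v),) * nd


def _pad_indices(shape, pads):
    """Flat indices of each element of ``shape`` inside the padded array."""
    padded = tuple(s + lo + hi for s, (lo, hi) in zip(shape, pads))
    key = ("pad", shape, tuple(pads))
    if key not in _IDX_CACHE:
        grids = np.meshgrid(
            *[np.arange(s) + lo for s, (lo, _) in zip(shape, pads)], indexing="ij"
        )
        idx = np.ravel_multi_index(grids, padded)
        _IDX_CACHE[key] = idx.astype(np.int32)
    return _IDX_CACHE[key], padded


def pad_zeros(x: Tensor, pads) -> Tensor:
    """Zero-pad; ``pads`` is a per-axis sequence of (low, high)."""
    pads = tuple(tuple(p) for p in pads)
    if all(p == (0, 0) for p in pads):
        return x
    idx, padded = _pad_indices(x.shape, pads)
    return reshape(scatter_add(x, idx, int(np.prod(padded))), padded)


def _im2col_indices(xshape, kernel, stride, nd):
    """Gather indices turning (N,C,*sp) into (C*K, N*L) patch columns."""
    key = ("col", xshape, kernel, stride)
    if key in _IDX_CACHE:
        return _IDX_CACHE[key]
    N, C = xshape[0], xshape[1]
    sp = xshape[2:]
    out_sp = tuple((s - k) // st + 1 for s, k, st in zip(sp, kernel, stride))
    # offsets within a patch: (C, *kernel)
    kgrids = np.meshgrid(np.arange(C), *[np.arange(k) for k in kernel], indexing="ij")
    patch = np.ravel_multi_index(kgrids, (C,) + sp)  # treats kernel offsets in x strides
    patch = patch.reshape(-1)  # (C*K,)
    # top-left corner of each output position: (*out_sp,)
    ogrids = np.meshgrid(*[np.arange(o) * st for o, st in zip(out_sp, stride)], indexing="ij")
    corner = np.ravel_multi_index([g for g in ogrids], sp)
    corner = corner.reshape(-1)  # (L,)
    base = patch[:, None] + corner[None, :]  # (C*K, L)
    csize = C * int(np.prod(sp))
    idx = (np.arange(N)[None, :, None] * csize + base[:, None, :]).reshape(
        base.shape[0], N * corner.size
    )
    out = (idx.astype(np.int32), out_sp)
    _IDX_CACHE[key] = out
    return out


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0) -> Tensor:
    """Cross-correlation of ``x`` (N,C,*sp) with ``w`` (O,C,*k)."""
    nd = x.ndim - 2
    stride = _tuplize(stride, nd)
    padding = _tuplize(padding, nd)
    O, C = w.shape[0], w.shape[1]
    kernel = tuple(w.shape[2:])
    if C != x.shape[1]:
        raise ValueError("channel mismatch between input and kernel")
    xp = pad_zeros(x, ((0, 0), (0, 0)) + tuple((p, p) for p in padding))
    idx, out_sp = _im2col_indices(xp.shape, kernel, stride, nd)
    cols = take(xp, idx)  # (C*K, N*L)
    w2 = reshape(w, (O, C * int(np.prod(kernel))))
    y = matmul(w2, cols)  # (O, N*L)
    N = x.shape[0]
    y = reshape(y, (O, N) + out_sp)
    y = transpose(y, (1, 0) + tuple(range(2, nd + 2)))
    if b is not None:
        y = add(y, reshape(b, (1, O) + (1,) * nd))
    return y


def _flip_swap_indices(wshape):
    """Indices realizing (O,C,*k) -> (C,O,*reversed k) as one gather."""
    key = ("flip", wshape)
    if key not in _IDX_CACHE:
        arr = np.arange(int(np.prod(wshape))).reshape(wshape)
        nd = len(wshape) - 2
        arr = np.swapaxes(arr, 0, 1)
        for ax in range(2, nd + 2):
            arr = np.flip(arr, axis=ax)
        _IDX_CACHE[key] = np.ascontiguousarray(arr)
    return _IDX_CACHE[key]


def _dilate_indices(xshape, stride, extra):
    """Indices of x elements inside the zero-inserted (dilated) array."""
    key = ("dil", xshape, stride, extra)
    if key in _IDX_CACHE:
        return _IDX_CACHE[key]
    sp = xshape[2:]
    dsp = tuple((s - 1) * st + 1 + e for s, st, e in zip(sp, stride, extra))
    full = xshape[:2] + dsp
    grids = np.meshgrid(
        np.arange(xshape[0]),
        np.arange(xshape[1]),
        *[np.arange(s) * st for s, st in zip(sp, stride)],
        indexing="ij",
    )
    idx = np.ravel_multi_index(grids, full).astype(np.int32)
    _IDX_CACHE[key] = (idx, full)
    return _IDX_CACHE[key]


def conv_transpose_nd(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0, output_padding=0
) -> Tensor:
    """Transposed convolution; ``w`` has shape (C_in, C_out, *k)."""
    nd = x.ndim - 2
    stride = _tuplize(stride, nd)
    padding = _tuplize(padding, nd)
    output_padding = _tuplize(output_padding, nd)
    kernel = tuple(w.shape[2:])
    idx, full = _dilate_indices(x.shape, stride, output_padding)
    xd = reshape(scatter_add(x, idx, int(np.prod(full))), full)
    wf = reshape(take(w, _flip_swap_indices(w.shape)), _flip_swap_indices(w.shape).shape)
    pads = tuple(k - 1 - p for k, p in zip(kernel, padding))
    return conv_nd(xd, wf, b=b, stride=1, padding=pads)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """(N, C*r^2, H, W) -> (N, C, r*H, r*W)."""
    N, Cr, H, W = x.shape
    C = Cr // (r * r)
    if C * r * r != Cr:
        raise ValueError("channels not divisible by r^2")
    y = reshape(x, (N, C, r, r, H, W))
    y = transpose(y, (0, 1, 4, 2, 5, 3))
    return reshape(y, (N, C, H * r, W * r))


def upsample_nearest(x: Tensor, r: int) -> Tensor:
    nd = x.ndim - 2
    key = ("ups", x.shape, r)
    if key not in _IDX_CACHE:
        sp = x.shape[2:]
        grids = np.meshgrid(
            np.arange(x.shape[0]),
            np.arange(x.shape[1]),
            *[np.arange(s * r) // r for s in sp],
            indexing="ij",
        )
        _IDX_CACHE[key] = np.ravel_multi_index(grids, x.shape).astype(np.int32)
    return take(x, _IDX_CACHE[key])
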