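"""Differentiable image operations in channels-last (NHWC) layout.

Convolutions are evaluated tap by tap: for each of the kh*kw kernel taps a
contiguous spatial slice of the padded input is multiplied with that tap's
(in_ch, out_ch) weight matrix and accumulated.  This keeps both passes
BLAS-bound with cache-friendly copies, which matters on a single CPU.

Weights are stored as (kh, kw, in_ch, out_ch); activations as (N, H, W, C).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .autograd import Tensor, _DTYPE, as_tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "max_unpool2d",
    "batch_norm2d",
    "concat",
    "spatial_mean",
    "spatial_max",
    "channel_mean",
    "channel_max",
    "bce_with_logits",
    "mse",
]


def _pad_hw(x: np.ndarray, padding: int) -> np.ndarray:
    if not padding:
        return x
    return np.pad(x, ((0, 0), (padding, padding), (padding, padding), (0, 0)))


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation; ``weight`` has shape (kh, kw, in_ch, out_ch)."""
    n, h, w, c = x.shape
    kh, kw, ci, o = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {ci}")
    span_h = dilation * (kh - 1) + 1
    span_w = dilation * (kw - 1) + 1
    ho = (h + 2 * padding - span_h) // stride + 1
    wo = (w + 2 * padding - span_w) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"input {h}x{w} too small for this convolution")
    xp = _pad_hw(x.data, padding)

    def tap_slice(arr: np.ndarray, i: int, j: int) -> np.ndarray:
        return arr[:,
                   i * dilation: i * dilation + (ho - 1) * stride + 1: stride,
                   j * dilation: j * dilation + (wo - 1) * stride + 1: stride, :]

    m = n * ho * wo
    out = np.zeros((m, o), dtype=_DTYPE)
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(tap_slice(xp, i, j)).reshape(m, c)
            out += xs @ weight.data[i, j]
    if bias is not None:
        out += bias.data
    out = out.reshape(n, ho, wo, o)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g: np.ndarray):
        g2 = g.reshape(m, o)
        grad_w = np.empty_like(weight.data) if weight.requires_grad else None
        grad_x = None
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                if grad_w is not None:
                    xs = np.ascontiguousarray(tap_slice(xp, i, j)).reshape(m, c)
                    grad_w[i, j] = xs.T @ g2
                if dxp is not None:
                    tap_slice(dxp, i, j)[...] += (g2 @ weight.data[i, j].T
                                                  ).reshape(n, ho, wo, c)
        if dxp is not None:
            grad_x = dxp[:, padding: padding + h, padding: padding + w, :] \
                if padding else dxp
        grad_b = g2.sum(axis=0) if bias is not None and bias.requires_grad else None
        if bias is None:
            return grad_x, grad_w
        return grad_x, grad_w, grad_b

    return Tensor(out, _parents=parents, _backward=backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Transposed convolution; ``weight`` has shape (kh, kw, in_ch, out_ch)."""
    n, h, w, c = x.shape
    kh, kw, ci, o = weight.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {ci}")
    ho = (h - 1) * stride - 2 * padding + kh
    wo = (w - 1) * stride - 2 * padding + kw
    m = n * h * w
    x2 = x.data.reshape(m, c)
    canvas = np.zeros((n, ho + 2 * padding, wo + 2 * padding, o), dtype=_DTYPE)

    def tap_slice(arr: np.ndarray, i: int, j: int) -> np.ndarray:
        return arr[:, i: i + (h - 1) * stride + 1: stride,
                   j: j + (w - 1) * stride + 1: stride, :]

    for i in range(kh):
        for j in range(kw):
            tap_slice(canvas, i, j)[...] += (x2 @ weight.data[i, j]
                                             ).reshape(n, h, w, o)
    out = canvas[:, padding: padding + ho, padding: padding + wo, :]
    if bias is not None:
        out = out + bias.data

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g: np.ndarray):
        gp = _pad_hw(g, padding)
        grad_x = np.zeros((m, c), dtype=_DTYPE) if x.requires_grad else None
        grad_w = np.empty_like(weight.data) if weight.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                gs = np.ascontiguousarray(tap_slice(gp, i, j)).reshape(m, o)
                if grad_x is not None:
                    grad_x += gs @ weight.data[i, j].T
                if grad_w is not None:
                    grad_w[i, j] = x2.T @ gs
        if grad_x is not None:
            grad_x = grad_x.reshape(n, h, w, c)
        grad_b = g.sum(axis=(0, 1, 2)) if bias is not None and bias.requires_grad else None
        if bias is None:
            return grad_x, grad_w
        return grad_x, grad_w, grad_b

    return Tensor(out, _parents=parents, _backward=backward)


def max_pool2d(x: Tensor, kernel: int = 2) -> Tuple[Tensor, np.ndarray]:
    """Non-overlapping max pooling; returns (pooled, flat argmax indices).

    Indices address the flattened H*W spatial plane of the input per
    (sample, channel), which is what :func:`max_unpool2d` needs to restore
    each maximum to its origin.
    """
    n, h, w, c = x.shape
    if h % kernel or w % kernel:
        raise ValueError(f"spatial size {h}x{w} not divisible by pool kernel {kernel}")
    ho, wo = h // kernel, w // kernel
    win = x.data.reshape(n, ho, kernel, wo, kernel, c)
    win = win.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, kernel * kernel)
    local = win.argmax(axis=-1)
    rows = (local // kernel) + np.arange(ho)[None, :, None, None] * kernel
    cols = (local % kernel) + np.arange(wo)[None, None, :, None] * kernel
    flat_idx = (rows * w + cols).reshape(n, ho * wo, c)
    pooled = np.take_along_axis(x.data.reshape(n, h * w, c), flat_idx, axis=1)

    def backward(g: np.ndarray):
        dx = np.zeros((n, h * w, c), dtype=_DTYPE)
        np.put_along_axis(dx, flat_idx, g.reshape(n, ho * wo, c), axis=1)
        return (dx.reshape(n, h, w, c),)

    out = Tensor(pooled.reshape(n, ho, wo, c), _parents=(x,), _backward=backward)
    return out, flat_idx.reshape(n, ho, wo, c)


def max_unpool2d(x: Tensor, indices: np.ndarray, output_size: Tuple[int, int]) -> Tensor:
    """Place each value at its stored argmax position; zeros elsewhere."""
    n, h, w, c = x.shape
    oh, ow = output_size
    idx = indices.reshape(n, h * w, c)

    def backward(g: np.ndarray):
        gathered = np.take_along_axis(g.reshape(n, oh * ow, c), idx, axis=1)
        return (gathered.reshape(n, h, w, c).astype(_DTYPE),)

    out = np.zeros((n, oh * ow, c), dtype=_DTYPE)
    np.put_along_axis(out, idx, x.data.reshape(n, h * w, c), axis=1)
    return Tensor(out.reshape(n, oh, ow, c), _parents=(x,), _backward=backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation; updates running stats in place."""
    n, h, w, c = x.shape
    if training:
        mean = x.data.mean(axis=(0, 1, 2))
        var = x.data.var(axis=(0, 1, 2))
        m = n * h * w
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        # unbiased running variance, biased batch variance in the normaliser
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mean, var = running_mean, running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(_DTYPE)
    xhat = (x.data - mean) * inv_std
    out = gamma.data * xhat + beta.data

    def backward(g: np.ndarray):
        grad_gamma = (g * xhat).sum(axis=(0, 1, 2)) if gamma.requires_grad else None
        grad_beta = g.sum(axis=(0, 1, 2)) if beta.requires_grad else None
        grad_x = None
        if x.requires_grad:
            dxhat = g * gamma.data
            if training:
                m = n * h * w
                s1 = dxhat.sum(axis=(0, 1, 2))
                s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
                grad_x = ((dxhat - s1 / m - xhat * (s2 / m)) * inv_std).astype(_DTYPE)
            else:
                grad_x = dxhat * inv_std
        return grad_x, grad_gamma, grad_beta

    return Tensor(out, _parents=(x, gamma, beta), _backward=backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray):
        return tuple(np.ascontiguousarray(p) for p in np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=backward)


def spatial_mean(x: Tensor) -> Tensor:
    """Global average pool over H, W (keepdims)."""
    return x.mean(axis=(1, 2), keepdims=True)


def spatial_max(x: Tensor) -> Tensor:
    """Global max pool over H, W (keepdims)."""
    n, h, w, c = x.shape
    flat = x.data.reshape(n, h * w, c)
    idx = flat.argmax(axis=1)[:, None, :]
    out = np.take_along_axis(flat, idx, axis=1)

    def backward(g: np.ndarray):
        dx = np.zeros_like(flat)
        np.put_along_axis(dx, idx, g.reshape(n, 1, c), axis=1)
        return (dx.reshape(x.shape),)

    return Tensor(out.reshape(n, 1, 1, c), _parents=(x,), _backward=backward)


def channel_mean(x: Tensor) -> Tensor:
    return x.mean(axis=-1, keepdims=True)


def channel_max(x: Tensor) -> Tensor:
    idx = x.data.argmax(axis=-1)[..., None]
    out = np.take_along_axis(x.data, idx, axis=-1)

    def backward(g: np.ndarray):
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, idx, g, axis=-1)
        return (dx,)

    return Tensor(out, _parents=(x,), _backward=backward)


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on raw scores."""
    z = logits.data
    t = np.asarray(target, dtype=_DTYPE)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

    def backward(g: np.ndarray):
        s = 1.0 / (1.0 + np.exp(-z))
        return (g * (s - t) / z.size,)

    return Tensor(loss.mean(), _parents=(logits,), _backward=backward)


def mse(prediction: Tensor, target) -> Tensor:
    """Mean squared error between two batches (target is constant)."""
    target = as_tensor(target)
    if prediction.shape != target.shape:
        raise ValueError(
            f"shape mismatch: {prediction.shape} vs {target.shape}")
    diff = prediction.data - target.data

    def backward(g: np.ndarray):
        return (g * 2.0 * diff / diff.size,)

    return Tensor(np.mean(diff ** 2), _parents=(prediction,), _backward=backward)
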