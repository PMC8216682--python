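"""Low-level convolution / transposed-convolution kernels with backprop.

Tensors are channels-last float64, shape (batch, H, W, channels): with the
channel axis innermost the window-gather and scatter-add loops touch
contiguous runs, which is what makes the pure-numpy training loop fast
enough.  Kernels are stored (out_channels, in_channels, k, k) at the API
surface and re-laid-out internally per call (the kernels are tiny).

Convolution is cross-correlation (the CNN convention).  The transposed
convolution ("deconvolution") follows the output-size rule
stride*(in - 1) + kernel - 2*padding: zero-interleaved scatter followed by a
symmetric crop of ``padding`` pixels per side.  Every gradient is pinned by
a central finite-difference test.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GeometryError",
    "conv2d_forward",
    "conv2d_backward",
    "deconv2d_forward",
    "deconv2d_backward",
    "prelu_forward",
    "prelu_backward",
]


class GeometryError(ValueError):
    """A stage produced a non-positive spatial size."""


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if not pad:
        return x
    b, h, w, c = x.shape
    out = np.zeros((b, h + 2 * pad, w + 2 * pad, c), dtype=x.dtype)
    out[:, pad:-pad, pad:-pad, :] = x
    return out


def _window_cols(x: np.ndarray, k: int, stride: int):
    """(B, H, W, C) -> contiguous (B, L, k*k*C) patch matrix + (oh, ow)."""
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    b, oh, ow = win.shape[:3]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(b, oh * ow, k * k * x.shape[3])
    return np.ascontiguousarray(cols), (oh, ow)


def conv2d_forward(x, weight, bias, padding: int, stride: int = 1):
    """y = x (*) weight + bias.  x: (B, H, W, I); weight: (O, I, k, k)."""
    o, i, k, _ = weight.shape
    x_p = _pad_hw(x, padding)
    if x_p.shape[1] < k or x_p.shape[2] < k:
        raise GeometryError(f"convolution input {x_p.shape[1:3]} smaller than kernel {k}")
    cols, (oh, ow) = _window_cols(x_p, k, stride)
    w_mat = weight.transpose(2, 3, 1, 0).reshape(k * k * i, o)
    y = cols @ w_mat
    y += bias
    y = y.reshape(x.shape[0], oh, ow, o)
    cache = (cols, x.shape, padding, stride, oh, ow)
    return y, cache


def conv2d_backward(gy, weight, cache, need_input_grad: bool = True):
    """Gradients of a conv2d_forward call. Returns (gx, gW, gb); gx is None
    when ``need_input_grad`` is False (first network stage)."""
    cols, x_shape, padding, stride, oh, ow = cache
    o, i, k, _ = weight.shape
    b, h, w, _ = x_shape
    g = gy.reshape(b, oh * ow, o)
    g_w = np.tensordot(cols, g, axes=([0, 1], [0, 1]))  # (k*k*I, O)
    g_w = g_w.reshape(k, k, i, o).transpose(3, 2, 0, 1)
    g_b = g.sum(axis=(0, 1))
    if not need_input_grad:
        return None, g_w, g_b
    w_mat = weight.transpose(2, 3, 1, 0).reshape(k * k * i, o).astype(gy.dtype, copy=False)
    g_cols = (g @ w_mat.T).reshape(b, oh, ow, k, k, i)
    g_xp = np.zeros((b, h + 2 * padding, w + 2 * padding, i), dtype=gy.dtype)
    for di in range(k):
        for dj in range(k):
            g_xp[:, di : di + (oh - 1) * stride + 1 : stride,
                 dj : dj + (ow - 1) * stride + 1 : stride, :] += g_cols[:, :, :, di, dj, :]
    g_x = g_xp[:, padding : padding + h, padding : padding + w, :]
    return g_x, g_w, g_b


def deconv2d_forward(x, weight, bias, padding: int, stride: int):
    """Transposed convolution.  x: (B, h, w, I); weight: (O, I, k, k);
    output size per axis is stride*(in - 1) + k - 2*padding."""
    b, h, w, i = x.shape
    o, i2, k, _ = weight.shape
    if i2 != i:
        raise ValueError(f"channel mismatch: input {i}, kernel expects {i2}")
    out_h = stride * (h - 1) + k - 2 * padding
    out_w = stride * (w - 1) + k - 2 * padding
    if out_h <= 0 or out_w <= 0:
        raise GeometryError(f"deconvolution output size {out_h}x{out_w} is non-positive")
    w_mat = weight.transpose(1, 2, 3, 0).reshape(i, k * k * o)
    tmp = (x.reshape(b * h * w, i) @ w_mat).reshape(b, h, w, k, k, o)
    full = np.zeros((b, stride * (h - 1) + k, stride * (w - 1) + k, o), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            full[:, di : di + (h - 1) * stride + 1 : stride,
                 dj : dj + (w - 1) * stride + 1 : stride, :] += tmp[:, :, :, di, dj, :]
    y = full[:, padding : padding + out_h, padding : padding + out_w, :]
    if padding:
        y = y.copy()
    y += bias
    cache = (x, padding, stride)
    return y, cache


def deconv2d_backward(gy, weight, cache):
    """Gradients of deconv2d_forward. Returns (gx, gW, gb)."""
    x, padding, stride = cache
    b, h, w, i = x.shape
    o, _, k, _ = weight.shape
    g_full = _pad_hw(gy, padding)
    cols_g, (oh, ow) = _window_cols(g_full, k, stride)  # (B, h*w, k*k*O)
    w_mat = weight.transpose(2, 3, 0, 1).reshape(k * k * o, i)
    g_x = (cols_g @ w_mat).reshape(b, h, w, i)
    g_w = np.tensordot(x.reshape(b * h * w, i), cols_g.reshape(b * h * w, k * k * o),
                       axes=(0, 0))  # (I, k*k*O)
    g_w = g_w.reshape(i, k, k, o).transpose(3, 0, 1, 2)
    g_b = gy.sum(axis=(0, 1, 2))
    return g_x, g_w, g_b


def prelu_forward(z, alpha):
    """PReLU max(0,z) + alpha*min(0,z); alpha per channel, shape (C,)."""
    y = np.where(z > 0.0, z, alpha * z)
    return y, z


def prelu_backward(gy, z, alpha):
    """Returns (gz, galpha)."""
    neg = z < 0.0
    gz = np.where(neg, alpha * gy, gy)
    ga = np.where(neg, gy * z, 0.0).sum(axis=(0, 1, 2))
    return gz, ga
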