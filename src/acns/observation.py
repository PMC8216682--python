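"""Degradation (observation) model and baseline upsamplers.

The low-resolution observation is modelled as anti-aliased bicubic
downsampling of the high-resolution image, Y = D_f X.  The bicubic kernel is
the classic 4-tap Keys kernel with a = -0.5; on downscale the kernel support
is stretched by the scale factor (anti-aliasing), the convention of the
standard imaging-toolbox ``imresize``.  All operators are deterministic,
float64, and preserve constants exactly up to round-off.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

from .grid import ImageGrid, as_values

__all__ = [
    "bicubic_resize",
    "bicubic_downsample",
    "blur3x3_nn_downsample",
    "downsample_residual",
    "baseline_upsample",
    "crop_to_multiple",
]


def _cubic(x: np.ndarray) -> np.ndarray:
    # Keys bicubic kernel, a = -0.5
    ax = np.abs(x)
    ax2 = ax * ax
    ax3 = ax2 * ax
    out = np.where(ax <= 1.0, 1.5 * ax3 - 2.5 * ax2 + 1.0, 0.0)
    mid = (ax > 1.0) & (ax < 2.0)
    out = np.where(mid, -0.5 * ax3 + 2.5 * ax2 - 4.0 * ax + 2.0, out)
    return out


def _resize_weights(in_size: int, out_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-output-pixel source indices and weights for one axis.

    Uses the half-pixel-centre mapping u = (i + 0.5)/scale - 0.5 and, when
    downscaling, stretches the kernel by 1/scale (anti-aliasing). Border
    samples are clamped (replicate) and weights renormalized to sum to 1, so
    constants are reproduced exactly.
    """
    scale = out_size / in_size
    i = np.arange(out_size, dtype=np.float64)
    u = (i + 0.5) / scale - 0.5
    kscale = min(scale, 1.0)  # kernel stretch on downscale only
    support = 2.0 / kscale
    left = np.floor(u - support).astype(np.int64) + 1
    n_taps = int(np.ceil(2 * support)) + 2
    idx = left[:, None] + np.arange(n_taps)[None, :]
    w = _cubic((u[:, None] - idx) * kscale) * kscale
    w /= w.sum(axis=1, keepdims=True)
    idx = np.clip(idx, 0, in_size - 1)
    return idx, w


def bicubic_resize(values: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Separable bicubic resize (anti-aliased on downscale) of a 2-D array."""
    values = np.asarray(values, dtype=np.float64)
    out_h, out_w = out_shape
    if values.shape == (out_h, out_w):
        return values.copy()
    idx_r, w_r = _resize_weights(values.shape[0], out_h)
    idx_c, w_c = _resize_weights(values.shape[1], out_w)
    tmp = np.einsum("ok,okw->ow", w_r, values[idx_r, :], optimize=True)
    out = np.einsum("ok,hok->ho", w_c, tmp[:, idx_c], optimize=True)
    return out


def crop_to_multiple(values: np.ndarray, f: int) -> np.ndarray:
    """Centre-crop so both dimensions are divisible by f."""
    h, w = values.shape
    nh, nw = (h // f) * f, (w // f) * f
    if nh == 0 or nw == 0:
        raise ValueError(f"image {values.shape} too small for scale {f}")
    r0, c0 = (h - nh) // 2, (w - nw) // 2
    return values[r0 : r0 + nh, c0 : c0 + nw]


def bicubic_downsample(image, scale: int):
    """LR observation Y = D_f X: anti-aliased bicubic decimation by ``scale``.

    Dimensions not divisible by ``scale`` are centre-cropped to the nearest
    multiple first. ``scale`` = 1 is the identity.
    """
    if scale < 1:
        raise ValueError(f"scale factor must be >= 1, got {scale}")
    x = as_values(image)
    x = crop_to_multiple(x, scale)
    out = bicubic_resize(x, (x.shape[0] // scale, x.shape[1] // scale))
    if isinstance(image, ImageGrid):
        return image.with_values(out)
    return out


def blur3x3_nn_downsample(image):
    """Surrogate degradation: 3x3 mean filter (replicate borders), then keep
    every 2nd pixel starting at index 0.  Requires even dimensions."""
    x = as_values(image)
    if x.shape[0] % 2 or x.shape[1] % 2:
        raise ValueError(f"even dimensions required, got {x.shape}")
    blurred = uniform_filter(x, size=3, mode="nearest")
    out = blurred[::2, ::2]
    if isinstance(image, ImageGrid):
        return image.with_values(out)
    return out


def downsample_residual(z, y, scale: int):
    """Degradation residual Y - D_f Z (un-quantized)."""
    zv, yv = as_values(z), as_values(y)
    if (zv.shape[0] != yv.shape[0] * scale) or (zv.shape[1] != yv.shape[1] * scale):
        raise ValueError(
            f"dimension mismatch: z {zv.shape} is not {scale}x the size of y {yv.shape}"
        )
    res = yv - as_values(bicubic_downsample(zv, scale))
    if isinstance(y, ImageGrid):
        return y.with_values(res)
    return res


def baseline_upsample(image, scale: int, method: str = "bicubic"):
    """Baseline enlargement by ``scale``: pixel-replicating nearest neighbour
    or bicubic interpolation (same kernel as the downsampler)."""
    if scale < 1:
        raise ValueError(f"scale factor must be >= 1, got {scale}")
    x = as_values(image)
    if method == "nearest":
        out = np.repeat(np.repeat(x, scale, axis=0), scale, axis=1)
    elif method == "bicubic":
        out = bicubic_resize(x, (x.shape[0] * scale, x.shape[1] * scale))
    else:
        raise ValueError(f"unknown upsampling method {method!r}")
    if isinstance(image, ImageGrid):
        return image.with_values(out)
    return out
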