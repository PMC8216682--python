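"""Aligned LR/HR training patch pairs.

LR patches of ``lr_patch`` (default 11) pixels are tiled over the degraded
image with a fixed stride; each HR target is the centre crop, of the size
implied by the network geometry, of the f*lr_patch region obtained by
scaling the LR origin.  LR patches are cut from the *whole* degraded image
(not degraded per patch) so patch borders see the same anti-aliasing as
inference inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import NetworkSpec, validate_spec
from .grid import ImageGrid, as_values
from .observation import bicubic_downsample, crop_to_multiple

__all__ = ["PatchPairSet", "count_patches", "extract_pairs", "assemble_training_set"]

DEFAULT_LR_PATCH = 11
DEFAULT_STRIDE = 4


@dataclass
class PatchPairSet:
    """Aligned LR/HR patches with provenance.

    lr : (P, s, s) float64, intensity units
    hr : (P, h, h) float64, h = f*(s - w1) + w_out - 2p
    origins : (P, 2) LR top-left (row, col), 0-based
    source_ids : (P,) index of the source image
    """

    lr: np.ndarray
    hr: np.ndarray
    origins: np.ndarray
    source_ids: np.ndarray
    scale: int
    max_intensity: float = 255.0

    def __post_init__(self) -> None:
        n = len(self.lr)
        if not (len(self.hr) == len(self.origins) == len(self.source_ids) == n):
            raise ValueError("patch-pair arrays must have equal lengths")

    def __len__(self) -> int:
        return len(self.lr)


def count_patches(image_size: int, patch: int, stride: int) -> int:
    """Sliding-window patch count on a square image:
    (floor((size - patch)/stride) + 1)^2; 0 when the patch does not fit."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if patch > image_size:
        return 0
    per_axis = (image_size - patch) // stride + 1
    return per_axis * per_axis


def _axis_origins(size: int, patch: int, stride: int) -> np.ndarray:
    if patch > size:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, size - patch + 1, stride, dtype=np.int64)


def extract_pairs(
    hr,
    spec: NetworkSpec,
    stride: int = DEFAULT_STRIDE,
    lr_patch: int = DEFAULT_LR_PATCH,
    source_id: int = 0,
) -> PatchPairSet:
    """Degrade one HR image and tile aligned LR/HR patch pairs."""
    report = validate_spec(spec, lr_patch)
    if not report.passed:
        raise ValueError(f"network spec fails the design conditions:\n{report}")
    f = spec.scale
    hr_values = crop_to_multiple(as_values(hr), f)
    lr_values = as_values(bicubic_downsample(hr_values, f))
    h = report.hr_patch
    offset = (f * lr_patch - h) // 2  # centre alignment within the scaled region

    rows = _axis_origins(lr_values.shape[0], lr_patch, stride)
    cols = _axis_origins(lr_values.shape[1], lr_patch, stride)
    if rows.size == 0 or cols.size == 0:
        raise ValueError(
            f"image too small: LR {lr_values.shape} yields no {lr_patch}-pixel patches"
        )
    lr_list, hr_list, origins = [], [], []
    for r in rows:
        for c in cols:
            lr_list.append(lr_values[r : r + lr_patch, c : c + lr_patch])
            hr_r, hr_c = f * r + offset, f * c + offset
            hr_list.append(hr_values[hr_r : hr_r + h, hr_c : hr_c + h])
            origins.append((r, c))
    max_i = hr.max_intensity if isinstance(hr, ImageGrid) else 255.0
    n = len(lr_list)
    return PatchPairSet(
        lr=np.stack(lr_list),
        hr=np.stack(hr_list),
        origins=np.asarray(origins, dtype=np.int64),
        source_ids=np.full(n, source_id, dtype=np.int64),
        scale=f,
        max_intensity=max_i,
    )


def assemble_training_set(
    images,
    spec: NetworkSpec,
    shuffle_seed: int,
    stride: int = DEFAULT_STRIDE,
    lr_patch: int = DEFAULT_LR_PATCH,
) -> PatchPairSet:
    """Concatenate per-image pairs and shuffle deterministically by seed."""
    images = list(images)
    if not images:
        raise ValueError("empty image list")
    parts = [
        extract_pairs(img, spec, stride=stride, lr_patch=lr_patch, source_id=i)
        for i, img in enumerate(images)
    ]
    lr = np.concatenate([p.lr for p in parts])
    hr = np.concatenate([p.hr for p in parts])
    origins = np.concatenate([p.origins for p in parts])
    source_ids = np.concatenate([p.source_ids for p in parts])
    perm = np.random.default_rng(shuffle_seed).permutation(len(lr))
    return PatchPairSet(
        lr=lr[perm],
        hr=hr[perm],
        origins=origins[perm],
        source_ids=source_ids[perm],
        scale=spec.scale,
        max_intensity=parts[0].max_intensity,
    )
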