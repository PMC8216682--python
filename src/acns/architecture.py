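"""Network architecture: specification, validity algebra, plans, forward pass.

The super-resolution network has three stages: feature extraction (a single
w1 x w1 convolution to N_feature channels), n recursions of 3x3 nonlinear
mapping at N_map channels (plus one expansion back to N_feature channels),
and a single transposed-convolution reconstruction stage with kernel w_out,
zero-padding p and stride equal to the scale factor f.  Every convolution is
followed by a per-channel PReLU except the reconstruction stage.

A candidate (w1, w_out, p) is admissible for a given LR training-patch size
only if four geometric conditions hold; they guarantee the reconstruction
output is at least the LR patch and at most f times it, so aligned LR/HR
patch pairs exist.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import (
    GeometryError,
    conv2d_forward,
    deconv2d_forward,
    prelu_forward,
)
from .grid import ImageGrid, as_values

__all__ = [
    "NetworkSpec",
    "LayerStage",
    "LayerPlan",
    "StageParams",
    "ParameterSet",
    "ValidationReport",
    "GeometryError",
    "conv_output_size",
    "deconv_output_size",
    "validate_spec",
    "build_layer_plan",
    "count_weights",
    "reference_plan",
    "enumerate_valid_specs",
    "forward",
    "upscale",
    "parse_spec_string",
]

MAPPING_KERNEL = 3  # 3x3 mapping kernels with 1-pixel zero padding keep size
MAPPING_PAD = 1


@dataclass(frozen=True)
class NetworkSpec:
    """The six tunable hyperparameters plus the scale factor.

    n_feature : filters in feature extraction (and the expansion stage)
    n_map     : filters in each nonlinear-mapping recursion
    w1        : feature-extraction kernel edge (odd)
    w_out     : reconstruction (deconvolution) kernel edge (odd)
    p         : reconstruction zero-padding
    n         : number of nonlinear-mapping recursions
    scale     : scaling factor f
    """

    n_feature: int
    n_map: int
    w1: int
    w_out: int
    p: int
    n: int
    scale: int = 2

    def __post_init__(self) -> None:
        for name in ("n_feature", "n_map", "w1", "w_out", "n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.w1 % 2 == 0 or self.w_out % 2 == 0:
            raise ValueError("w1 and w_out must be odd")
        if self.p < 0:
            raise ValueError("padding p must be >= 0")
        if self.scale < 1:
            raise ValueError("scale factor must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        known = {f: d[f] for f in ("n_feature", "n_map", "w1", "w_out", "p", "n")}
        known["scale"] = d.get("scale", d.get("f", 2))
        extra = set(d) - set(known) - {"f"}
        if extra:
            raise ValueError(f"unknown NetworkSpec keys: {sorted(extra)}")
        return cls(**known)

    def __str__(self) -> str:
        return (
            f"ACNS({self.n_feature},{self.n_map},{self.w1},"
            f"{self.w_out},{self.p},{self.n})"
        )


def parse_spec_string(text: str, scale: int = 2) -> NetworkSpec:
    """Parse the compact notation "ACNS(N_feature,N_map,w1,w_out,p,n)"."""
    m = re.match(r"^\s*ACNS\(([\d\s,]+)\)\s*$", text)
    if not m:
        raise ValueError(f"cannot parse network spec string {text!r}")
    parts = [int(tok) for tok in m.group(1).split(",")]
    if len(parts) != 6:
        raise ValueError(f"expected 6 comma-separated integers in {text!r}")
    return NetworkSpec(*parts, scale=scale)


# ---------------------------------------------------------------------------
# size algebra


def conv_output_size(in_size: int, kernel: int, padding: int, stride: int = 1) -> int:
    """(in - kernel + 2*padding) // stride + 1 (floor division)."""
    if min(in_size, kernel) < 0 or padding < 0 or stride < 1:
        raise ValueError("sizes must be non-negative and stride >= 1")
    if in_size + 2 * padding < kernel:
        raise GeometryError(
            f"convolution input {in_size}+2*{padding} smaller than kernel {kernel}"
        )
    out = (in_size - kernel + 2 * padding) // stride + 1
    if out <= 0:
        raise GeometryError(f"convolution output size {out} is non-positive")
    return out


def deconv_output_size(in_size: int, kernel: int, padding: int, stride: int) -> int:
    """stride*(in - 1) + kernel - 2*padding."""
    if in_size < 1 or stride < 1:
        raise ValueError("in_size and stride must be >= 1")
    out = stride * (in_size - 1) + kernel - 2 * padding
    if out <= 0:
        raise GeometryError(f"deconvolution output size {out} is non-positive")
    return out


# ---------------------------------------------------------------------------
# validity conditions


@dataclass
class ConditionResult:
    index: int
    passed: bool
    statement: str


@dataclass
class ValidationReport:
    conditions: list[ConditionResult]
    passed: bool
    hr_patch: int | None  # implied HR patch size when all conditions pass

    def __str__(self) -> str:
        lines = [
            f"Condition{c.index}: {'PASS' if c.passed else 'FAIL'}  ({c.statement})"
            for c in self.conditions
        ]
        lines.append(f"overall: {'PASS' if self.passed else 'FAIL'}")
        if self.hr_patch is not None:
            lines.append(f"implied HR patch size: {self.hr_patch}")
        return "\n".join(lines)


def validate_spec(spec: NetworkSpec, lr_patch: int) -> ValidationReport:
    """Evaluate the four admissibility conditions for a training-patch size.

    1. w1 < lr_patch
    2. 2p < f*(lr_patch - w1)
    3. p < w_out
    4. lr_patch <= f*(lr_patch - w1) + w_out - 2p <= f*lr_patch + (lr_patch mod 2)
    """
    if lr_patch < 2:
        raise ValueError(f"lr_patch must be >= 2, got {lr_patch}")
    f, w1, w_out, p = spec.scale, spec.w1, spec.w_out, spec.p
    hr = f * (lr_patch - w1) + w_out - 2 * p
    conds = [
        ConditionResult(1, w1 < lr_patch, f"w1={w1} < lr_patch={lr_patch}"),
        ConditionResult(
            2, 2 * p < f * (lr_patch - w1), f"2p={2 * p} < f*(lr_patch-w1)={f * (lr_patch - w1)}"
        ),
        ConditionResult(3, p < w_out, f"p={p} < w_out={w_out}"),
        ConditionResult(
            4,
            lr_patch <= hr <= f * lr_patch + (lr_patch % 2),
            f"{lr_patch} <= f*(lr_patch-w1)+w_out-2p={hr} <= {f * lr_patch + lr_patch % 2}",
        ),
    ]
    passed = all(c.passed for c in conds)
    return ValidationReport(conds, passed, hr if passed else None)


def enumerate_valid_specs(
    lr_patch: int,
    scale: int,
    w1_candidates=(1, 3, 5, 7, 9),
    w_out_candidates=tuple(range(1, 22, 2)),
    p_candidates=tuple(range(0, 10)),
) -> list[tuple[int, int, int]]:
    """All (w1, w_out, p) triples passing the four conditions, lexicographic."""
    if not (w1_candidates and w_out_candidates and p_candidates):
        raise ValueError("candidate sets must be non-empty")
    out = []
    for w1 in sorted(w1_candidates):
        for w_out in sorted(w_out_candidates):
            for p in sorted(p_candidates):
                spec = NetworkSpec(1, 1, w1, w_out, p, 1, scale=scale)
                if validate_spec(spec, lr_patch).passed:
                    out.append((w1, w_out, p))
    return out


# ---------------------------------------------------------------------------
# layer plans


@dataclass(frozen=True)
class LayerStage:
    role: str  # feature_extraction | mapping | expansion | deconvolution
    in_channels: int
    out_channels: int
    kernel: int
    padding: int
    stride: int
    activation: str  # "prelu" | "none"
    recursive: bool = False  # weight-shared recursion; kernel counted once

    @property
    def kernel_weights(self) -> int:
        return self.out_channels * self.in_channels * self.kernel ** 2


@dataclass(frozen=True)
class LayerPlan:
    stages: tuple[LayerStage, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("empty layer plan")
        if self.stages[0].in_channels != 1:
            raise ValueError("first stage must take a single input channel")
        deconvs = [s.role for s in self.stages if s.role == "deconvolution"]
        if deconvs and (len(deconvs) != 1 or self.stages[-1].role != "deconvolution"):
            raise ValueError("at most one deconvolution stage, and it must be last")
        for a, b in zip(self.stages, self.stages[1:]):
            if a.out_channels != b.in_channels:
                raise ValueError(
                    f"channel chain broken: {a.out_channels} -> {b.in_channels}"
                )

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def channel_chain(self) -> tuple[int, ...]:
        return (self.stages[0].in_channels,) + tuple(s.out_channels for s in self.stages)


def build_layer_plan(spec: NetworkSpec) -> LayerPlan:
    """Stage list: feature extraction, n mapping recursions, expansion,
    deconvolution. Channel chain 1 -> N_feature -> N_map^n -> N_feature -> 1."""
    stages = [
        LayerStage("feature_extraction", 1, spec.n_feature, spec.w1, 0, 1, "prelu")
    ]
    in_ch = spec.n_feature
    for _ in range(spec.n):
        stages.append(
            LayerStage("mapping", in_ch, spec.n_map, MAPPING_KERNEL, MAPPING_PAD, 1, "prelu")
        )
        in_ch = spec.n_map
    stages.append(
        LayerStage("expansion", in_ch, spec.n_feature, MAPPING_KERNEL, MAPPING_PAD, 1, "prelu")
    )
    stages.append(
        LayerStage("deconvolution", spec.n_feature, 1, spec.w_out, spec.p, spec.scale, "none")
    )
    return LayerPlan(tuple(stages))


def count_weights(plan: LayerPlan, include_bias: bool = False, include_prelu: bool = False) -> int:
    """Sum of kernel weights over stages (weight-shared stages counted once).

    By default biases and PReLU slopes are excluded — the convention that
    reproduces the published per-network totals.
    """
    total = 0
    for s in plan.stages:
        total += s.kernel_weights
        if include_bias:
            total += s.out_channels
        if include_prelu and s.activation == "prelu":
            total += s.out_channels
    return total


def reference_plan(name: str) -> LayerPlan:
    """Fixed comparator configurations used for complexity comparisons.

    SRCNN: 9x9 (1->64), 1x1 (64->32), 5x5 (32->1).
    FSRCNN: 5x5 (1->56), 1x1 (56->12), four 3x3 (12->12), 1x1 (12->56),
            9x9 deconv (56->1).
    DRCN: 3x3 (1->256), 3x3 (256->256), one weight-shared recursive
          3x3 (256->256) counted once, 3x3 (256->256), 3x3 (256->1).
    """
    key = name.strip().upper()
    if key == "SRCNN":
        stages = (
            LayerStage("feature_extraction", 1, 64, 9, 0, 1, "none"),
            LayerStage("mapping", 64, 32, 1, 0, 1, "none"),
            LayerStage("mapping", 32, 1, 5, 0, 1, "none"),
        )
    elif key == "FSRCNN":
        stages = (
            LayerStage("feature_extraction", 1, 56, 5, 0, 1, "none"),
            LayerStage("mapping", 56, 12, 1, 0, 1, "none"),
            *(LayerStage("mapping", 12, 12, 3, 1, 1, "none") for _ in range(4)),
            LayerStage("expansion", 12, 56, 1, 0, 1, "none"),
            LayerStage("deconvolution", 56, 1, 9, 0, 2, "none"),
        )
    elif key == "DRCN":
        # the recursive stage unrolls 16 times at run time but its shared
        # kernel enters the weight count exactly once
        stages = (
            LayerStage("feature_extraction", 1, 256, 3, 1, 1, "none"),
            LayerStage("mapping", 256, 256, 3, 1, 1, "none"),
            LayerStage("mapping", 256, 256, 3, 1, 1, "none", recursive=True),
            LayerStage("mapping", 256, 256, 3, 1, 1, "none"),
            LayerStage("mapping", 256, 1, 3, 1, 1, "none"),
        )
    else:
        raise ValueError(f"unknown reference network {name!r}")
    return LayerPlan(stages)


# ---------------------------------------------------------------------------
# parameters and forward pass


@dataclass
class StageParams:
    kernel: np.ndarray  # (out_channels, in_channels, k, k)
    bias: np.ndarray  # (out_channels,)
    alpha: np.ndarray | None  # (out_channels,) PReLU slopes, None if no prelu

    def check(self, stage: LayerStage) -> None:
        expect = (stage.out_channels, stage.in_channels, stage.kernel, stage.kernel)
        if self.kernel.shape != expect:
            raise ValueError(f"kernel shape {self.kernel.shape} != plan {expect}")
        if self.bias.shape != (stage.out_channels,):
            raise ValueError(f"bias shape {self.bias.shape} != ({stage.out_channels},)")
        has_alpha = self.alpha is not None
        if has_alpha != (stage.activation == "prelu"):
            raise ValueError("PReLU slope presence does not match stage activation")
        if has_alpha and self.alpha.shape != (stage.out_channels,):
            raise ValueError(f"alpha shape {self.alpha.shape} != ({stage.out_channels},)")
        for arr in (self.kernel, self.bias) + ((self.alpha,) if has_alpha else ()):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite parameter values")


@dataclass
class ParameterSet:
    plan: LayerPlan
    stages: list[StageParams]

    def __post_init__(self) -> None:
        if len(self.stages) != len(self.plan.stages):
            raise ValueError("parameter/stage count mismatch")
        for sp, st in zip(self.stages, self.plan.stages):
            sp.check(st)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            self.plan,
            [
                StageParams(
                    s.kernel.copy(), s.bias.copy(), None if s.alpha is None else s.alpha.copy()
                )
                for s in self.stages
            ],
        )


def _forward_batch(params: ParameterSet, x: np.ndarray, caches: list | None = None):
    """Run the network on a channels-last (B, H, W, 1) batch. If ``caches``
    is a list it is filled with per-stage caches for backprop."""
    for sp, st in zip(params.stages, params.plan.stages):
        if st.role == "deconvolution":
            x, cache = deconv2d_forward(x, sp.kernel, sp.bias, st.padding, st.stride)
        else:
            x, cache = conv2d_forward(x, sp.kernel, sp.bias, st.padding, st.stride)
        if st.activation == "prelu":
            x, z = prelu_forward(x, sp.alpha)
            cache = (cache, z)
        if caches is not None:
            caches.append(cache)
    return x


def forward(params: ParameterSet, image, border_mode: str = "full-size"):
    """Single-image forward pass.

    border_mode="valid": no padding is added; the output has the natural size
    f*(S - w1) + w_out - 2p per axis.
    border_mode="full-size": the input is replicate-padded by (w1-1)/2 so the
    feature-extraction output matches the input size, and the reconstruction
    output is centre-cropped / edge-padded to exactly f*S.
    """
    values = as_values(image)
    f = params.plan.stages[-1].stride if params.plan.stages[-1].role == "deconvolution" else 1
    w1 = params.plan.stages[0].kernel
    x = values[None, :, :, None]
    if border_mode == "full-size":
        half = (w1 - 1) // 2
        if half:
            x = np.pad(x, ((0, 0), (half, half), (half, half), (0, 0)), mode="edge")
    elif border_mode != "valid":
        raise ValueError(f"unknown border_mode {border_mode!r}")
    y = _forward_batch(params, x)[0, :, :, 0]
    if border_mode == "full-size":
        y = _fit_to(y, (values.shape[0] * f, values.shape[1] * f))
    if isinstance(image, ImageGrid):
        return image.with_values(y)
    return y


def _fit_to(y: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Centre-crop or edge-pad each axis to the requested size."""
    for axis, target in enumerate(shape):
        cur = y.shape[axis]
        if cur > target:
            start = (cur - target) // 2
            y = y[(slice(None),) * axis + (slice(start, start + target),)]
        elif cur < target:
            before = (target - cur) // 2
            after = target - cur - before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, after)
            y = np.pad(y, pad, mode="edge")
    return y


def upscale(image: ImageGrid, params: ParameterSet) -> ImageGrid:
    """Enhance an LR image: normalize to [0, 1], run the network in full-size
    border mode, rescale and clip back to [0, MAX]."""
    max_i = image.max_intensity
    out = forward(params, image.values / max_i, border_mode="full-size")
    return image.with_values(np.clip(out, 0.0, 1.0) * max_i)
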