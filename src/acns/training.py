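"""Training: MSE loss, momentum SGD, Xavier initialization, the train loop.

The loss is L = (1/2N) * sum_i ||F(Y_i) - X_i||^2 over a mini-batch, with
gradients obtained by hand-written backprop through the conv / PReLU /
transposed-conv stages.  Weight updates follow classical momentum SGD,
Delta <- 0.9*Delta - eta*g; W <- W + Delta, with a smaller learning rate for
the reconstruction (deconvolution) stage than for the feature-extraction,
mapping and expansion stages.

Patch intensities are normalized to [0, 1] inside the loop (divide by MAX);
with raw 8-bit values the default learning rate diverges immediately.  The
sampling of each mini-batch is derived from (seed, iteration), so a run can
be checkpointed and resumed with a bit-identical loss trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import conv2d_backward, deconv2d_backward, prelu_backward
from .architecture import (
    LayerPlan,
    NetworkSpec,
    ParameterSet,
    StageParams,
    _forward_batch,
    build_layer_plan,
    validate_spec,
)
from .grid import as_values
from .patches import PatchPairSet

__all__ = [
    "TrainingConfig",
    "OptimizerState",
    "LossTrace",
    "TrainingDiverged",
    "mse_loss",
    "sgd_momentum_step",
    "xavier_init",
    "loss_and_gradients",
    "train",
]


class TrainingDiverged(RuntimeError):
    """The loss became non-finite."""


@dataclass(frozen=True)
class TrainingConfig:
    lr_main: float = 1e-3  # feature extraction / mapping / expansion stages
    lr_reconstruction: float = 1e-4  # deconvolution stage
    momentum: float = 0.9
    batch_size: int = 64
    iterations: int = 50_000
    seed: int = 0
    loss_log_interval: int = 100
    dtype: str = "float32"  # working precision of the update loop

    def __post_init__(self) -> None:
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")
        if self.lr_main <= 0 or self.lr_reconstruction <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch_size must be >= 1")


@dataclass
class OptimizerState:
    """Per-parameter velocity arrays, shapes mirroring the ParameterSet."""

    velocity: list[dict[str, np.ndarray]]

    @classmethod
    def zeros_like(cls, params: ParameterSet) -> "OptimizerState":
        vel = []
        for sp in params.stages:
            d = {"kernel": np.zeros_like(sp.kernel), "bias": np.zeros_like(sp.bias)}
            if sp.alpha is not None:
                d["alpha"] = np.zeros_like(sp.alpha)
            vel.append(d)
        return cls(vel)


@dataclass
class LossTrace:
    iterations: np.ndarray  # absolute iteration indices
    loss: np.ndarray

    def __len__(self) -> int:
        return len(self.iterations)


def mse_loss(outputs, targets) -> float:
    """(1/2N) * sum_i ||output_i - target_i||^2 (pixel-sum squared error)."""
    outs = [as_values(o) for o in outputs]
    tgts = [as_values(t) for t in targets]
    if len(outs) != len(tgts) or len(outs) == 0:
        raise ValueError("outputs and targets must be non-empty equal-length lists")
    total = 0.0
    for o, t in zip(outs, tgts):
        if o.shape != t.shape:
            raise ValueError(f"shape mismatch {o.shape} vs {t.shape}")
        diff = o - t
        total += float(np.sum(diff * diff))
    return total / (2.0 * len(outs))


def sgd_momentum_step(weights, gradients, velocity, rate: float, momentum: float = 0.9):
    """In-place momentum update: v <- m*v - eta*g; w <- w + v."""
    velocity *= momentum
    velocity -= rate * gradients
    weights += velocity
    return weights, velocity


def xavier_init(plan: LayerPlan, seed: int) -> ParameterSet:
    """Kernel entries ~ Uniform(+-sqrt(3/fan_in)) with fan_in = in_ch * k^2
    (variance 1/fan_in); biases 0; PReLU slopes 0.25.  Fully seed-determined."""
    rng = np.random.default_rng([seed, 0])
    stages = []
    for st in plan.stages:
        fan_in = st.in_channels * st.kernel ** 2
        limit = np.sqrt(3.0 / fan_in)
        kernel = rng.uniform(
            -limit, limit, (st.out_channels, st.in_channels, st.kernel, st.kernel)
        )
        bias = np.zeros(st.out_channels)
        alpha = np.full(st.out_channels, 0.25) if st.activation == "prelu" else None
        stages.append(StageParams(kernel, bias, alpha))
    return ParameterSet(plan, stages)


def loss_and_gradients(params: ParameterSet, lr_batch: np.ndarray, hr_batch: np.ndarray):
    """Forward + backward over a channels-last (B, s, s, 1) batch.

    Returns (loss, grads) where grads is a per-stage list of dicts with keys
    'kernel', 'bias' and (for PReLU stages) 'alpha'.
    """
    n = lr_batch.shape[0]
    caches: list = []
    out = _forward_batch(params, lr_batch, caches)
    if out.shape != hr_batch.shape:
        raise ValueError(f"network output {out.shape} != target {hr_batch.shape}")
    diff = out - hr_batch
    loss = float(np.sum(diff * diff)) / (2.0 * n)
    g = diff / n
    grads: list[dict[str, np.ndarray]] = [None] * len(params.stages)  # type: ignore
    for idx in range(len(params.stages) - 1, -1, -1):
        sp = params.stages[idx]
        st = params.plan.stages[idx]
        cache = caches[idx]
        entry: dict[str, np.ndarray] = {}
        if st.activation == "prelu":
            cache, z = cache
            g, entry["alpha"] = prelu_backward(g, z, sp.alpha)
        if st.role == "deconvolution":
            g, entry["kernel"], entry["bias"] = deconv2d_backward(g, sp.kernel, cache)
        else:
            g, entry["kernel"], entry["bias"] = conv2d_backward(
                g, sp.kernel, cache, need_input_grad=idx > 0
            )
        grads[idx] = entry
    return loss, grads


def _batch_indices(seed: int, iteration: int, n: int, batch: int) -> np.ndarray:
    rng = np.random.default_rng([seed, 1, iteration])
    return rng.integers(0, n, size=batch)


def train(
    spec: NetworkSpec,
    data: PatchPairSet,
    config: TrainingConfig,
    init: ParameterSet | None = None,
    state: OptimizerState | None = None,
    start_iteration: int = 0,
) -> tuple[ParameterSet, LossTrace, OptimizerState]:
    """Optimize the network on a patch-pair set.

    Runs iterations [start_iteration, config.iterations).  Passing the
    parameters and optimizer state from a checkpoint resumes a run with a
    bit-identical continuation of the loss trace.
    """
    if len(data) == 0:
        raise ValueError("empty training set")
    lr_patch = data.lr.shape[1]
    report = validate_spec(spec, lr_patch)
    if not report.passed:
        raise ValueError(f"network spec fails the design conditions:\n{report}")
    if data.hr.shape[1] != report.hr_patch:
        raise ValueError(
            f"HR patch size {data.hr.shape[1]} != implied size {report.hr_patch}"
        )
    if start_iteration >= config.iterations:
        raise ValueError("start_iteration must be < config.iterations")

    dtype = np.dtype(config.dtype)
    params = init.copy() if init is not None else xavier_init(build_layer_plan(spec), config.seed)
    for sp in params.stages:  # keep the whole loop in the working precision
        sp.kernel = sp.kernel.astype(dtype, copy=False)
        sp.bias = sp.bias.astype(dtype, copy=False)
        if sp.alpha is not None:
            sp.alpha = sp.alpha.astype(dtype, copy=False)
    state = (
        OptimizerState(
            [{k: v.astype(dtype) for k, v in d.items()} for d in state.velocity]
        )
        if state is not None
        else OptimizerState.zeros_like(params)
    )

    max_i = data.max_intensity
    lr_all = (data.lr / max_i)[:, :, :, None].astype(dtype)
    hr_all = (data.hr / max_i)[:, :, :, None].astype(dtype)
    n_pairs = len(data)

    iters = np.arange(start_iteration, config.iterations, dtype=np.int64)
    losses = np.empty(len(iters))
    for j, it in enumerate(iters):
        idx = _batch_indices(config.seed, int(it), n_pairs, config.batch_size)
        loss, grads = loss_and_gradients(params, lr_all[idx], hr_all[idx])
        if not np.isfinite(loss):
            raise TrainingDiverged(
                f"non-finite loss {loss} at iteration {it}; "
                "lower the learning rates or check the data scaling"
            )
        losses[j] = loss
        for sp, st, gr, vel in zip(params.stages, params.plan.stages, grads, state.velocity):
            rate = (
                config.lr_reconstruction if st.role == "deconvolution" else config.lr_main
            )
            sgd_momentum_step(sp.kernel, gr["kernel"], vel["kernel"], rate, config.momentum)
            sgd_momentum_step(sp.bias, gr["bias"], vel["bias"], rate, config.momentum)
            if sp.alpha is not None:
                sgd_momentum_step(sp.alpha, gr["alpha"], vel["alpha"], config.lr_main, config.momentum)
    return params, LossTrace(iters, losses), state
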