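"""Image and checkpoint I/O.

PNG: 8-bit grayscale, lossless round trip.  NIfTI: slice-wise read with
min-max rescale to [0, 255]; the applied rescale is recorded in a JSON
sidecar so it can be inverted.  Checkpoints: a single .npz archive of named
float arrays plus a JSON header (format version, network spec, iteration,
optimizer state presence, free-form metadata).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .architecture import (
    LayerPlan,
    NetworkSpec,
    ParameterSet,
    StageParams,
    build_layer_plan,
)
from .grid import ImageGrid
from .training import LossTrace, OptimizerState

__all__ = [
    "load_image",
    "save_image",
    "load_nifti_slice",
    "save_checkpoint",
    "load_checkpoint",
    "Checkpoint",
    "CheckpointError",
]

CHECKPOINT_FORMAT = "acns-checkpoint"
CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# images


def load_image(path, slice_index: int | None = None, axis: int = 2) -> ImageGrid:
    """Load an 8-bit grayscale PNG, or one slice of a NIfTI volume."""
    path = Path(path)
    if path.suffix == ".png":
        img = Image.open(path)
        if img.mode != "L":
            raise ValueError(
                f"{path}: unsupported PNG mode {img.mode!r}; "
                "only 8-bit grayscale ('L') is supported"
            )
        return ImageGrid(np.asarray(img, dtype=np.float64))
    if path.name.endswith((".nii", ".nii.gz")):
        return load_nifti_slice(path, slice_index, axis=axis)
    raise ValueError(f"{path}: unsupported image format")


def save_image(grid: ImageGrid, path) -> None:
    """Quantize (round half away from zero) and write an 8-bit grayscale PNG."""
    path = Path(path)
    if path.suffix != ".png":
        raise ValueError(f"{path}: only PNG export is supported")
    Image.fromarray(grid.quantized().astype(np.uint8), mode="L").save(path)


def load_nifti_slice(path, slice_index: int | None, axis: int = 2) -> ImageGrid:
    """Extract one slice of a NIfTI volume (RAS-ordered data array, slicing
    along ``axis``) and min-max rescale it to [0, 255].  The rescale is
    recorded in ``<path>.slice<i>.json`` so it can be inverted."""
    path = Path(path)
    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim == 2:
        data = vol
        slice_index = 0
    elif vol.ndim >= 3:
        if slice_index is None:
            raise ValueError(f"{path}: a slice index is required for volumes")
        vol = vol.reshape(vol.shape[:3])
        data = np.take(vol, slice_index, axis=axis)
    else:
        raise ValueError(f"{path}: unsupported dimensionality {vol.ndim}")
    vmin, vmax = float(data.min()), float(data.max())
    scale = 255.0 / (vmax - vmin) if vmax > vmin else 1.0
    rescaled = (data - vmin) * scale
    sidecar = path.parent / f"{path.name}.slice{slice_index}.json"
    sidecar.write_text(
        json.dumps({"vmin": vmin, "vmax": vmax, "scale": scale, "axis": axis}, indent=1)
    )
    return ImageGrid(rescaled)


# ---------------------------------------------------------------------------
# checkpoints


class CheckpointError(ValueError):
    """Malformed, tampered or incompatible checkpoint."""


@dataclass
class Checkpoint:
    spec: NetworkSpec
    params: ParameterSet
    trace: LossTrace | None
    state: OptimizerState | None
    iteration: int
    metadata: dict


def save_checkpoint(
    params: ParameterSet,
    spec: NetworkSpec,
    path,
    trace: LossTrace | None = None,
    state: OptimizerState | None = None,
    iteration: int = 0,
    metadata: dict | None = None,
) -> None:
    """Write a single-file archive of named arrays plus a JSON header."""
    arrays: dict[str, np.ndarray] = {}
    for i, sp in enumerate(params.stages):
        arrays[f"stage{i}_kernel"] = sp.kernel
        arrays[f"stage{i}_bias"] = sp.bias
        if sp.alpha is not None:
            arrays[f"stage{i}_alpha"] = sp.alpha
    if state is not None:
        for i, vel in enumerate(state.velocity):
            for key, arr in vel.items():
                arrays[f"velocity{i}_{key}"] = arr
    if trace is not None:
        arrays["trace_iterations"] = trace.iterations
        arrays["trace_loss"] = trace.loss
    header = {
        "format": CHECKPOINT_FORMAT,
        "version": CHECKPOINT_VERSION,
        "spec": spec.to_dict(),
        "iteration": int(iteration),
        "has_state": state is not None,
        "has_trace": trace is not None,
        "metadata": metadata or {},
    }
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> Checkpoint:
    """Load and re-validate a checkpoint; arrays round-trip bit-exactly."""
    with np.load(path, allow_pickle=False) as archive:
        data = {k: archive[k] for k in archive.files}
    if "__header__" not in data:
        raise CheckpointError(f"{path}: missing checkpoint header")
    try:
        header = json.loads(bytes(data["__header__"]).decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise CheckpointError(f"{path}: unreadable header ({exc})") from exc
    if header.get("format") != CHECKPOINT_FORMAT:
        raise CheckpointError(f"{path}: not an {CHECKPOINT_FORMAT} file")
    if header.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"{path}: unsupported checkpoint version {header.get('version')}"
        )
    try:
        spec = NetworkSpec.from_dict(header["spec"])
    except (KeyError, TypeError, ValueError) as exc:
        raise CheckpointError(f"{path}: invalid network spec in header ({exc})") from exc
    plan = build_layer_plan(spec)
    stages = []
    for i, st in enumerate(plan.stages):
        try:
            kernel = data[f"stage{i}_kernel"]
            bias = data[f"stage{i}_bias"]
        except KeyError as exc:
            raise CheckpointError(f"{path}: missing arrays for stage {i}") from exc
        alpha = data.get(f"stage{i}_alpha")
        stages.append(StageParams(kernel, bias, alpha))
    try:
        params = ParameterSet(plan, stages)
    except ValueError as exc:
        raise CheckpointError(f"{path}: arrays do not match the spec ({exc})") from exc
    state = None
    if header.get("has_state"):
        velocity = []
        for i, sp in enumerate(params.stages):
            vel = {
                "kernel": data[f"velocity{i}_kernel"],
                "bias": data[f"velocity{i}_bias"],
            }
            if sp.alpha is not None:
                vel["alpha"] = data[f"velocity{i}_alpha"]
            velocity.append(vel)
        state = OptimizerState(velocity)
    trace = None
    if header.get("has_trace"):
        trace = LossTrace(data["trace_iterations"], data["trace_loss"])
    return Checkpoint(
        spec=spec,
        params=params,
        trace=trace,
        state=state,
        iteration=int(header.get("iteration", 0)),
        metadata=header.get("metadata", {}),
    )
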