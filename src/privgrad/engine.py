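"""The per-sample gradient engine: wrap, forward, clip, aggregate, noise.

DP-SGD needs the gradient of each sample's loss individually before any
reduction.  The engine realises the replica idiom: a wrapped model exposes
one *view* of the network per minibatch sample, all views aliasing a single
parameter store (replication adds no parameter memory), and the whole
minibatch is executed in one batched dispatch whose backward pass keeps the
batch axis — so the result is identical, sample for sample, to running B
independent single-sample passes.  Parallelism is a contract on the result
(order-independence), not a prescribed mechanism.

One DP step is then:

    per-sample grads  g_i            (parallel_forward + per_sample_grads)
    clip              g_i <- g_i * min(1, C/||g_i||)
    aggregate+noise   ( sum_i g_i + N(0, sigma^2 C^2 I) ) / B   (mean)

With sigma = 0 and C = inf this is an ordinary minibatch-mean gradient, so
any first-order optimiser consumes the output unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from types import SimpleNamespace
from typing import Callable

import numpy as np

from . import nn
from .noise import GaussianNoiseSource
from .surgery import validate

__all__ = [
    "EngineError",
    "WrappedModel",
    "PerSampleGradients",
    "ClipReport",
    "wrap",
    "parallel_forward",
    "per_sample_grads",
    "clip",
    "aggregate_and_noise",
    "dp_step",
    "serial_oracle",
]

_NORM_FLOOR = 1e-12  # division guard for zero-gradient samples


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class PerSampleGradients:
    """Flattened per-sample gradients: row i is d(loss_i)/d(parameters)."""

    values: np.ndarray  # (B, P)
    per_sample_norms: np.ndarray  # (B,)

    @classmethod
    def from_values(cls, values: np.ndarray) -> "PerSampleGradients":
        return cls(values, np.linalg.norm(values, axis=1))


@dataclass(frozen=True)
class ClipReport:
    pre_norms: np.ndarray
    clip_factors: np.ndarray
    clip_norm: float


class WrappedModel:
    """A model plus B weight-sharing replica views.

    Each replica's parameter dict contains the *same ndarray objects* as
    the base model's layers: a write through the base store is observable
    through every replica and no parameter memory is added.  ``wrap`` with
    B = 1 is behaviourally identical to the plain model.
    """

    def __init__(self, model: nn.Sequential, minibatch_size: int):
        if minibatch_size < 1:
            raise EngineError(f"minibatch size must be >= 1, got {minibatch_size}")
        validate(model)  # refuse cross-sample state up front
        self.model = model
        self.minibatch_size = minibatch_size
        self.replicas = tuple(
            SimpleNamespace(
                index=i,
                params={name: p for name, p in model.named_parameters()},
            )
            for i in range(minibatch_size)
        )

    @property
    def num_params(self) -> int:
        return self.model.num_params


def wrap(model: nn.Sequential, minibatch_size: int) -> WrappedModel:
    """Validate DP-compatibility and build the replica wrapper."""
    return WrappedModel(model, minibatch_size)


def parallel_forward(
    wrapped: WrappedModel, batch: np.ndarray, train: bool = True
) -> np.ndarray:
    """Forward the whole minibatch in one dispatch.

    Output row i equals the plain model applied to sample i alone (the
    surgery gate guarantees no cross-sample statistics), so the result is
    independent of any scheduling order.
    """
    if batch.shape[0] != wrapped.minibatch_size:
        raise EngineError(
            f"batch size {batch.shape[0]} != wrapped minibatch size "
            f"{wrapped.minibatch_size}"
        )
    return wrapped.model.forward(batch, train=train)


def per_sample_grads(
    wrapped: WrappedModel, loss_grad: np.ndarray
) -> PerSampleGradients:
    """Backward pass yielding one flattened gradient row per sample.

    ``loss_grad`` is d(loss_i)/d(output_i) with leading batch axis, as
    returned by the per-sample loss functions; a scalar (already reduced
    over the batch) cannot be attributed to samples and is refused.
    """
    if np.ndim(loss_grad) == 0:
        raise EngineError(
            "loss gradient is a scalar: the loss was reduced over the batch "
            "before backward, so per-sample gradients cannot be attributed"
        )
    if loss_grad.shape[0] != wrapped.minibatch_size:
        raise EngineError(
            f"loss gradient batch axis {loss_grad.shape[0]} != minibatch size "
            f"{wrapped.minibatch_size}"
        )
    wrapped.model.backward(loss_grad)
    values = wrapped.model.per_sample_flat_grads()
    return PerSampleGradients.from_values(values)


def clip(
    grads: PerSampleGradients, clip_norm: float
) -> tuple[PerSampleGradients, ClipReport]:
    """Scale each row to L2 norm at most C, preserving direction.

    factor_i = min(1, C / max(||g_i||, 1e-12)); rows already within the
    norm (including all-zero rows) pass through unchanged.
    """
    if clip_norm <= 0:
        raise EngineError(f"clip norm must be > 0, got {clip_norm}")
    pre = grads.per_sample_norms
    factors = np.minimum(1.0, clip_norm / np.maximum(pre, _NORM_FLOOR))
    clipped = grads.values * factors[:, None]
    report = ClipReport(pre_norms=pre.copy(), clip_factors=factors,
                        clip_norm=clip_norm)
    return PerSampleGradients.from_values(clipped), report


def aggregate_and_noise(
    clipped: PerSampleGradients,
    clip_norm: float,
    sigma: float,
    reduction: str = "mean",
    noise_source: GaussianNoiseSource | None = None,
    noise: np.ndarray | None = None,
    nominal_batch_size: int | None = None,
) -> np.ndarray:
    """Sum the clipped rows, add N(0, sigma^2 C^2 I), optionally average.

    For ``reduction="mean"`` the noisy sum is divided by the nominal batch
    size (the wrapped minibatch size, or ``nominal_batch_size`` for Poisson
    batches whose realised size varies), giving per-coordinate noise std
    sigma*C/B — the calibration the accountant analyses.  ``noise`` may be
    supplied directly (tests); otherwise it is drawn from ``noise_source``.
    """
    if sigma < 0:
        raise EngineError(f"sigma must be >= 0, got {sigma}")
    if reduction not in ("mean", "sum"):
        raise EngineError(f"unknown reduction {reduction!r}")
    B, P = clipped.values.shape
    total = clipped.values.sum(axis=0)
    if sigma > 0 and math.isfinite(clip_norm):
        if noise is None:
            if noise_source is None:
                raise EngineError("sigma > 0 requires a noise source or vector")
            noise = noise_source.draw(P, sigma * clip_norm)
        if noise.shape != (P,):
            raise EngineError(f"noise length {noise.shape} != parameter count ({P},)")
        total = total + noise
    if reduction == "mean":
        denom = nominal_batch_size if nominal_batch_size is not None else B
        total = total / denom
    return total


def dp_step(
    wrapped: WrappedModel,
    batch: np.ndarray,
    loss_fn: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    clip_norm: float,
    sigma: float,
    noise_source: GaussianNoiseSource | None = None,
    reduction: str = "mean",
    nominal_batch_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One full DP-SGD gradient computation.

    ``loss_fn(output, sample_indices)`` returns (per-sample losses, loss
    grad); the index argument lets the closure pick the right labels when
    the oracle below re-runs single samples.  Writes the aggregated noisy
    gradient into the model's optimiser slots and returns
    (per-sample losses, flat aggregated gradient).
    """
    out = parallel_forward(wrapped, batch)
    losses, lgrad = loss_fn(out, np.arange(batch.shape[0]))
    grads = per_sample_grads(wrapped, lgrad)
    if math.isfinite(clip_norm):
        grads, _ = clip(grads, clip_norm)
    flat = aggregate_and_noise(
        grads, clip_norm, sigma, reduction=reduction,
        noise_source=noise_source, nominal_batch_size=nominal_batch_size,
    )
    wrapped.model.set_flat_grad(flat)
    return losses, flat


def serial_oracle(
    model: nn.Sequential,
    batch: np.ndarray,
    loss_fn: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
) -> PerSampleGradients:
    """Reference per-sample gradients: one single-sample pass per row.

    Definitionally correct and independent of the batched engine; used as
    the equivalence oracle in tests.  ``loss_fn`` has the same
    (output, sample_indices) signature as in :func:`dp_step`.
    """
    rows = []
    for i in range(batch.shape[0]):
        xi = batch[i:i + 1]
        out = model.forward(xi, train=True)
        _, lgrad = loss_fn(out, np.array([i]))
        model.backward(lgrad)
        rows.append(model.per_sample_flat_grads()[0])
    return PerSampleGradients.from_values(np.stack(rows))
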