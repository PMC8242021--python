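"""End-to-end private and non-private training with a privacy watchdog.

The private loop composes the package: per epoch, minibatches from the
uniform or Poisson sampler are pushed through the per-sample gradient
engine (forward, per-sample backward, clip, aggregate+noise) and handed to
a standard first-order optimiser.  Before *executing* step t+1 the
accountant computes the epsilon that step would certify; if it would
exceed the configured budget the run halts — prospective accounting, so a
trace can never overshoot its budget.  Epsilon spent is therefore
non-decreasing along every trace and the halting step is exactly the
analytic inversion of the accountant.

Learning-rate scheduling follows the plateau rule: the rate is halved when
the validation loss has stagnated (relative improvement below 1e-3) for
two consecutive epochs.

Also here: the evaluation metrics (rank-based ROC-AUC for classification,
Dice overlap for segmentation), small reference model builders, and the
timing/peak-memory benchmark harness (informational only — results are
hardware-dependent).
"""

from __future__ import annotations

import json
import math
import resource
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .accounting import PrivacySpent, TrainingSchedule, audit
from .data import DatasetManifest, class_weights, poisson_batches, uniform_batches
from .engine import dp_step, wrap
from .noise import GaussianNoiseSource
from .surgery import validate
from .synthetic import load_split_arrays

__all__ = [
    "ConfigError",
    "RunConfig",
    "RunTrace",
    "train_private",
    "train_nonprivate",
    "roc_auc",
    "dice",
    "benchmark",
    "tiny_cnn",
    "tiny_cnn_bn",
    "tiny_segnet",
]

_PLATEAU_FACTOR = 0.5
_PLATEAU_PATIENCE = 2  # epochs
_PLATEAU_REL_THRESHOLD = 1e-3


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything one training run needs beyond the data manifest."""

    task: str  # classification | segmentation
    model: nn.Sequential
    schedule: TrainingSchedule
    optimiser: str = "sgd"  # sgd | adam
    learning_rate: float = 0.005
    epsilon_budget: float = math.inf
    accounting_mode: str = "gdp-poisson"
    sampler: str = "uniform"  # uniform | poisson
    secure_rng: bool = True
    seed: int | None = None  # data-order/init seed; never the DP noise
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.task not in ("classification", "segmentation"):
            raise ConfigError(f"unknown task {self.task!r}")
        if self.optimiser not in ("sgd", "adam"):
            raise ConfigError(f"unknown optimiser {self.optimiser!r}")
        if self.sampler not in ("uniform", "poisson"):
            raise ConfigError(f"unknown sampler {self.sampler!r}")
        if self.epsilon_budget <= 0:
            raise ConfigError("epsilon budget must be > 0")


@dataclass
class RunTrace:
    """Per-step records plus the final accounting and metrics."""

    records: list[dict] = field(default_factory=list)
    final_privacy: PrivacySpent | None = None
    final_metrics: dict = field(default_factory=dict)
    halt_reason: str = "completed"

    @property
    def steps_taken(self) -> int:
        return len(self.records)


def _make_optimiser(config: RunConfig) -> nn.SGD | nn.Adam:
    if config.optimiser == "sgd":
        return nn.SGD(config.model, config.learning_rate)
    return nn.Adam(config.model, config.learning_rate)


def _loss_closure(config: RunConfig, labels: np.ndarray,
                  weights: np.ndarray | None,
                  masks: np.ndarray | None) -> Callable:
    """Build the per-sample loss for one minibatch index set."""
    def make(batch_idx: np.ndarray):
        def loss_fn(out: np.ndarray, within: np.ndarray):
            sel = batch_idx[within]
            if config.task == "classification":
                return nn.softmax_cross_entropy(out, labels[sel], weights)
            return nn.bce_with_logits(out, masks[sel])
        return loss_fn
    return make


def _epoch_val_loss(config: RunConfig, x_val, y_val, weights, batch: int = 64
                    ) -> float:
    losses = []
    for i in range(0, len(x_val), batch):
        out = config.model.forward(x_val[i:i + batch], train=False)
        if config.task == "classification":
            l, _ = nn.softmax_cross_entropy(out, y_val[i:i + batch], weights)
        else:
            l, _ = nn.bce_with_logits(out, y_val[i:i + batch])
        losses.append(l)
    return float(np.concatenate(losses).mean())


def _final_metrics(config: RunConfig, x_val, y_val) -> dict:
    outs = []
    for i in range(0, len(x_val), 64):
        outs.append(config.model.forward(x_val[i:i + 64], train=False))
    out = np.concatenate(outs)
    if config.task == "classification":
        scores = out[:, 1] - out[:, 0]
        return {"roc_auc": roc_auc(scores, y_val)}
    pred = (out > 0.0).astype(float)
    scores = [dice(pred[i, 0], y_val[i, 0]) for i in range(len(pred))]
    return {"dice": float(np.mean(scores))}


class _PlateauScheduler:
    """Halve the learning rate after `patience` stagnant epochs."""

    def __init__(self, optimiser, factor=_PLATEAU_FACTOR,
                 patience=_PLATEAU_PATIENCE, rel_threshold=_PLATEAU_REL_THRESHOLD):
        self.opt = optimiser
        self.factor, self.patience, self.rel = factor, patience, rel_threshold
        self.best = math.inf
        self.stagnant = 0

    def step(self, val_loss: float) -> None:
        if val_loss < self.best * (1 - self.rel):
            self.best = val_loss
            self.stagnant = 0
        else:
            self.stagnant += 1
            if self.stagnant >= self.patience:
                self.opt.lr *= self.factor
                self.stagnant = 0


def _write_logs(config: RunConfig, trace: RunTrace) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "steps.jsonl", "w") as fh:
        for rec in trace.records:
            fh.write(json.dumps(rec) + "\n")
    summary = {
        "halt_reason": trace.halt_reason,
        "steps": trace.steps_taken,
        "metrics": trace.final_metrics,
    }
    if trace.final_privacy is not None:
        p = trace.final_privacy
        summary["privacy"] = {
            "mu": p.mu, "epsilon": None if math.isinf(p.epsilon) else p.epsilon,
            "delta": p.delta, "steps_accounted": p.steps_accounted,
            "mode": p.mode,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def train_private(config: RunConfig, manifest: DatasetManifest) -> RunTrace:
    """DP-SGD training under a privacy budget with a prospective watchdog.

    Refuses insecure noise and refuses a global seed while the secure RNG
    is on (a seed would promise a reproducibility that secure noise cannot
    deliver).  Every executed step — including noise-only steps from empty
    Poisson batches — is charged to the accountant *before* it runs.
    """
    if not config.secure_rng:
        raise ConfigError(
            "private training requires the secure noise source; "
            "insecure seeded noise is for tests of the noise module only"
        )
    if config.seed is not None:
        raise ConfigError(
            "refusing to run private training with a global seed while the "
            "secure RNG is enabled: the run cannot be made reproducible"
        )
    validate(config.model)
    sched = config.schedule
    noise = GaussianNoiseSource(secure=True)

    x_train, y_train = load_split_arrays(manifest, "train")
    x_val, y_val = load_split_arrays(manifest, "val")
    weights_arr = None
    if config.task == "classification":
        counts = manifest.subset("train").class_counts
        w = class_weights(counts)
        weights_arr = np.array([w[k] for k in sorted(w)])
        masks = None
        labels = y_train
    else:
        masks = y_train
        labels = np.zeros(len(x_train), dtype=int)
    make_loss = _loss_closure(config, labels, weights_arr, masks)

    opt = _make_optimiser(config)
    scheduler = _PlateauScheduler(opt)
    trace = RunTrace()
    n = len(x_train)
    B = sched.batch_size
    steps_per_epoch = math.ceil(n / B)
    total_steps = sched.total_steps
    P = config.model.num_params
    sigma, C = sched.noise_multiplier, sched.clip_norm

    step = 0
    done = False
    epoch = 0
    while step < total_steps and not done:
        if config.sampler == "uniform":
            batches = uniform_batches(n, B, seed=int(np.random.default_rng().integers(2**31)))
        else:
            batches = poisson_batches(n, sched.sample_rate,
                                      min(steps_per_epoch, total_steps - step),
                                      noise_source=noise)
        for batch_idx in batches:
            prospective = audit(sched, config.accounting_mode, steps=step + 1)
            if prospective.epsilon > config.epsilon_budget:
                trace.halt_reason = "budget_exhausted"
                done = True
                break
            if len(batch_idx) == 0:
                # noise-only step: the mechanism released pure noise
                flat = noise.draw(P, sigma * C) / B
                config.model.set_flat_grad(flat)
                losses = np.array([])
            else:
                wrapped = wrap(config.model, len(batch_idx))
                losses, _ = dp_step(
                    wrapped, x_train[batch_idx], make_loss(batch_idx),
                    clip_norm=C, sigma=sigma, noise_source=noise,
                    nominal_batch_size=B,
                )
            opt.step()
            trace.records.append({
                "step": step,
                "loss": float(losses.mean()) if losses.size else None,
                "epsilon": prospective.epsilon,
                "lr": opt.lr,
            })
            step += 1
            if step >= total_steps:
                break
        if not done:
            val_loss = _epoch_val_loss(config, x_val, y_val, weights_arr)
            scheduler.step(val_loss)
        epoch += 1

    trace.final_privacy = audit(sched, config.accounting_mode, steps=step)
    trace.final_metrics = _final_metrics(config, x_val, y_val)
    _write_logs(config, trace)
    return trace


def train_nonprivate(config: RunConfig, manifest: DatasetManifest) -> RunTrace:
    """Ordinary minibatch training with the same logging and scheduling.

    Runs through the same engine with sigma = 0 and no clipping, so the
    update is the exact minibatch-mean gradient; the reported privacy
    budget is infinite.
    """
    validate(config.model)
    sched = config.schedule
    x_train, y_train = load_split_arrays(manifest, "train")
    x_val, y_val = load_split_arrays(manifest, "val")
    weights_arr = None
    if config.task == "classification":
        counts = manifest.subset("train").class_counts
        w = class_weights(counts)
        weights_arr = np.array([w[k] for k in sorted(w)])
        masks = None
        labels = y_train
    else:
        masks = y_train
        labels = np.zeros(len(x_train), dtype=int)
    make_loss = _loss_closure(config, labels, weights_arr, masks)

    opt = _make_optimiser(config)
    scheduler = _PlateauScheduler(opt)
    trace = RunTrace()
    n = len(x_train)
    B = sched.batch_size
    total_steps = sched.total_steps
    rng = np.random.default_rng(config.seed)

    step = 0
    while step < total_steps:
        for batch_idx in uniform_batches(n, B, seed=int(rng.integers(2**31))):
            wrapped = wrap(config.model, len(batch_idx))
            losses, _ = dp_step(
                wrapped, x_train[batch_idx], make_loss(batch_idx),
                clip_norm=math.inf, sigma=0.0, nominal_batch_size=len(batch_idx),
            )
            opt.step()
            trace.records.append({
                "step": step, "loss": float(losses.mean()),
                "epsilon": math.inf, "lr": opt.lr,
            })
            step += 1
            if step >= total_steps:
                break
        val_loss = _epoch_val_loss(config, x_val, y_val, weights_arr)
        scheduler.step(val_loss)

    trace.final_privacy = PrivacySpent(0.0, math.inf, sched.delta, step,
                                       "nonprivate")
    trace.final_metrics = _final_metrics(config, x_val, y_val)
    _write_logs(config, trace)
    return trace


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with half-credit for ties."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC-AUC is undefined for single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores)))


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Overlap 2|A∩B| / (|A|+|B|) of two binary masks; both-empty = 1."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(
            f"mask shapes differ: {pred_mask.shape} vs {true_mask.shape}"
        )
    a = pred_mask.astype(bool)
    b = true_mask.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


# ---------------------------------------------------------------------------
# reference model builders (tiny, for fixtures and smoke runs)
# ---------------------------------------------------------------------------

def tiny_cnn(image_size: int = 32, width: int = 8, n_classes: int = 2,
             seed: int = 0) -> nn.Sequential:
    """Two conv blocks + linear head; image size must be divisible by 4."""
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        nn.Conv2d(1, width, 3, padding=1, rng=rng),
        nn.ReLU(),
        nn.AvgPool2d(2),
        nn.Conv2d(width, 2 * width, 3, padding=1, rng=rng),
        nn.ReLU(),
        nn.AvgPool2d(2),
        nn.Flatten(),
        nn.Linear(2 * width * (image_size // 4) ** 2, n_classes, rng=rng),
    )


def tiny_cnn_bn(image_size: int = 32, width: int = 8, n_classes: int = 2,
                seed: int = 0) -> nn.Sequential:
    """Like :func:`tiny_cnn` but with batch normalisation after each conv
    (running statistics on — requires surgery before private training)."""
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        nn.Conv2d(1, width, 3, padding=1, rng=rng),
        nn.BatchNorm2d(width),
        nn.ReLU(),
        nn.AvgPool2d(2),
        nn.Conv2d(width, 2 * width, 3, padding=1, rng=rng),
        nn.BatchNorm2d(2 * width),
        nn.ReLU(),
        nn.AvgPool2d(2),
        nn.Flatten(),
        nn.Linear(2 * width * (image_size // 4) ** 2, n_classes, rng=rng),
    )


def tiny_segnet(width: int = 8, seed: int = 0) -> nn.Sequential:
    """Minimal encoder-decoder producing one logit map per pixel."""
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        nn.Conv2d(1, width, 3, padding=1, rng=rng),
        nn.ReLU(),
        nn.AvgPool2d(2),
        nn.Conv2d(width, 2 * width, 3, padding=1, rng=rng),
        nn.ReLU(),
        nn.Upsample2d(2),
        nn.Conv2d(2 * width, 1, 3, padding=1, rng=rng),
    )


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

def benchmark(task: str = "classification", image_size: int = 64,
              batch_size: int = 32, steps: int = 25, repetitions: int = 5,
              width: int = 8, seed: int = 0) -> dict:
    """Median wall time for `steps` DP steps at the given batch size, over
    `repetitions` runs, plus peak resident memory.

    Informational only: absolute numbers are hardware-dependent.  The
    protocol (25 steps of 32 samples, 5 timing repetitions, peak RSS for
    one batch) mirrors the standard comparison set-up for DP-SGD engines.
    """
    rng = np.random.default_rng(seed)
    x = rng.random((batch_size, 1, image_size, image_size))
    if task == "classification":
        model = tiny_cnn(image_size, width=width, seed=seed)
        y = rng.integers(0, 2, batch_size)
        def loss_fn(out, within):
            return nn.softmax_cross_entropy(out, y[within], None)
    else:
        model = tiny_segnet(width=width, seed=seed)
        m = (rng.random((batch_size, 1, image_size, image_size)) > 0.5).astype(float)
        def loss_fn(out, within):
            return nn.bce_with_logits(out, m[within])
    noise = GaussianNoiseSource(secure=True)
    wrapped = wrap(model, batch_size)
    opt = nn.SGD(model, lr=1e-3)

    times = []
    for _ in range(repetitions):
        t0 = time.perf_counter()
        for _ in range(steps):
            dp_step(wrapped, x, loss_fn, clip_norm=1.0, sigma=1.0,
                    noise_source=noise)
            opt.step()
        times.append(time.perf_counter() - t0)
    # one-batch peak RSS (ru_maxrss is KiB on Linux)
    dp_step(wrapped, x, loss_fn, clip_norm=1.0, sigma=1.0, noise_source=noise)
    peak_kib = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss
    return {
        "task": task,
        "batch_size": batch_size,
        "steps": steps,
        "repetitions": times,
        "median_seconds": float(np.median(times)),
        "peak_rss_mib": peak_kib / 1024.0,
        "per_sample_grad_mib": batch_size * model.num_params * 8 / 2**20,
    }
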