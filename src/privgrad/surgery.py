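"""DP-compatibility model surgery.

Per-sample gradient semantics require every layer's output for sample *i*
to be a function of sample *i* alone.  Batch normalisation breaks this in
two ways: its running mean/variance are a non-private state accumulated
across samples and steps, and its training-mode statistics couple the
samples of a batch.  Surgery detects such layers and flips them into a
per-sample-statistics mode (each sample normalised by its own per-channel
spatial moments, in training and evaluation alike), or optionally
substitutes group normalisation.  Layers whose statefulness is not
understood fail closed: privacy correctness outranks convenience.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = ["DPIncompatibilityError", "Finding", "SurgeryReport", "scan", "fix", "validate"]


class DPIncompatibilityError(ValueError):
    """A model contains layers that break per-sample gradient semantics."""


#: Layers that compute strictly per-sample (no cross-sample or cross-step
#: state); anything outside this allowlist and the batch-norm family is
#: treated as unknown and fails closed.
_PER_SAMPLE_SAFE = (
    nn.Linear,
    nn.Conv2d,
    nn.AvgPool2d,
    nn.Upsample2d,
    nn.ReLU,
    nn.Sigmoid,
    nn.Flatten,
    nn.GroupNorm,
)


@dataclass(frozen=True)
class Finding:
    layer: str
    issue: str
    action: str  # "fixed: ..." once repaired, "required: ..." before

    @property
    def outstanding(self) -> bool:
        return self.action.startswith("required")


@dataclass(frozen=True)
class SurgeryReport:
    findings: tuple[Finding, ...] = field(default_factory=tuple)

    @property
    def compliant(self) -> bool:
        return not any(f.outstanding for f in self.findings)

    def __str__(self) -> str:
        if not self.findings:
            return "model is DP-compatible; no findings"
        lines = [f"{len(self.findings)} finding(s); compliant={self.compliant}"]
        for f in self.findings:
            lines.append(f"  {f.layer}: {f.issue} -> {f.action}")
        return "\n".join(lines)


def scan(model: nn.Sequential) -> SurgeryReport:
    """Flag every layer holding or computing cross-sample state."""
    findings: list[Finding] = []
    for name, layer in model.named_layers():
        if isinstance(layer, nn.BatchNorm2d):
            if not layer.per_sample_stats:
                findings.append(Finding(
                    layer=name,
                    issue="batch normalisation with cross-sample statistics"
                          + (" and running averages" if layer.track_running_stats else ""),
                    action="required: switch to per-sample statistics",
                ))
        elif not isinstance(layer, _PER_SAMPLE_SAFE):
            findings.append(Finding(
                layer=name,
                issue=f"unknown layer kind {type(layer).__name__}; "
                      "per-sample independence cannot be certified",
                action="required: manual review",
            ))
    return SurgeryReport(tuple(findings))


def fix(model: nn.Sequential, strategy: str = "disable_stats"
        ) -> tuple[nn.Sequential, SurgeryReport]:
    """Repair flagged layers in place; idempotent.

    strategy="disable_stats" (default) keeps each batch-norm layer but
    makes it normalise every sample by its own statistics and drop the
    running averages; affine parameters are preserved.
    strategy="group_norm" substitutes a single-group group-norm layer,
    transplanting the affine parameters.

    Unknown stateful layers raise: no silent pass.
    """
    if strategy not in ("disable_stats", "group_norm"):
        raise ValueError(f"unknown surgery strategy {strategy!r}")
    findings: list[Finding] = []
    for idx, layer in enumerate(model.layers):
        name = f"{idx}.{type(layer).__name__}"
        if isinstance(layer, nn.BatchNorm2d) and not layer.per_sample_stats:
            if strategy == "disable_stats":
                layer.per_sample_stats = True
                layer.track_running_stats = False
                layer.running_mean = np.zeros(layer.num_features)
                layer.running_var = np.ones(layer.num_features)
                findings.append(Finding(name,
                    "batch normalisation with cross-sample statistics",
                    "fixed: per-sample statistics enabled, running averages removed"))
            else:
                gn = nn.GroupNorm(1, layer.num_features)
                gn.params["gamma"][...] = layer.params["gamma"]
                gn.params["beta"][...] = layer.params["beta"]
                model.layers[idx] = gn
                findings.append(Finding(name,
                    "batch normalisation with cross-sample statistics",
                    "fixed: substituted single-group group normalisation"))
        elif not isinstance(layer, (_PER_SAMPLE_SAFE, nn.BatchNorm2d)):
            raise DPIncompatibilityError(
                f"cannot repair layer {name}: unknown stateful kind "
                f"{type(layer).__name__}"
            )
    return model, SurgeryReport(tuple(findings))


def validate(model: nn.Sequential) -> None:
    """Raise unless the model is certified per-sample independent."""
    report = scan(model)
    if not report.compliant:
        raise DPIncompatibilityError(
            "model is not DP-compatible:\n" + str(report)
        )
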