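"""Typed configuration objects for every stage of the pipeline.

Defaults encode the published experimental settings of the method: 10-s
windows, batch size 256, triplet margin alpha = 0.1, learning rate 0.1,
loss weights initialized at (1, 0, 0), and the positive-label proportions
of the scripted / in-the-wild context datasets used as generator priors.
Configs are pydantic models with ``extra="forbid"`` so typos in YAML files
fail loudly, and every validation error is reported at once.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

ACTIVITY_LABELS: tuple[str, ...] = (
    "bathroom", "jogging", "lying_down", "running", "sitting", "sleeping",
    "stairs_down", "stairs_up", "standing", "talking_on_phone", "typing",
    "walking",
)
PRIOCEPTION_LABELS: tuple[str, ...] = ("phone_in_hand", "phone_in_pocket", "phone_in_bag")

# Positive-label proportions observed in the scripted (source) and
# in-the-wild (target) context datasets, per activity, as fractions.
SCRIPTED_ACTIVITY_PRIORS: dict[str, float] = {
    "bathroom": 0.0315, "jogging": 0.0204, "lying_down": 0.0110,
    "running": 0.0195, "sitting": 0.1199, "sleeping": 0.0219,
    "stairs_down": 0.0252, "stairs_up": 0.0089, "standing": 0.0171,
    "talking_on_phone": 0.0141, "typing": 0.0365, "walking": 0.6400,
}
WILD_ACTIVITY_PRIORS: dict[str, float] = {
    "bathroom": 0.0217, "jogging": 0.0027, "lying_down": 0.1624,
    "running": 0.0037, "sitting": 0.3871, "sleeping": 0.3769,
    "stairs_down": 0.0200, "stairs_up": 0.0192, "standing": 0.0846,
    "talking_on_phone": 0.0127, "typing": 0.0645, "walking": 0.1351,
}


def _default_priors(table: dict[str, float], labels: tuple[str, ...]) -> list[float]:
    acts = [table[l] for l in labels if l in ACTIVITY_LABELS]
    n_prio = sum(1 for l in labels if l in PRIOCEPTION_LABELS)
    return acts + [1.0 / n_prio] * n_prio if n_prio else acts


class GeneratorConfig(BaseModel):
    """Conditions of the simulated coincident (scripted + in-the-wild) study."""

    model_config = ConfigDict(extra="forbid")

    n_source: int = Field(2000, gt=0)
    n_target: int = Field(2000, gt=0)
    n_subjects_per_domain: int = Field(20, gt=1)
    sample_rate: float = Field(25.0, gt=0, description="Hz")
    window_seconds: float = Field(10.0, gt=0)
    label_names: list[str] = Field(
        default_factory=lambda: list(ACTIVITY_LABELS) + list(PRIOCEPTION_LABELS))
    label_priors_source: list[float] | None = None
    label_priors_target: list[float] | None = None
    shift_magnitude: float = Field(1.0, ge=0)
    target_label_noise: float = Field(0.05, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        n = self.sample_rate * self.window_seconds
        if abs(n - round(n)) > 1e-9 or round(n) <= 0:
            raise ValueError("sample_rate * window_seconds must be a positive integer")
        for name in self.label_names:
            if name not in ACTIVITY_LABELS and name not in PRIOCEPTION_LABELS:
                raise ValueError(f"unknown context label {name!r}")
        if not any(l in PRIOCEPTION_LABELS for l in self.label_names):
            raise ValueError("at least one prioception label is required")
        if not any(l in ACTIVITY_LABELS for l in self.label_names):
            raise ValueError("at least one activity label is required")
        if self.label_priors_source is None:
            self.label_priors_source = _default_priors(
                SCRIPTED_ACTIVITY_PRIORS, tuple(self.label_names))
        if self.label_priors_target is None:
            self.label_priors_target = _default_priors(
                WILD_ACTIVITY_PRIORS, tuple(self.label_names))
        for priors in (self.label_priors_source, self.label_priors_target):
            if len(priors) != len(self.label_names):
                raise ValueError("label priors must match label_names in length")
            if any(p < 0 or p > 1 for p in priors):
                raise ValueError("label priors must lie in [0, 1]")
        return self

    @property
    def window_samples(self) -> int:
        return int(round(self.sample_rate * self.window_seconds))

    @property
    def activity_names(self) -> list[str]:
        return [l for l in self.label_names if l in ACTIVITY_LABELS]

    @property
    def prioception_names(self) -> list[str]:
        return [l for l in self.label_names if l in PRIOCEPTION_LABELS]


class ModelConfig(BaseModel):
    """Dual-view network architecture."""

    model_config = ConfigDict(extra="forbid")

    mlp_hidden: int = Field(16, gt=0)
    head_hidden: int = Field(32, gt=0)
    cnn_channels: list[int] = Field(default_factory=lambda: [16, 32, 64])
    cnn_combined_channels: list[int] = Field(default_factory=lambda: [16, 32, 64])
    cnn_kernel: int = Field(5, gt=0)
    cnn_strides: list[int] = Field(default_factory=lambda: [1, 1, 1])
    cnn_combined_strides: list[int] = Field(default_factory=lambda: [1, 1, 1])
    attention: bool = True
    leaky_slope: float = 0.01

    @model_validator(mode="after")
    def _validate(self) -> "ModelConfig":
        for seq in (self.cnn_channels, self.cnn_combined_channels):
            if len(seq) != 3 or any(c <= 0 for c in seq):
                raise ValueError("CNN stacks use three positive channel counts")
        if any(s <= 0 for s in self.cnn_strides + self.cnn_combined_strides):
            raise ValueError("strides must be positive")
        return self


class KernelBankConfig(BaseModel):
    """Gaussian kernel bank for the multi-kernel MMD."""

    model_config = ConfigDict(extra="forbid")

    betas: list[float] | None = None           # None -> equal weights
    bandwidths: list[float] | None = None      # None -> median heuristic
    median_multipliers: list[float] = Field(
        default_factory=lambda: [0.25, 0.5, 1.0, 2.0, 4.0])

    @model_validator(mode="after")
    def _validate(self) -> "KernelBankConfig":
        if self.bandwidths is not None and any(s <= 0 for s in self.bandwidths):
            raise ValueError("bandwidths must be positive")
        if self.betas is not None:
            if any(b < 0 for b in self.betas):
                raise ValueError("kernel weights must be non-negative")
            n = len(self.bandwidths) if self.bandwidths else len(self.median_multipliers)
            if len(self.betas) != n:
                raise ValueError("betas must match the number of kernels")
        if not self.median_multipliers and self.bandwidths is None:
            raise ValueError("kernel bank must contain at least one kernel")
        return self


class MiningConfig(BaseModel):
    """Joint-fusion online triplet mining settings."""

    model_config = ConfigDict(extra="forbid")

    margin: float = Field(0.1, ge=0)
    pseudo_threshold: float = Field(0.5, gt=0, lt=1)
    refresh_every: int = Field(1, gt=0)
    per_anchor_cap: int | None = Field(None, gt=0)


class TrainConfig(BaseModel):
    """Optimization loop settings (loss schedule, batches, method switch)."""

    model_config = ConfigDict(extra="forbid")

    epochs: int = Field(30, gt=0)
    batch_size: int = Field(256, ge=2)
    lr0: float = Field(0.1, gt=0)
    lambda1: float = Field(1.0, ge=0)
    lambda_max: float = Field(1.0, ge=0)
    gamma: float = 10.0
    lr_decay_a: float = 10.0
    lr_decay_b: float = 0.75
    val_frac: float = Field(0.1, gt=0, lt=1)
    seed: int = 0
    method: str = "tripledare"

    @model_validator(mode="after")
    def _validate(self) -> "TrainConfig":
        valid = {"tripledare", "dan", "coral", "source_only"}
        if self.method not in valid and not self.method.startswith("ablation-"):
            raise ValueError(f"method must be one of {sorted(valid)} or 'ablation-<mask>'")
        return self


class RunConfig(BaseModel):
    """Top-level config: one document drives a whole pipeline run."""

    model_config = ConfigDict(extra="forbid")

    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    mining: MiningConfig = Field(default_factory=MiningConfig)
    kernels: KernelBankConfig = Field(default_factory=KernelBankConfig)
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, filling defaults for missing sections."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return RunConfig.model_validate(doc or {})


def dump_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
    return path
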