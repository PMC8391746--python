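"""YAML pipeline configuration with strict key validation.

The defaults reproduce the packaged synthetic benchmark: a
clean-dominated unlabeled training split, labeled validation/test splits
with realistic grade mixtures, a 2000-tree isolation forest with
subsample size 256, and accuracy-maximizing two-threshold calibration.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .records import ECG, KINDS

__all__ = ["PipelineConfig", "default_config", "load_config"]


@dataclass
class PipelineConfig:
    kind: str = ECG
    fs: float | None = None
    stride_s: float | None = None
    clip_k: float = 5.0
    band: tuple | None = None
    n_trees: int = 2000
    psi: int = 256
    contamination: float = 0.05
    seed: int = 0
    calibration_policy: str = "accuracy"
    alarm_policy: str = "default"
    # synthetic benchmark sizes / mixtures (see synth.DatasetConfig)
    n_train: int = 1200
    n_validation: int = 1200
    n_test: int = 1000
    train_mix: tuple = (0.90, 0.05, 0.05)
    validation_mix: tuple = (0.8734, 0.0546, 0.0720)
    test_mix: tuple = (0.8039, 0.0606, 0.1355)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"config: kind must be one of {KINDS}")
        for name in ("n_trees", "psi", "n_train", "n_validation", "n_test"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive")
        if not 0 <= self.contamination < 0.5:
            raise ValueError("config: contamination must be in [0, 0.5)")
        if self.calibration_policy != "accuracy":
            raise ValueError("config: only the 'accuracy' calibration policy exists")
        if self.alarm_policy not in ("default", "strict"):
            raise ValueError("config: alarm_policy must be 'default' or 'strict'")
        for name in ("train_mix", "validation_mix", "test_mix"):
            mix = tuple(getattr(self, name))
            setattr(self, name, mix)
            if len(mix) != 3 or abs(sum(mix) - 1) > 1e-6 or any(p < 0 for p in mix):
                raise ValueError(f"config: {name} must be 3 proportions summing to 1")

    def to_dict(self) -> dict:
        return asdict(self)


#: Benchmark grade mixtures per kind: realistic wearable-monitoring label
#: proportions (validation-style and test-style splits differ, the test
#: split being noisier).
_BENCHMARK_MIX = {
    ECG: {"validation_mix": (0.8734, 0.0546, 0.0720),
          "test_mix": (0.8039, 0.0606, 0.1355)},
    "RESP": {"validation_mix": (0.6270, 0.2450, 0.1280),
             "test_mix": (0.6749, 0.1757, 0.1494)},
}


def default_config(kind: str = ECG, **overrides) -> PipelineConfig:
    """Benchmark config for a channel kind, with kind-appropriate grade
    mixtures; keyword overrides are applied on top."""
    params = dict(kind=kind, **_BENCHMARK_MIX[kind])
    if kind == "RESP":
        params.update(n_train=900, n_validation=1200, n_test=800)
    params.update(overrides)
    return PipelineConfig(**params)


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected with the offending
    key path in the message."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path}: top level must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
    for name in ("train_mix", "validation_mix", "test_mix", "band"):
        if name in data and data[name] is not None:
            data[name] = tuple(data[name])
    return PipelineConfig(**data)
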