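"""Run configuration: a YAML-serializable record driving the CLI pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .fitting import OptimizerConfig
from .task import TaskDesign

_DESIGN_FIELDS = set(TaskDesign.__dataclass_fields__)
_OPT_FIELDS = set(OptimizerConfig.__dataclass_fields__)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, fully serializable for provenance."""

    n_participants: int = 184
    model_id: str = "M3"
    models: tuple[str, ...] = ("M0", "M1", "M2", "M3", "M4", "M5")
    design: TaskDesign = field(default_factory=TaskDesign)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    n_datasets: int = 1000
    n_agents_per_model: int = 50
    master_seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs = dict(raw)
    if "design" in kwargs:
        bad = set(kwargs["design"]) - _DESIGN_FIELDS
        if bad:
            raise ValueError(f"{path}: unknown design keys {sorted(bad)}")
        kwargs["design"] = TaskDesign(**kwargs["design"])
    if "optimizer" in kwargs:
        bad = set(kwargs["optimizer"]) - _OPT_FIELDS
        if bad:
            raise ValueError(f"{path}: unknown optimizer keys {sorted(bad)}")
        kwargs["optimizer"] = OptimizerConfig(**kwargs["optimizer"])
    if "models" in kwargs:
        kwargs["models"] = tuple(kwargs["models"])
    return RunConfig(**kwargs)
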