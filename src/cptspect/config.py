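"""Declarative run configuration: defaults, YAML round-trip, validation.

Stage parameters default to the reference task values: 480 trials at a
985 ms SOA with 100 targets, a 1135 ms response window, a 60% accuracy
floor, 8 CoV blocks of 60 trials, 44 interior spline knots, alpha 0.05 and
a Bonferroni family of 6 pairwise comparisons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cptspect.simulate import GroupSpec, TaskSpec, ConfigurationError


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "cptspect_run"
    input_trials: str | None = None  # when set, the simulate stage is skipped
    task: dict = field(default_factory=dict)
    groups: list = field(default_factory=list)
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "preprocess": True,
            "vigilance": True,
            "spectrum": True,
            "fda": True,
        }
    )
    response_window: float = 1135.0
    min_accuracy: float = 0.60
    n_blocks: int = 8
    block_size: int = 60
    reference_group: str = "HC"
    oversampling: float = 1.0
    detrend: bool = True
    n_interior_knots: int = 44
    alpha: float = 0.05
    bonferroni_m: int = 6
    n_eval: int = 200

    def task_spec(self) -> TaskSpec:
        return TaskSpec(**self.task)

    def group_specs(self) -> list[GroupSpec]:
        out = []
        for g in self.groups:
            g = dict(g)
            out.append(
                GroupSpec(
                    name=str(g.pop("name")),
                    n=int(g.pop("n")),
                    params=g.pop("params", {}),
                    **g,
                )
            )
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations (empty when the config is runnable)."""
    v: list[str] = []
    if not isinstance(config.seed, int) or config.seed < 0:
        v.append(f"seed must be a non-negative integer, got {config.seed!r}")
    try:
        spec = config.task_spec()
        spec.validate()
    except (TypeError, ConfigurationError) as exc:
        v.append(f"task: {exc}")
        spec = None
    if spec is not None:
        if config.response_window < spec.soa:
            v.append(
                f"response_window {config.response_window} < soa {spec.soa}"
            )
        if config.n_blocks * config.block_size != spec.n_trials:
            v.append(
                f"n_blocks ({config.n_blocks}) x block_size "
                f"({config.block_size}) != n_trials ({spec.n_trials})"
            )
    if not (0.0 <= config.min_accuracy <= 1.0):
        v.append(f"min_accuracy must lie in [0, 1], got {config.min_accuracy}")
    if config.oversampling <= 0:
        v.append("oversampling must be positive")
    if not (0.0 < config.alpha < 1.0):
        v.append(f"alpha must lie in (0, 1), got {config.alpha}")
    if config.n_interior_knots < 0:
        v.append("n_interior_knots must be non-negative")
    if config.bonferroni_m < 1:
        v.append("bonferroni_m must be >= 1")
    if config.n_eval < 2:
        v.append("n_eval must be >= 2")
    if config.input_trials is not None:
        if not Path(config.input_trials).exists():
            v.append(f"input trial log not found: {config.input_trials}")
    elif config.stages.get("simulate", True):
        if not config.groups:
            v.append("no groups configured and no input_trials given")
        for g in config.groups:
            if int(g.get("n", 0)) < 1:
                v.append(f"group {g.get('name')!r} is empty")
    return v
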