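"""Run configuration: validated YAML in, fully-defaulted settings out."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .models import MODEL_NAMES, build_model

__all__ = ["RunConfig", "read_config", "write_config"]

_PROTOCOL_KINDS = ("none", "step", "pulse", "periodic")


@dataclass
class RunConfig:
    """Validated settings for one analysis run."""

    model: str = "pfeuty"
    mu: float | None = None
    overrides: dict[str, float] = field(default_factory=dict)
    protocol: dict = field(default_factory=lambda: {"kind": "none"})
    n_generations: int = 6
    t_points: int = 50
    delta: float = 0.01
    steady_tol: float = 1e-8
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")
        if self.mu is not None and not self.mu > 0:
            raise ValueError("mu must be positive")
        if self.n_generations < 1 or self.t_points < 1:
            raise ValueError("n_generations and t_points must be >= 1")
        if not 0 < self.delta < 0.5:
            raise ValueError("delta (log-parameter step) must be in (0, 0.5)")
        kind = self.protocol.get("kind", "none")
        if kind not in _PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {kind!r}")
        # building the model validates every parameter override by name
        model = build_model(self.model, mu=self.mu, overrides=self.overrides)
        for name, _ in self.protocol.get("targets", []):
            if name not in model.params:
                raise ValueError(f"protocol targets unknown parameter {name!r}")

    def build_model(self):
        return build_model(self.model, mu=self.mu, overrides=self.overrides)


def read_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "protocol" in raw and raw["protocol"] is not None:
        proto = raw["protocol"]
        targets = proto.get("targets", [])
        proto["targets"] = [tuple(t) for t in targets]
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    data = asdict(cfg)
    data["protocol"] = dict(data["protocol"])
    data["protocol"]["targets"] = [list(t) for t in data["protocol"].get("targets", [])]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
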