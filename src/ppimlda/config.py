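"""Pipeline configuration: one YAML file drives every stage.

Every analysis constant has an explicit field with its conventional default —
4 mm seed-sphere radius, gray-matter threshold 0.25 (strict), 1% selection
fraction, trace/p shrinkage target — so an emitted config is a complete,
reproducible record of a run.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .synthetic import SimConfig


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    #: "maps" simulates subject-level interaction maps directly; "timeseries"
    #: simulates full BOLD runs and estimates the maps with the PPI GLM
    mode: str = "maps"
    gm_threshold: float = 0.25
    contrast: str = "interaction"  # or "physio": condition-independent control
    fraction: float = 0.01
    ranking: str = "weight"
    lambda_bar_rule: str = "trace_p"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if self.mode not in ("maps", "timeseries"):
            raise ValueError(f"mode must be 'maps' or 'timeseries', got {self.mode!r}")
        if self.contrast not in ("interaction", "physio"):
            raise ValueError(f"contrast must be 'interaction' or 'physio', got {self.contrast!r}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """SHA-256 of the canonical YAML serialisation (embedded in reports)."""
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
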