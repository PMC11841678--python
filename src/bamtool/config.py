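"""Pipeline configuration: a single versioned JSON file, flags override."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict

from .errors import InputError

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, round-trippable through JSON."""

    fragment_tol: float = 0.02
    network_threshold: float = 0.8
    adduct: str = "[M+H]+"
    scorer_name: str = "default"
    seed: int = 0
    paths: Dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.fragment_tol <= 0:
            raise InputError(f"fragment_tol must be positive, got {self.fragment_tol}")
        if not 0 < self.network_threshold <= 1:
            raise InputError(
                f"network_threshold must be in (0, 1], got {self.network_threshold}"
            )
        if self.scorer_name not in ("default", "uniform"):
            raise InputError(f"unknown scorer {self.scorer_name!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise InputError(f"unsupported config schema version {version}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        try:
            return cls.from_dict(json.loads(path.read_text()))
        except json.JSONDecodeError as exc:
            raise InputError(f"config file {path} is not valid JSON: {exc}") from exc
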