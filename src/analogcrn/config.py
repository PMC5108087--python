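"""Run configuration, result serialisation and provenance metadata.

Configs are plain JSON with a small validated schema; unknown keys are
rejected so that typos fail loudly.  Every result file embeds the seed,
solver options and metric conventions that produced it, plus a hash of
the originating config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "ConfigError", "load_config", "write_results",
           "config_hash"]

TASKS = ("compile", "count", "simulate", "fit-regime", "step-test",
         "montecarlo", "critical-delta", "fixtures")

_FIELDS = {
    "task": str,
    "circuit": (str, dict, type(None)),
    "system": (str, dict, type(None)),
    "seed": (int, type(None)),
    "solver": (dict, type(None)),
    "inputs": (dict, type(None)),
    "delta": (float, int, type(None)),
    "n_samples": (int, type(None)),
    "output_dir": (str, type(None)),
}

_SEED_REQUIRED = ("montecarlo", "critical-delta", "fit-regime", "fixtures")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    task: str
    circuit: str | dict | None = None
    system: str | dict | None = None
    seed: int | None = None
    solver: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    delta: float | None = None
    n_samples: int | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if self.task not in TASKS:
            raise ConfigError(f"unknown task {self.task!r}; one of {TASKS}")
        if self.task in _SEED_REQUIRED and self.seed is None:
            raise ConfigError(f"task {self.task!r} requires an explicit seed")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Read and validate a JSON run configuration."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a JSON object")
    unknown = set(data) - set(_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        types = _FIELDS[key]
        if not isinstance(value, types):
            raise ConfigError(
                f"config field {key!r}: expected {types}, got {type(value)}")
    if "task" not in data:
        raise ConfigError("config is missing the required 'task' field")
    if data.get("solver") is None:
        data.pop("solver", None)
    if data.get("inputs") is None:
        data.pop("inputs", None)
    return RunConfig(**data)


def config_hash(config: RunConfig | dict) -> str:
    payload = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_results(payload: dict, path, metadata: dict | None = None,
                  time_series: dict | None = None) -> list[Path]:
    """Write a JSON result (and optional CSV time series next to it).

    ``metadata`` (seed, solver options, conventions, config hash...) is
    embedded under a "meta" key.  Time series are written as
    comma-separated CSV with a header row and no index column.
    """
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    doc = {"meta": metadata or {}, **payload}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, cls=_Encoder)
    written.append(path)
    for name, table in (time_series or {}).items():
        csv_path = path.with_name(f"{path.stem}_{name}.csv")
        pd.DataFrame(table).to_csv(csv_path, index=False)
        written.append(csv_path)
    return written
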