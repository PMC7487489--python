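"""Run configuration: YAML schema, validation and normalisation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from mignet.errors import ConfigError, InputError

_METHODS = ("welch", "moderated")
_POLICIES = ("majority", "lexicographic", "all_paths_mean")


@dataclasses.dataclass
class RunConfig:
    """Validated parameters of a full pipeline run.

    Paths may stay None for stages that are not executed (e.g. no mRNA
    matrix when only the miRNA side is analysed).
    """

    mirna_expression: str | None = None
    mrna_expression: str | None = None
    groups: str | None = None
    edges: str | None = None
    targets: str | None = None
    cell_fate: str | None = None
    out_dir: str = "mignet_out"
    alpha: float = 0.05
    fc_threshold: float = 1.5
    pseudocount: float = 1.0
    method: str = "welch"
    policy: str = "majority"
    strict: bool = False
    top_k: int = 50
    max_depth: int | None = None
    readjust_cellfate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise ConfigError("fc_threshold must exceed 1")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be nonnegative")
        if self.method not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}")
        if self.policy not in _POLICIES:
            raise ConfigError(f"policy must be one of {_POLICIES}")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1 when set")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the normalised configuration (for the run manifest)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields all defaults; unknown keys are rejected by
    name so typos never silently fall back to a default.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
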