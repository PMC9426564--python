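"""Run configuration: defaults, YAML file, and flag overrides.

Precedence is CLI flag > config file > built-in default.  Every field is
validated against the preconditions of the module it feeds, at load time,
so a bad value fails before any work starts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    k: int = 21
    metric: str = "ab_jaccard"
    min_abundance: int = 1
    k_min: int = 2
    k_max: int | None = None          # None -> n - 1 ("auto")
    suboptimal_target: int | None = None
    strategies: list[str] = field(
        default_factory=lambda: ["SASB", "SACB", "CASB", "CACB"])
    min_contig_len: int = 1500
    breadth_min: float = 0.3
    ani_thresholds: list[float] = field(default_factory=lambda: [0.95, 0.99])
    af_min: float = 0.6
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 11 <= self.k <= 31:
            raise ValueError(f"k must be in [11, 31], got {self.k}")
        if self.metric not in ("ab_jaccard", "bray_curtis"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.min_abundance < 1:
            raise ValueError("min_abundance must be >= 1")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max is not None and self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        for s in self.strategies:
            if s not in ("SASB", "SACB", "CASB", "CACB"):
                raise ValueError(f"unknown strategy {s!r}")
        if self.min_contig_len < 1:
            raise ValueError("min_contig_len must be positive")
        if not 0 <= self.breadth_min <= 1:
            raise ValueError("breadth_min must be in [0, 1]")
        for t in self.ani_thresholds:
            if not 0 < t < 1:
                raise ValueError(f"ani threshold {t} outside (0, 1)")
        if not 0 <= self.af_min <= 1:
            raise ValueError("af_min must be in [0, 1]")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"unknown log level {self.log_level!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_FIELD_NAMES = {f.name for f in fields(RunConfig)}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Resolve a RunConfig from defaults, an optional YAML file and flags.

    Unknown keys raise an error listing the valid ones; invalid values
    raise the precondition they violate.  ``overrides`` entries with value
    None are treated as "not given".
    """
    values: dict = {}
    if path is not None:
        with open(path) as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(loaded) - _FIELD_NAMES
        if unknown:
            raise ValueError(
                f"{path}: unknown config keys {sorted(unknown)}; "
                f"valid keys: {sorted(_FIELD_NAMES)}"
            )
        values.update(loaded)
    for key, val in (overrides or {}).items():
        if key not in _FIELD_NAMES:
            raise ValueError(f"unknown config key {key!r}; valid: {sorted(_FIELD_NAMES)}")
        if val is not None:
            values[key] = val
    return RunConfig(**values)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved config beside outputs for provenance."""
    with open(path, "w") as out:
        yaml.safe_dump(config.to_dict(), out, sort_keys=True)
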