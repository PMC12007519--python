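"""YAML run configuration for the pipeline CLI.

All sampling ranges default to the values baked into :mod:`mrsynth.constants`;
the config controls the grid, counts, seeds, paths, and injection fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from . import constants as C
from .assembly import DatasetConfig


class ConfigError(ValueError):
    """Configuration schema violation, reporting the offending field path."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "mrsynth_out"
    b0_values: tuple = C.DEFAULT_B0_TESLA
    te_values: tuple = C.DEFAULT_TE_SECONDS
    examples_per_cell: int = C.DEFAULT_EXAMPLES_PER_CELL
    cohorts: tuple = ("healthy", "clinical")
    subsample_factor: int = 4
    n_points: int = 4096
    p_oov: float = C.OOV_INJECTION_PROBABILITY
    log_level: str = "INFO"

    def dataset_config(self) -> DatasetConfig:
        return DatasetConfig(
            b0_values=tuple(self.b0_values),
            te_values=tuple(self.te_values),
            examples_per_cell=self.examples_per_cell,
            cohorts=tuple(self.cohorts),
            subsample_factor=self.subsample_factor,
            n_points=self.n_points,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def provenance(self) -> dict:
        """Config embedded in artifacts: content-determining fields only
        (paths and logging excluded, so identical seeds give identical
        bytes wherever the artifacts are written)."""
        out = asdict(self)
        out.pop("out_dir", None)
        out.pop("log_level", None)
        return out


_VALIDATORS = {
    "seed": lambda v: isinstance(v, int) and 0 <= v,
    "out_dir": lambda v: isinstance(v, str) and v,
    "b0_values": lambda v: isinstance(v, (list, tuple)) and all(0 < float(x) for x in v),
    "te_values": lambda v: isinstance(v, (list, tuple)) and all(0 < float(x) < 1 for x in v),
    "examples_per_cell": lambda v: isinstance(v, int) and v > 0,
    "cohorts": lambda v: isinstance(v, (list, tuple))
    and all(c in C.CONCENTRATION_TABLE for c in v),
    "subsample_factor": lambda v: isinstance(v, int) and v >= 1,
    "n_points": lambda v: isinstance(v, int) and v >= 64,
    "p_oov": lambda v: isinstance(v, (int, float)) and 0.0 <= v <= 1.0,
    "log_level": lambda v: isinstance(v, str),
}


def validate(raw: dict) -> RunConfig:
    """Validate a raw mapping against the schema; errors name the field."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key in raw:
        if key not in _VALIDATORS:
            raise ConfigError(f"{key}: unknown configuration field")
    for key, check in _VALIDATORS.items():
        if key in raw and not check(raw[key]):
            raise ConfigError(f"{key}: invalid value {raw[key]!r}")
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate(raw)
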