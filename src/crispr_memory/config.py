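"""Parameter registry: every numeric threshold used by the pipeline.

Defaults follow the analysis protocol this package implements (95/95
identity/coverage protospacer matching, 90/90 repeat clustering, 100 bp
repeat masking margin, 15 kb / 4 kb neighborhoods, 12%/1.5% sliding
windows, 2000 bootstraps, alignment scores 1/-2/-2/-1, 200 community
trials).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from crispr_memory.errors import ConfigError

__all__ = ["Parameters", "load_config"]

# field name -> (is_fraction, must_be_positive)
_FRACTION_FIELDS = {
    "protospacer_min_identity",
    "protospacer_min_coverage",
    "repeat_cluster_identity",
    "repeat_cluster_coverage",
    "spacer_derep_identity",
    "neighborhood_score_ratio",
    "window_width_frac",
    "window_step_frac",
    "ci_level",
}
_POSITIVE_INT_FIELDS = {
    "repeat_mask_margin",
    "neighborhood_flank_target",
    "neighborhood_flank_abundance",
    "min_spacers_oriented",
    "min_arrays_per_subtype",
    "min_spacer_samples",
    "n_bootstraps",
    "community_trials",
}


@dataclass
class Parameters:
    """All tunable thresholds of the pipeline, with validated defaults."""

    protospacer_min_identity: float = 0.95
    protospacer_min_coverage: float = 0.95
    repeat_cluster_identity: float = 0.90
    repeat_cluster_coverage: float = 0.90
    spacer_derep_identity: float = 1.00
    repeat_mask_margin: int = 100
    neighborhood_flank_target: int = 7500
    neighborhood_flank_abundance: int = 2000
    neighborhood_score_ratio: float = 0.9
    neighborhood_evalue_analog: float = 1e-8
    window_width_frac: float = 0.12
    window_step_frac: float = 0.015
    min_spacers_oriented: int = 6
    min_arrays_per_subtype: int = 25
    min_spacer_samples: int = 2
    n_bootstraps: int = 2000
    ci_level: float = 0.95
    align_match: int = 1
    align_mismatch: int = -2
    align_gap_open: int = -2
    align_gap_extend: int = -1
    community_trials: int = 200
    promiscuity_cap: int = 1000
    promiscuity_ratio: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _FRACTION_FIELDS:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        for name in _POSITIVE_INT_FIELDS:
            value = getattr(self, name)
            if not (isinstance(value, int) and value > 0):
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.align_match <= 0:
            raise ConfigError(f"align_match must be > 0, got {self.align_match!r}")
        for name in ("align_mismatch", "align_gap_open", "align_gap_extend"):
            if getattr(self, name) > 0:
                raise ConfigError(f"{name} must be <= 0, got {getattr(self, name)!r}")
        if self.neighborhood_evalue_analog <= 0:
            raise ConfigError("neighborhood_evalue_analog must be > 0")
        if self.window_step_frac > self.window_width_frac:
            raise ConfigError("window_step_frac must not exceed window_width_frac")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "Parameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
        return cls(**dict(mapping))


def load_config(path: str | Path) -> Parameters:
    """Load a YAML/JSON parameter file; absent keys fall back to defaults.

    Raises
    ------
    ConfigError
        If the file cannot be parsed, contains unknown keys, or holds an
        out-of-range value.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must hold a mapping, got {type(data).__name__}")
    return Parameters.from_mapping(data)
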