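"""Pipeline configuration: a single YAML file with every analysis threshold.

All conventional thresholds of the screen surface here as named keys with
their conventional defaults: the 0.05 significance level, the
more-than-three-event-reports filter for model predictors, the 0.95
confidence level of the Woolf interval and the 0.9 Spearman rho**2
collinearity cut-off.  Unknown keys are rejected so that typos fail before
any computation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """The configuration file is invalid."""


@dataclass
class PipelineConfig:
    """Validated settings for an end-to-end run."""

    demo_path: str = ""
    drug_path: str = ""
    reac_path: str = ""
    delimiter: str = ","
    encoding: str = "utf-8"
    output_dir: str = "pvscreen-output"

    event_term: str = "hiccups"
    target_drug: str = "dexamethasone"
    synonym_map: dict[str, str] = field(default_factory=dict)
    anticancer_drugs: list[str] = field(default_factory=list)

    alpha: float = 0.05
    min_reports: int = 3
    ci_level: float = 0.95
    collinearity_threshold: float = 0.9
    t_test_variant: str = "welch"
    continuity_correction: bool = False
    screen_unit: str = "record"
    model_unit: str = "case"
    orphan_policy: str = "drop"

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path!s} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {unknown}")
        config = cls(**raw)
        config.validate()
        return config

    def validate(self, require_inputs: bool = False) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.ci_level < 1:
            raise ConfigError(f"ci_level must be in (0,1), got {self.ci_level}")
        if self.min_reports < 0:
            raise ConfigError("min_reports must be >= 0")
        if not 0 < self.collinearity_threshold <= 1:
            raise ConfigError("collinearity_threshold must be in (0,1]")
        if self.t_test_variant not in ("welch", "pooled"):
            raise ConfigError(f"t_test_variant must be 'welch' or 'pooled'")
        if self.screen_unit not in ("record", "case"):
            raise ConfigError("screen_unit must be 'record' or 'case'")
        if self.model_unit not in ("record", "case"):
            raise ConfigError("model_unit must be 'record' or 'case'")
        if self.orphan_policy not in ("drop", "error"):
            raise ConfigError("orphan_policy must be 'drop' or 'error'")
        if not self.event_term:
            raise ConfigError("event_term must be non-empty")
        if require_inputs:
            for name in ("demo_path", "drug_path", "reac_path"):
                value = getattr(self, name)
                if not value:
                    raise ConfigError(f"{name} is required")
                if not Path(value).exists():
                    raise ConfigError(f"{name}: no such file {value!r}")
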