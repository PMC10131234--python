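"""Structured pipeline configuration (YAML-backed).

One config object drives the whole pipeline: the synthetic generator (or the
paths of real input tables), the disruption profile to inject, the discovery
threshold and topic rules, the group definitions to measure, the key months,
and reporting options.  The merged config is hashed into the run manifest so
any output file can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .discovery import DiscoveryConfig, TopicRule
from .measures import RecoveryThresholds
from .synthetic import DisruptionProfile, SyntheticConfig
from .terminology import GroupDefinition

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs, in one (hashable) place."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    disruption: DisruptionProfile | None = field(default_factory=DisruptionProfile)
    #: restrict the injected disruption to codes with this prefix (None = all)
    disruption_prefix: str | None = None
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    groups: tuple[GroupDefinition, ...] = ()
    key_months: tuple[str, ...] = ("2020-02", "2020-04", "2020-12")
    quantile_rule: str = "linear"
    disruption_start: str | None = "2020-04"
    recovery_thresholds: RecoveryThresholds = field(default_factory=RecoveryThresholds)
    charts: bool = True
    chart_format: str = "svg"
    max_chart_subjects: int = 6

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticConfig(**_tupled(raw.pop("synthetic")))
        if "disruption" in raw:
            d = raw.pop("disruption")
            kwargs["disruption"] = None if d is None else DisruptionProfile(**d)
        if "discovery" in raw:
            d = dict(raw.pop("discovery"))
            rules = tuple(TopicRule(**_tupled(r)) for r in d.pop("topic_rules", ()))
            kwargs["discovery"] = DiscoveryConfig(
                topic_rules=rules, **_tupled(d)
            )
        if "groups" in raw:
            kwargs["groups"] = tuple(
                GroupDefinition(**_tupled(g)) for g in raw.pop("groups")
            )
        if "recovery_thresholds" in raw:
            kwargs["recovery_thresholds"] = RecoveryThresholds(
                **raw.pop("recovery_thresholds")
            )
        for k in (
            "disruption_prefix", "key_months", "quantile_rule", "disruption_start",
            "charts", "chart_format", "max_chart_subjects",
        ):
            if k in raw:
                v = raw.pop(k)
                kwargs[k] = tuple(v) if k == "key_months" else v
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.from_dict(raw)


def config_hash(cfg: PipelineConfig) -> str:
    """SHA-256 of the canonical JSON form of the config (manifest key)."""
    canonical = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()
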