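"""Pipeline configuration: one YAML file with per-command sections.

Unknown keys are rejected with a warning naming the offending field,
so typos do not silently fall back to defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from trusscast.harvest import IntegrationRule
from trusscast.thermal import ForecastHyperparameters, QCConfig
from trusscast.tracking import TrackerConfig


@dataclass
class EvalSettings:
    lead_weeks: int = 5
    representative: str = "midpoint"  # earliest | midpoint | latest
    mwf_records: bool = True  # snap synthetic records to Mon/Wed/Fri

    def __post_init__(self) -> None:
        if self.representative not in ("earliest", "midpoint", "latest"):
            raise ValueError(f"unknown representative date {self.representative!r}")


@dataclass
class ScenarioSettings:
    """Defaults of the synthetic experiment (7 trusses, 2-year sensor log)."""

    n_trusses: int = 7
    n_flowers: int = 4
    jitter_sd_px: float = 2.0
    drop_prob: float = 0.0
    nonfruit_prob: float = 0.0
    frames_per_day: int = 1
    temp_start: str = "2018-09-01"
    temp_end: str = "2021-03-31"
    train_end: str = "2020-08-31"  # forecaster trains on the first two years
    bloom_start: str = "2020-09-01"
    noise_sd: float = 2.0
    outlier_rate: float = 0.001
    missing_span_rate: float = 0.5


@dataclass
class PipelineConfig:
    paths: dict = field(default_factory=dict)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    forecaster: ForecastHyperparameters = field(default_factory=ForecastHyperparameters)
    rule: IntegrationRule = field(default_factory=IntegrationRule)
    evaluation: EvalSettings = field(default_factory=EvalSettings)
    scenario: ScenarioSettings = field(default_factory=ScenarioSettings)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, source=str(path))

    @classmethod
    def from_dict(cls, raw: dict, source: str = "<dict>") -> "PipelineConfig":
        sections = {
            "tracker": TrackerConfig,
            "qc": QCConfig,
            "forecaster": ForecastHyperparameters,
            "rule": IntegrationRule,
            "evaluation": EvalSettings,
            "scenario": ScenarioSettings,
        }
        known_top = set(sections) | {"paths", "seed"}
        for key in raw:
            if key not in known_top:
                warnings.warn(f"{source}: unknown config section {key!r} ignored")
        kwargs: dict = {"paths": raw.get("paths", {}) or {}, "seed": int(raw.get("seed", 0))}
        for name, klass in sections.items():
            sub = raw.get(name, {}) or {}
            valid = {f.name for f in fields(klass)}
            for key in sub:
                if key not in valid:
                    warnings.warn(f"{source}: unknown key {name}.{key} ignored")
            kwargs[name] = klass(**{k: v for k, v in sub.items() if k in valid})
        return cls(**kwargs)
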