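"""Run configuration: one YAML-loadable object driving the whole pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from .synthetic import (
    LatentMobilityModel,
    PopulationSpec,
    ValidationError,
    default_latent_model,
)
from .survey import ResponseModel

__all__ = ["RunConfig", "default_config", "load_config"]

DEFAULT_STRINGENCY_BREAKPOINTS = [
    ("2019-12-30", 2.0),
    ("2020-03-16", 82.0),
    ("2020-04-14", 70.0),
    ("2020-05-01", 55.0),
    ("2020-06-15", 38.0),
    ("2020-09-14", 48.0),
    ("2020-10-12", 55.0),
    ("2020-11-03", 70.0),
    ("2020-11-17", 80.0),
    ("2020-12-07", 65.0),
    ("2020-12-26", 80.0),
    ("2021-02-08", 62.0),
]


@dataclass
class LockdownConfig:
    """A region-targeted partial lockdown: extra stringency points applied
    to the treated regions during the window.  Defines the DiD design."""

    regions: list[str] = field(default_factory=lambda: ["east"])
    start: str = "2020-11-03"
    end: str = "2020-12-13"
    extra_stringency: float = 20.0
    pre_start: str = "2020-09-07"


@dataclass
class GsmConfig:
    tower_spacing_km: float = 1.0
    event_rate_per_hour: float = 0.6
    coverage_prob: float = 0.8
    tower_jitter_sd_km: float = 0.35
    min_events: int = 1
    rog_share_threshold_km: float = 0.5


@dataclass
class GpsConfig:
    optin_prob: float = 0.4
    alpha: float = 0.5  # visit-count vs duration blend
    baseline_window_start: str = "2020-01-03"
    baseline_window_end: str = "2020-02-06"
    invert_residential: bool = False


@dataclass
class HarmonizeConfig:
    baseline_week: str = "2020-03-23"
    min_days: int = 4
    moving_average: bool = False
    moving_average_window: int = 7


@dataclass
class RunConfig:
    seed: int = 0
    start_date: str = "2019-12-30"
    end_date: str = "2021-03-14"
    population: PopulationSpec = field(default_factory=lambda: PopulationSpec(n_persons=500))
    population_mode: str = "quota"
    latent_model: LatentMobilityModel = field(default_factory=default_latent_model)
    stringency_breakpoints: list = field(
        default_factory=lambda: list(DEFAULT_STRINGENCY_BREAKPOINTS)
    )
    lockdown: LockdownConfig | None = field(default_factory=LockdownConfig)
    gsm: GsmConfig = field(default_factory=GsmConfig)
    gps: GpsConfig = field(default_factory=GpsConfig)
    survey: ResponseModel = field(default_factory=ResponseModel)
    harmonize: HarmonizeConfig = field(default_factory=HarmonizeConfig)
    first_wave_start: str = "2020-03-23"
    weighting_targets: dict | None = None  # defaults to the population margins

    def validate(self) -> None:
        import pandas as pd

        self.population.validate()
        self.latent_model.validate()
        start, end = pd.Timestamp(self.start_date), pd.Timestamp(self.end_date)
        if end <= start:
            raise ValidationError("end_date must be after start_date")
        for d in (
            self.harmonize.baseline_week,
            self.first_wave_start,
            self.gps.baseline_window_start,
            self.gps.baseline_window_end,
        ):
            if not (start <= pd.Timestamp(d) <= end):
                raise ValidationError(f"configured date {d} outside simulated range")

    def targets(self) -> dict:
        return self.weighting_targets or self.population.margins


def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def _merge_dataclass(obj, overrides: dict):
    for key, value in overrides.items():
        if not hasattr(obj, key):
            raise ValidationError(f"unknown config key '{key}' for {type(obj).__name__}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _merge_dataclass(current, value)
        else:
            setattr(obj, key, value)
    return obj


def load_config(path: str | None = None, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file (flat nested mapping mirroring the
    dataclass fields), then apply explicit overrides.  Missing keys keep
    their defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "population" in raw:
            pop = raw.pop("population")
            _merge_dataclass(cfg.population, pop)
        if "lockdown" in raw:
            ld = raw.pop("lockdown")
            if ld is None:
                cfg.lockdown = None
            else:
                if cfg.lockdown is None:
                    cfg.lockdown = LockdownConfig()
                _merge_dataclass(cfg.lockdown, ld)
        if "latent_model" in raw:
            lm = raw.pop("latent_model")
            for key, value in lm.items():
                if not hasattr(cfg.latent_model, key):
                    raise ValidationError(f"unknown latent model key '{key}'")
                current = getattr(cfg.latent_model, key)
                if isinstance(current, dict) and isinstance(value, dict):
                    current.update(value)
                else:
                    setattr(cfg.latent_model, key, value)
        _merge_dataclass(cfg, raw)
    if overrides:
        _merge_dataclass(cfg, overrides)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    """Write the effective configuration as YAML (audit copy in the run dir)."""

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if hasattr(obj, "item"):  # numpy scalars shadow the builtin types
            return obj.item()
        if isinstance(obj, (int, float, str, bool)) or obj is None:
            return obj
        return str(obj)

    with open(path, "w") as fh:
        yaml.safe_dump(encode(cfg), fh, sort_keys=False)
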