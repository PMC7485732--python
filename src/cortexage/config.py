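"""Pipeline configuration: YAML round-trip of all stage settings."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acquisition import AcquisitionProtocol
from .aging import AGE_SD_REFERENCE, CORTICAL_REFERENCE, AgingModel, calibrate_aging_model
from .phantom import GeometryConfig

__all__ = ["CohortSettings", "StatsSettings", "AgingSettings", "PipelineConfig"]


def _tupled(value):
    return tuple(value) if isinstance(value, list) else value


def _build(cls, payload: dict):
    """Instantiate a dataclass from a dict, casting lists back to tuples."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{k: _tupled(v) for k, v in payload.items()})


@dataclass(frozen=True)
class CohortSettings:
    n: int = 40
    age_range: tuple[float, float] = (19.0, 71.0)
    sex_counts: tuple[int, int] = (19, 21)  # (male, female)


@dataclass(frozen=True)
class StatsSettings:
    n_perm: int = 1000
    threshold_p: float = 0.05
    cluster_alpha: float = 0.05
    smooth_fwhm_mm: float = 10.0


@dataclass(frozen=True)
class AgingSettings:
    """Calibration targets for the linear aging model."""

    targets: dict = field(default_factory=lambda: {k: dict(v) for k, v in CORTICAL_REFERENCE.items()})
    sd_age: float = AGE_SD_REFERENCE
    reference_age: float = 45.0

    def build(self) -> AgingModel:
        return calibrate_aging_model(
            self.targets, sd_age=self.sd_age, reference_age=self.reference_age
        )


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cohort: CohortSettings = field(default_factory=CohortSettings)
    aging_model: AgingSettings = field(default_factory=AgingSettings)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    stats: StatsSettings = field(default_factory=StatsSettings)
    #: sample statistics on the ground-truth ribbon instead of the GMM one
    oracle_ribbon: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        kw = {}
        for name, sub in (
            ("cohort", CohortSettings),
            ("aging_model", AgingSettings),
            ("geometry", GeometryConfig),
            ("protocol", AcquisitionProtocol),
            ("stats", StatsSettings),
        ):
            if name in payload:
                kw[name] = _build(sub, payload.pop(name))
        kw.update(payload)
        return _build_top(cls, kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))
        return path


def _build_top(cls, kw):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(kw) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cls(**kw)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
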