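"""Pipeline configuration: one YAML file driving every stage.

Defaults mirror the published workflow settings wherever one exists (QC
thresholds 90/30/5/50, kNN k = 5, BMR 3 SD then 1 SD, 250 iterations, 95%
confidence, post-filter thresholds, 10-fold / slope 0.5-1.5 xenobiotic
screen, 5 ppm / 5 s / r > 0.7 grouping, Spearman p < 0.05 with 0.6 strong
cutoff).  Unknown keys are rejected by name so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .chem import TPHP_FORMULA
from .synthetic import GeneratorConfig
from .workflow import BmdSettings


def _nested_type(f: dataclasses.Field):
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        sample = f.default_factory()
        if dataclasses.is_dataclass(sample):
            return type(sample)
    return None


def _from_dict(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        nested = _nested_type(known[key])
        if nested is not None and isinstance(val, dict):
            kwargs[key] = _from_dict(nested, val, f"{path}.{key}")
        elif isinstance(val, list):
            kwargs[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


@dataclass
class PreprocessConfig:
    qc_presence_min: float = 90.0
    qc_rsd_max: float = 30.0
    blank_ratio_max: float = 5.0
    study_presence_min: float = 50.0
    apply_qc_rules: bool = True
    knn_k: int = 5
    pqn_reference: str = "study"  # "study" | "qc"


@dataclass
class XenoConfig:
    parent_formula: str = TPHP_FORMULA
    fold_change_factor: float = 10.0
    slope_min: float = 0.5
    slope_max: float = 1.5
    rt_tolerance_s: float = 5.0
    corr_threshold: float = 0.7
    ppm_tolerance: float = 5.0


@dataclass
class CorrelationConfig:
    p_cutoff: float = 0.05
    strong_cutoff: float = 0.6


@dataclass
class PipelineConfig:
    """Structured settings for every stage, YAML round-trippable."""

    seed: int = 0
    simulate: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bmd: BmdSettings = field(default_factory=BmdSettings)
    xeno: XenoConfig = field(default_factory=XenoConfig)
    correlation: CorrelationConfig = field(default_factory=CorrelationConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [_clean(v) for v in obj]
            return obj
        with open(path, "w") as fh:
            yaml.safe_dump(_clean(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data, "pipeline")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
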