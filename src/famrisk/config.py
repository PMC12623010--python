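"""Structured run configuration (YAML) for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from typing import List, Optional, Tuple

import yaml

from .ascertain import CodePolicy
from .errors import ConfigurationError
from .simulate import SimulationParams


@dataclass
class MatchingConfig:
    ratio: int = 2
    birth_year_window: float = 2.5
    seed: Optional[int] = None  # derived from the master seed when None

    def validate(self):
        if self.ratio < 1:
            raise ConfigurationError("matching.ratio: must be >= 1")
        if self.birth_year_window < 0:
            raise ConfigurationError("matching.birth_year_window: must be >= 0")


@dataclass
class AnalysisConfig:
    degrees: Tuple = (1, 2, 3)
    spousal: bool = True
    stratified: bool = False
    estimator: str = "marginal"  # or "mixed" (random intercept per index)

    def validate(self):
        for d in self.degrees:
            if d not in (1, 2, 3):
                raise ConfigurationError(f"analysis.degrees: invalid degree {d!r}")
        if self.estimator not in ("marginal", "mixed"):
            raise ConfigurationError(
                f"analysis.estimator: unknown estimator {self.estimator!r}")


@dataclass
class RunConfig:
    simulation: SimulationParams = field(default_factory=SimulationParams)
    policy: CodePolicy = field(default_factory=CodePolicy)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    reference_year: Optional[int] = None  # default: end of the EHR window
    output_dir: str = "famrisk_out"

    def validate(self):
        self.simulation.validate()
        self.matching.validate()
        self.analysis.validate()

    def resolved_reference_year(self) -> int:
        return (self.reference_year if self.reference_year is not None
                else self.simulation.ehr_years[1])


def _build(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{section}: unknown key {sorted(unknown)[0]!r}")
    coerced = dict(data)
    for f in fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
        if f.name in coerced and f.name in ("qualifying_codes", "exclusionary_codes"):
            coerced[f.name] = frozenset(str(c) for c in coerced[f.name])
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    cfg = RunConfig(
        simulation=_build(SimulationParams, data.get("simulation", {}), "simulation"),
        policy=_build(CodePolicy, data.get("policy", {}), "policy"),
        matching=_build(MatchingConfig, data.get("matching", {}), "matching"),
        analysis=_build(AnalysisConfig, data.get("analysis", {}), "analysis"),
        reference_year=data.get("reference_year"),
        output_dir=str(data.get("output_dir", "famrisk_out")),
    )
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig) -> str:
    """Serialize a config back to YAML (code sets as sorted lists)."""
    data = {
        "simulation": asdict(cfg.simulation),
        "policy": {
            "qualifying_codes": sorted(cfg.policy.qualifying_codes),
            "exclusionary_codes": sorted(cfg.policy.exclusionary_codes),
            "min_distinct_years": cfg.policy.min_distinct_years,
            "min_age": cfg.policy.min_age,
            "min_relatives": cfg.policy.min_relatives,
            "distinct_year_codes": cfg.policy.distinct_year_codes,
        },
        "matching": asdict(cfg.matching),
        "analysis": {**asdict(cfg.analysis), "degrees": list(cfg.analysis.degrees)},
        "reference_year": cfg.reference_year,
        "output_dir": cfg.output_dir,
    }
    for k in ("birth_year_range", "ehr_years"):
        data["simulation"][k] = list(data["simulation"][k])
    return yaml.safe_dump(data, sort_keys=True)


def with_master_seed(cfg: RunConfig, seed: int) -> RunConfig:
    """Derive all per-stage seeds from one master seed by fixed offsets."""
    sim = replace(cfg.simulation, seed=seed % 2**31)
    matching = replace(cfg.matching, seed=(seed + 1009) % 2**31)
    return replace(cfg, simulation=sim, matching=matching)
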