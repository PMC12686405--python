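"""Run configuration: a strict, YAML-backed description of a full run.

Every knob that affects numbers lives here; unknown keys are rejected
with the offending key named, so typos never silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .genes import BsrThresholds
from .sip import SipContext
from .synthetic import (CellPopulationScenario, HitTableScenario,
                        IncubationScenario, RegionNutrientConfig,
                        DEFAULT_NUTRIENT_REGIONS)


def _build(cls, data: Mapping[str, Any], path: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**{k: (tuple(v) if isinstance(v, list) and k.endswith(
            ("_window", "_range_m")) else v) for k, v in data.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RegionRateConfig:
    """Per-region rate handling: censoring policy and replicate design."""

    censoring_policy: str = "lod"        # "lod" | "zero"
    reconcile_duplicates: bool = False   # duplicate-bottle design
    depth_cutoff_m: float | None = None  # upper-water-column selection
    min_depth_m: float | None = None     # e.g. "below 80 m" selections

    def __post_init__(self):
        if self.censoring_policy not in ("lod", "zero"):
            raise ConfigError(
                f"censoring_policy must be 'lod' or 'zero', "
                f"got {self.censoring_policy!r}")


@dataclass
class StatsConfig:
    whisker_mode: str = "pct10_90"
    lod_policy: str = "lod"

    def __post_init__(self):
        if self.whisker_mode not in ("pct10_90", "iqr1_5"):
            raise ConfigError(f"unknown whisker_mode {self.whisker_mode!r}")
        if self.lod_policy not in ("lod", "half-lod", "zero"):
            raise ConfigError(f"unknown lod_policy {self.lod_policy!r}")


@dataclass
class SipRunConfig:
    natural_abundance_ratio: float = 3.7e-3
    substrate_at_percent: float = 97.0
    incubation_time_days: float = 1.0
    poisson_error_max: float = 0.05
    background_window: tuple[float, float] = (3.4e-3, 4.0e-3)
    growth_model: str = "linear"
    lod_k: float = 3.0
    lod_ratio: float | None = None       # override; else derived from background
    background_group: str = "background"

    def context(self, lod_ratio=None) -> SipContext:
        return SipContext(
            natural_abundance_ratio=self.natural_abundance_ratio,
            substrate_at_percent=self.substrate_at_percent,
            incubation_time_days=self.incubation_time_days,
            lod_ratio=self.lod_ratio if lod_ratio is None else lod_ratio,
            poisson_error_max=self.poisson_error_max,
            background_window=tuple(self.background_window),
            growth_model=self.growth_model)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, seeds included."""

    outdir: str = "run_output"
    seed: int = 0
    alpha: float = 0.05
    library_size_reads: int = 1_000_000
    incubations: list[IncubationScenario] = field(default_factory=list)
    cells: list[CellPopulationScenario] = field(default_factory=list)
    hits: HitTableScenario | None = None
    nutrient_regions: dict[str, RegionNutrientConfig] = field(
        default_factory=lambda: dict(DEFAULT_NUTRIENT_REGIONS))
    regions: dict[str, RegionRateConfig] = field(default_factory=dict)
    classifier: BsrThresholds = field(default_factory=BsrThresholds)
    sip: SipRunConfig = field(default_factory=SipRunConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def region_rate_config(self, region: str) -> RegionRateConfig:
        return self.regions.get(region, RegionRateConfig())

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        if not isinstance(data, Mapping):
            raise ConfigError("top level of the config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key in ("outdir", "seed", "alpha", "library_size_reads"):
            if key in data:
                kwargs[key] = data[key]
        if "incubations" in data:
            kwargs["incubations"] = [
                _build(IncubationScenario, d, f"incubations[{i}]")
                for i, d in enumerate(data["incubations"])]
        if "cells" in data:
            kwargs["cells"] = [
                _build(CellPopulationScenario, d, f"cells[{i}]")
                for i, d in enumerate(data["cells"])]
        if "hits" in data and data["hits"] is not None:
            kwargs["hits"] = _build(HitTableScenario, data["hits"], "hits")
        if "nutrient_regions" in data:
            kwargs["nutrient_regions"] = {
                name: _build(RegionNutrientConfig, d, f"nutrient_regions.{name}")
                for name, d in data["nutrient_regions"].items()}
        if "regions" in data:
            kwargs["regions"] = {
                name: _build(RegionRateConfig, d, f"regions.{name}")
                for name, d in data["regions"].items()}
        if "classifier" in data:
            kwargs["classifier"] = _build(BsrThresholds, data["classifier"],
                                          "classifier")
        if "sip" in data:
            kwargs["sip"] = _build(SipRunConfig, data["sip"], "sip")
        if "stats" in data:
            kwargs["stats"] = _build(StatsConfig, data["stats"], "stats")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in vars(obj).items()}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if hasattr(obj, "tolist"):
                return obj.tolist()
            return obj
        return convert(self)

    def hash(self) -> str:
        """Stable digest of the full configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    return RunConfig() if path is None else RunConfig.from_yaml(path)
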