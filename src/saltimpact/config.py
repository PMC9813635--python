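"""Run configuration: a single YAML file describing a whole study run."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError
from .events import DEFAULT_PREMATURE_FRAC_65_74
from .population import GeneratorConfig
from .scenarios import Scenario, paper_scenarios
from .uncertainty import UncertaintyConfig

DEFAULT_SBP_MODELS = ("trial_based", "population_based")
DEFAULT_HORIZONS = (2030, 2040)


@dataclass
class RunConfig:
    """Everything a full study run needs.

    The default configuration reproduces the study design: a generated
    synthetic population, the three policy scenarios, both SBP-effect
    models, horizons 2030 and 2040, and 5000 Monte Carlo iterations.
    """

    population_source: str = "generate"  # "generate" or a CSV path
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    scenarios: list[Scenario] = field(default_factory=paper_scenarios)
    sbp_models: tuple[str, ...] = DEFAULT_SBP_MODELS
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    uncertainty: UncertaintyConfig = field(default_factory=UncertaintyConfig)
    premature_frac_65_74: float = DEFAULT_PREMATURE_FRAC_65_74
    output_dir: str = "results"

    def validate(self) -> None:
        if not self.scenarios:
            raise ConfigError("scenarios must contain at least one scenario")
        if not self.horizons:
            raise ConfigError("horizons must contain at least one year")
        for variant in self.sbp_models:
            if variant not in DEFAULT_SBP_MODELS:
                raise ConfigError(
                    f"sbp_models entries must be in {DEFAULT_SBP_MODELS}, "
                    f"got {variant!r}"
                )
        if not 0.0 <= self.premature_frac_65_74 <= 1.0:
            raise ConfigError(
                f"premature_frac_65_74 must be in [0, 1], "
                f"got {self.premature_frac_65_74}"
            )
        if self.population_source != "generate" and not Path(
            self.population_source
        ).exists():
            raise ConfigError(
                f"population_source CSV not found: {self.population_source}"
            )
        for scenario in self.scenarios:
            for horizon in self.horizons:
                if horizon > scenario.end_year:
                    raise ConfigError(
                        f"horizons include {horizon} but scenario "
                        f"{scenario.name!r} ends in {scenario.end_year}"
                    )
        self.generator.validate()
        self.uncertainty.validate()

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RunConfig":
        known = {
            "population_source",
            "generator",
            "scenarios",
            "sbp_models",
            "horizons",
            "uncertainty",
            "premature_frac_65_74",
            "output_dir",
        }
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown run config field(s): {sorted(unknown)}")
        kwargs: dict = {}
        if "population_source" in mapping:
            kwargs["population_source"] = str(mapping["population_source"])
        if "generator" in mapping:
            kwargs["generator"] = GeneratorConfig.from_mapping(mapping["generator"])
        if "scenarios" in mapping:
            kwargs["scenarios"] = [
                _scenario_from_mapping(entry) for entry in mapping["scenarios"]
            ]
        if "sbp_models" in mapping:
            kwargs["sbp_models"] = tuple(mapping["sbp_models"])
        if "horizons" in mapping:
            kwargs["horizons"] = tuple(int(h) for h in mapping["horizons"])
        if "uncertainty" in mapping:
            kwargs["uncertainty"] = UncertaintyConfig.from_mapping(
                mapping["uncertainty"]
            )
        if "premature_frac_65_74" in mapping:
            kwargs["premature_frac_65_74"] = float(mapping["premature_frac_65_74"])
        if "output_dir" in mapping:
            kwargs["output_dir"] = str(mapping["output_dir"])
        config = cls(**kwargs)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        mapping = yaml.safe_load(text)
        if not isinstance(mapping, Mapping):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_mapping(mapping)


def _scenario_from_mapping(entry: Mapping) -> Scenario:
    known = {"kind", "magnitude", "achieve_year", "end_year", "name"}
    unknown = set(entry) - known
    if unknown:
        raise ConfigError(f"unknown scenario field(s): {sorted(unknown)}")
    for required in ("kind", "magnitude", "achieve_year", "end_year"):
        if required not in entry:
            raise ConfigError(f"scenario is missing required field {required!r}")
    return Scenario(
        kind=str(entry["kind"]),
        magnitude=float(entry["magnitude"]),
        achieve_year=int(entry["achieve_year"]),
        end_year=int(entry["end_year"]),
        name=str(entry.get("name", "")),
    )
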