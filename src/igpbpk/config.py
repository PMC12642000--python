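"""Validated run configuration (YAML) and the shipped defaults.

Every numeric default in ``defaults.yaml`` carries a provenance tag in a
comment: ``{published}`` for published reference values, ``{derived}`` for
values back-calculated from published summaries, ``{calibrated}`` for
values fixed once by the shipped calibration script, and ``{placeholder}``
for configurable stand-ins with no published source.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .params import DrugParams
from .pregnancy import ReferenceParams

__all__ = ["RunConfig", "DrugBlock", "PopulationBlock", "load_config", "dump_config", "default_config"]


class DrugBlock(BaseModel):
    """Analyte-specific configuration."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    clearance: float
    sigma_tight: float
    sigma_leaky: float
    ka: float | None = None
    bioavailability_im: float = 1.0
    infusion_duration: float = 1.0 / 6.0

    def drug_params(self, baseline_conc: float = 0.0) -> DrugParams:
        return DrugParams(
            clearance=self.clearance,
            sigma_tight=self.sigma_tight,
            sigma_leaky=self.sigma_leaky,
            ka=self.ka,
            bioavailability_im=self.bioavailability_im,
            baseline_conc=baseline_conc,
        )


class PopulationBlock(BaseModel):
    """Virtual-population experiment settings."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    n: int = 100
    bw_mean: float = 74.0
    bw_sd: float = 18.0
    gain_fraction: float = 0.23
    dose_per_kg: float = 0.5
    trough_time: float = 28.0
    trimester: int = 3
    seed: int = 20317


class PhysiologyBlock(BaseModel):
    """Reference 70-kg physiology."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    reference_bodyweight: float = 70.0
    plasma_volume: float = 2.6
    tight_volume: float = 8.11
    leaky_volume: float = 4.37
    lymph_volume: float = 5.2
    lymph_flow_total: float = 2.9
    sigma_lymph: float = 0.2
    leaky_flow_fraction: float = 2.0 / 3.0


class PregnancyBlock(BaseModel):
    """Trimester-specific adjustments."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    trimester_plasma_volume: dict[int, float] = {0: 2.6, 1: 2.78, 2: 3.30, 3: 3.67}
    pregnancy_bw_gain: float = 0.23
    baseline_igg: dict[int, float] = {0: 13.0, 1: 12.98, 2: 12.95, 3: 12.93}


class RunConfig(BaseModel):
    """Top-level validated configuration."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    physiology: PhysiologyBlock = PhysiologyBlock()
    pregnancy: PregnancyBlock = PregnancyBlock()
    drugs: dict[str, DrugBlock]
    population: PopulationBlock = PopulationBlock()

    def reference(self) -> ReferenceParams:
        """Merge physiology and pregnancy blocks into ReferenceParams."""
        return ReferenceParams(
            reference_bodyweight=self.physiology.reference_bodyweight,
            plasma_volume=self.physiology.plasma_volume,
            tight_volume=self.physiology.tight_volume,
            leaky_volume=self.physiology.leaky_volume,
            lymph_volume=self.physiology.lymph_volume,
            lymph_flow_total=self.physiology.lymph_flow_total,
            sigma_lymph=self.physiology.sigma_lymph,
            leaky_flow_fraction=self.physiology.leaky_flow_fraction,
            trimester_plasma_volume=dict(self.pregnancy.trimester_plasma_volume),
            pregnancy_bw_gain=self.pregnancy.pregnancy_bw_gain,
            baseline_igg=dict(self.pregnancy.baseline_igg),
        )

    def drug_block(self, analyte: str) -> DrugBlock:
        try:
            return self.drugs[analyte]
        except KeyError:
            raise ValueError(f"no drug block configured for analyte {analyte!r}") from None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (tags in comments are not kept)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def default_config() -> RunConfig:
    """The configuration shipped with the package."""
    text = importlib.resources.files("igpbpk").joinpath("defaults.yaml").read_text()
    return RunConfig.model_validate(yaml.safe_load(text))
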