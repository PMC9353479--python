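"""Schema-validated run configuration (TOML or YAML).

Every tunable of the pipeline lives here with its shipped default; unknown
keys are rejected so typos fail loudly.  ``RunConfig()`` with no arguments is
the exact configuration the turn-key scenarios are calibrated for.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConditionsConfig(_Section):
    """Incubator temperature and water viscosity for Stokes-Einstein."""

    temperature_k: float = Field(default=310.15, gt=0)
    viscosity_pa_s: float = Field(default=8.9e-4, gt=0)


class GeometryConfig(_Section):
    """Channel cross-section dimensions and reservoir loading."""

    medium_channel_width_um: float = Field(default=1000.0, gt=0)
    gel_channel_width_um: float = Field(default=1000.0, gt=0)
    height_um: float = Field(default=200.0, gt=0)
    length_mm: float = Field(default=6.0, gt=0)
    reservoir_volume_ul: float = Field(default=120.0, gt=0)
    dx_um: float = Field(default=5.0, gt=0)
    gel_cell_density_per_ml: float = Field(default=1.0e6, ge=0)
    bec_suspension_per_ml: float = Field(default=8.0e5, ge=0)
    bec_seed_volume_ul: float = Field(default=60.0, ge=0)


class GelConfigSection(_Section):
    """Collagen gel physical properties."""

    volume_fraction: float = Field(default=0.125, gt=0, lt=1)
    fiber_radius_nm: float = Field(default=200.0, gt=0)
    permeability_m2: float = Field(default=1e-13, gt=0)
    collagen_density_mg_ml: float = Field(default=2.0, gt=0)


class FlowConfig(_Section):
    """Lumped hydrostatic drainage parameters."""

    tau_s: float = Field(default=200.0, gt=0)
    initial_head_ul: float = Field(default=60.0, ge=0)
    reservoir_area_m2: float = Field(default=1.65e-6, gt=0)


class CollagenaseScenarioConfig(_Section):
    """Selective-extraction simulation settings."""

    load_mg_ml: float = Field(default=1.0, ge=0)
    molecular_weight_da: float = Field(default=100_000.0, gt=0)
    duration_s: float = Field(default=1800.0, gt=0)
    d_medium_m2_s: float = Field(default=8.4e-11, gt=0)
    d_gel_m2_s: float = Field(default=8.35e-11, gt=0)
    reach_threshold_fraction: float = Field(default=0.01, gt=0, lt=1)
    activation_min_mg_ml: float = Field(default=0.5, ge=0)
    activation_max_mg_ml: float = Field(default=2.5, gt=0)
    pbs_reservoir_ul: float = Field(default=120.0, gt=0)
    collagenase_reservoir_ul: float = Field(default=60.0, gt=0)
    sample_interval_s: float = Field(default=10.0, gt=0)


class CytokineScenarioConfig(_Section):
    """Secretion/diffusion comparison between chip and Transwell."""

    duration_h: float = Field(default=24.0, gt=0)
    solutes: list[str] = Field(default_factory=lambda: ["serpin E1", "IL-8"])
    sample_interval_s: float = Field(default=300.0, gt=0)
    arrival_threshold_fraction: float = Field(default=0.01, gt=0, lt=1)
    separation_mm: float = Field(default=0.9, gt=0)
    well_area_cm2: float = Field(default=1.9, gt=0)
    tumor_zone_um: float = Field(default=200.0, gt=0)


class RunConfig(_Section):
    """Top-level configuration; section defaults are the shipped calibration."""

    conditions: ConditionsConfig = Field(default_factory=ConditionsConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    gel: GelConfigSection = Field(default_factory=GelConfigSection)
    flow: FlowConfig = Field(default_factory=FlowConfig)
    collagenase: CollagenaseScenarioConfig = Field(default_factory=CollagenaseScenarioConfig)
    cytokine: CytokineScenarioConfig = Field(default_factory=CytokineScenarioConfig)

    def snapshot(self) -> dict:
        """Plain-dict snapshot complete enough to rerun bit-identically."""
        return self.model_dump(mode="json")


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML (or YAML) config file into a validated :class:`RunConfig`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(path.read_text()) or {}
        else:
            data = tomllib.loads(path.read_text())
    except (yaml.YAMLError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}:\n{exc}") from exc


def default_config_path() -> Path:
    """Path of the shipped ``default.toml`` (for reference / copying)."""
    return Path(__file__).parent / "data" / "default.toml"
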