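"""Validated run configuration (YAML) shared by all subcommands.

The schema is validated before any computation; every run writes the
resolved configuration next to its outputs so results are auditable.
All stochastic artifacts are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from rimap.optics import OpticalSystem


class OpticsConfig(BaseModel):
    numerical_aperture: float = 1.46
    emission_wavelength: float = 670.0
    n_immersion: float = 1.52
    n_ambient: float = 1.33
    pixel_size_sample: float = 160.0
    defocus: float = 500.0
    zernike_terms: dict[int, float] = Field(default_factory=dict)
    roi_size: int = 15
    oversampling: int = 3
    pupil_samples: int = 96

    @model_validator(mode="after")
    def _check(self):
        # delegate the physical invariants to the domain type
        self.build()
        return self

    def build(self) -> OpticalSystem:
        return OpticalSystem(**self.model_dump())


class PrecisionSweepConfig(BaseModel):
    heights_nm: list[float] = Field(
        default_factory=lambda: [float(h) for h in range(10, 401, 20)])
    sbr_values: list[float] = Field(default_factory=lambda: [10.0, 100.0, 1000.0])
    photons: float = 1e5
    n_layer: float = 1.43
    afm_delta_z: float = 1.0

    @field_validator("photons")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("photons must be positive")
        return v


class LocalizeConfig(BaseModel):
    absolute_threshold: float = 450.0
    relative_threshold: float = 1.5
    n_layer: float = 1.33
    layer_thickness: float = 0.0


class FibrilConfig(BaseModel):
    n_grid: list[float] = Field(
        default_factory=lambda: [1.38, 1.40, 1.42, 1.44, 1.46, 1.48])
    window_nlocs: int = 40
    map_window_nlocs: int = 100
    overlap_fraction: float = 0.9
    llr_cutoff: float = 600.0
    dbscan_eps: float = 30.0
    dbscan_min_samples: int = 10
    n_resamples: int = 1000
    n_draws: int = 10000
    debris_offset: float = 0.0

    @field_validator("overlap_fraction")
    @classmethod
    def _frac(cls, v):
        if not (0.0 <= v < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        return v


class SynthConfig(BaseModel):
    axis_length: float = 3500.0
    radius_wet: float = 69.0
    radius_dry: float = 40.0
    n_true: float = 1.43
    surface_label_density: float = 600.0
    glass_label_density: float = 60.0
    frames: int = 9000
    mean_photons: float = 3000.0
    background: float = 27.0
    p_on: float = 1e-4
    afm_pixel_size: float = 39.0
    afm_noise_sigma: float = 0.3


class RunConfig(BaseModel):
    """Top-level configuration of a run."""

    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    precision: PrecisionSweepConfig = Field(default_factory=PrecisionSweepConfig)
    localize: LocalizeConfig = Field(default_factory=LocalizeConfig)
    fibril: FibrilConfig = Field(default_factory=FibrilConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    seed: int = 1
    output_dir: str = "rimap_out"
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)


def write_resolved_config(config: RunConfig, out_dir) -> Path:
    """Write the fully resolved configuration next to the outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "resolved_config.json"
    path.write_text(json.dumps(config.model_dump(), indent=2, sort_keys=True))
    return path
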