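"""Validated pipeline configuration; defaults reproduce the bench protocol."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from lfnc.scenarios import RATIO_WINDOW, TABLE_RR_BPM, TABLE_TI_MS, TABLE_VT_ML
from lfnc.simulator import RigGeometry
from lfnc.scenarios import WaveformSpec


class PipelineConfig(BaseModel):
    """Full configuration of the end-to-end pipeline.

    Defaults are the bench protocol: the VT/RR/Ti grid with the Ti/Te
    window, four cannula flows at 100% O2 supply, triplicates with 0.15-pp
    measurement noise, dead space 5.2 mL, and charts at 5 and 7.5 mL/kg.
    Unknown keys are rejected.
    """

    model_config = ConfigDict(extra="forbid")

    # rig geometry
    dead_space_ml: float = 5.2
    lung_residual_ml: float = 30.0
    n_cells: int = 50

    # waveform / integration
    waveform: str = "passive"
    dt_ms: float = 1.0
    tol_pp: float = 0.01
    max_breaths: int = 500

    # scenario grid
    vt_values: list[float] = Field(default_factory=lambda: list(TABLE_VT_ML))
    rr_values: list[float] = Field(default_factory=lambda: list(TABLE_RR_BPM))
    ti_values: list[float] = Field(default_factory=lambda: list(TABLE_TI_MS))
    ratio_lo: float = RATIO_WINDOW[0]
    ratio_hi: float = RATIO_WINDOW[1]

    # protocol
    flows: list[float] = Field(default_factory=lambda: [0.1, 0.3, 0.5, 1.0])
    supply_o2_percent: float = 100.0
    replicates: int = 3
    noise_sd_pp: float = 0.15
    seed: int = 0

    # charts
    vt_per_kg_values: list[float] = Field(default_factory=lambda: [5.0, 7.5])
    weight_grid: list[float] = Field(
        default_factory=lambda: [w / 2 for w in range(1, 13)]
    )
    chart_rr_values: list[float] = Field(default_factory=lambda: list(TABLE_RR_BPM))
    vt_cap_ml: float = 30.0

    # bias analysis
    bias_thresholds_pp: list[float] = Field(default_factory=lambda: [3.0, 5.0])

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        # constructing the domain objects runs their invariant checks
        RigGeometry(self.dead_space_ml, self.lung_residual_ml, self.n_cells)
        WaveformSpec(self.waveform, self.dt_ms)
        if self.tol_pp <= 0:
            raise ValueError("tol_pp must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if self.noise_sd_pp < 0:
            raise ValueError("noise_sd_pp must be non-negative")
        if not (21.0 <= self.supply_o2_percent <= 100.0):
            raise ValueError("supply_o2_percent must lie in [21, 100]")
        if self.ratio_lo <= 0 or self.ratio_hi <= 0 or self.ratio_lo >= self.ratio_hi:
            raise ValueError("require 0 < ratio_lo < ratio_hi")
        return self

    def geometry(self) -> RigGeometry:
        return RigGeometry(self.dead_space_ml, self.lung_residual_ml, self.n_cells)

    def waveform_spec(self) -> WaveformSpec:
        return WaveformSpec(self.waveform, self.dt_ms)


def load_config(path) -> PipelineConfig:
    """Parse, default and validate a YAML/JSON config file.

    An empty file yields the full default (bench-protocol) configuration.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig, path) -> Path:
    """Write a config back to YAML (round-trips through load_config)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
    return path
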