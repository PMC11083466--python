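"""Predictive FiO2 lookup charts over infant weight and respiratory rate.

Bedside users know the cannula flow, the infant's weight and RR — not VT or
Ti.  The charts fix VT per kg (5 or 7.5 mL/kg), derive VT from weight, and
evaluate the simulated steady-state FiO2 at the representative Ti for each
RR: the largest grid Ti keeping Ti/Te inside the physiological window
(slower breaths take longer inspirations).  Cells whose VT
exceeds the 30-mL design cap are left absent rather than extrapolated.  The
clinically typical 30-60 breaths/min band is flagged and shaded in plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lfnc.scenarios import (
    RATIO_WINDOW,
    TABLE_TI_MS,
    BreathingScenario,
    WaveformSpec,
    feasible_ti,
)
from lfnc.simulator import CannulaSetting, RigGeometry, simulate_steady_state

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS_KG = tuple(np.arange(0.5, 6.01, 0.5).round(1))
DEFAULT_RR_BPM = (30, 40, 50, 60, 70, 80)


@dataclass(frozen=True)
class ChartSpec:
    """One chart panel: a cannula flow at a fixed VT-per-kg setting."""

    flow_l_min: float
    vt_per_kg: float
    weight_grid: tuple[float, ...] = DEFAULT_WEIGHTS_KG
    rr_grid: tuple[float, ...] = DEFAULT_RR_BPM
    band: tuple[float, float] = (30.0, 60.0)
    vt_cap_ml: float = 30.0
    ti_grid: tuple[float, ...] = TABLE_TI_MS
    ratio_window: tuple[float, float] = RATIO_WINDOW
    supply_o2_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.flow_l_min < 0:
            raise ValueError("flow_l_min must be non-negative")
        if self.vt_per_kg <= 0:
            raise ValueError("vt_per_kg must be positive")
        if self.vt_cap_ml <= 0:
            raise ValueError("vt_cap_ml must be positive")


@dataclass
class ChartTable:
    """Chart cells (weight x RR -> FiO2 %) plus the spec that produced them.

    ``cells`` is a wide DataFrame indexed by weight_kg with RR columns; NaN
    marks absent cells (VT above the cap or no feasible Ti at that RR).
    """

    cells: pd.DataFrame
    spec: ChartSpec
    geometry: RigGeometry = field(default_factory=RigGeometry)

    def value(self, weight_kg: float, rr_bpm: float) -> float:
        return float(self.cells.loc[weight_kg, rr_bpm])

    def to_long(self) -> pd.DataFrame:
        """Long-format frame: weight_kg, rr_bpm, fio2_percent, in_band."""
        long = (
            self.cells.reset_index()
            .melt(id_vars="weight_kg", var_name="rr_bpm", value_name="fio2_percent")
            .astype({"rr_bpm": float})
            .sort_values(["weight_kg", "rr_bpm"], ignore_index=True)
        )
        lo, hi = self.spec.band
        long["in_band"] = (long["rr_bpm"] >= lo) & (long["rr_bpm"] <= hi)
        return long


def build_chart(
    spec: ChartSpec,
    geometry: RigGeometry | None = None,
    waveform: WaveformSpec | None = None,
    tol_pp: float = 0.01,
    max_breaths: int = 500,
) -> ChartTable:
    """Simulate every (weight, RR) cell of a chart panel.

    Each cell is the steady-state FiO2 at the representative (largest
    feasible) Ti for that RR; deterministic given geometry and waveform (no
    measurement noise).
    """
    if geometry is None:
        geometry = RigGeometry()
    cannula = CannulaSetting(spec.flow_l_min, spec.supply_o2_fraction)
    ti_by_rr = {
        rr: feasible_ti(rr, spec.ti_grid, *spec.ratio_window) for rr in spec.rr_grid
    }
    for rr, tis in ti_by_rr.items():
        if not tis:
            logger.warning(
                "no feasible Ti at RR %.0f bpm; chart column left absent", rr
            )

    table = pd.DataFrame(
        np.nan, index=list(spec.weight_grid), columns=list(spec.rr_grid), dtype=float
    )
    table.index.name = "weight_kg"
    for w in spec.weight_grid:
        vt = w * spec.vt_per_kg
        if vt > spec.vt_cap_ml:
            continue
        for rr in spec.rr_grid:
            tis = ti_by_rr[rr]
            if not tis:
                continue
            table.loc[w, rr] = simulate_steady_state(
                BreathingScenario(vt, rr, max(tis)),
                cannula,
                geometry,
                waveform,
                tol_pp=tol_pp,
                max_breaths=max_breaths,
            ).fio2_percent
    return ChartTable(cells=table, spec=spec, geometry=geometry)


def write_chart(table: ChartTable, destination) -> Path:
    """Write the chart in long CSV format (absent cells as empty fields)."""
    path = Path(destination)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_long().to_csv(path, index=False)
    return path


def read_chart(path) -> pd.DataFrame:
    """Read a chart CSV back as the long-format frame."""
    return pd.read_csv(path)


def plot_chart(table: ChartTable, ax=None):
    """Render a chart panel: FiO2 vs weight, one line per RR, band shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    lo, hi = table.spec.band
    band_cols = [rr for rr in table.cells.columns if lo <= rr <= hi]
    if band_cols:
        upper = table.cells[band_cols].max(axis=1)
        lower = table.cells[band_cols].min(axis=1)
        ax.fill_between(
            table.cells.index, lower, upper, color="0.8", label=f"RR {lo:.0f}-{hi:.0f}"
        )
    for rr in table.cells.columns:
        ax.plot(table.cells.index, table.cells[rr], marker="o", ms=3, label=f"RR {rr:.0f}")
    ax.set_xlabel("weight (kg)")
    ax.set_ylabel("effective FiO2 (%)")
    ax.set_title(
        f"{table.spec.flow_l_min} L/min, VT {table.spec.vt_per_kg} mL/kg"
    )
    ax.legend(fontsize=7)
    return ax
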