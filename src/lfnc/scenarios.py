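"""Tidal-breathing scenarios and piston flow waveforms.

A breathing scenario is one (VT, RR, Ti) combination; expiratory time Te,
the Ti/Te ratio and minute ventilation MV follow arithmetically.  The study
grid crosses all combinations and keeps those with a physiologically
plausible Ti/Te ratio.  Waveforms reconstruct the piston drive as an
instantaneous flow profile whose integral over each phase is exactly VT.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

#: Tidal-volume grid of the bench protocol (mL): 5-mL steps up to 20, then 10-mL steps.
TABLE_VT_ML: tuple[float, ...] = (5, 10, 15, 20, 30, 40, 50, 60, 70, 80)
#: Respiratory-rate grid (breaths/min).
TABLE_RR_BPM: tuple[float, ...] = (30, 40, 50, 60, 70, 80)
#: Inspiratory-time grid (ms).
TABLE_TI_MS: tuple[float, ...] = (300, 500, 700, 900)
#: Ti/Te feasibility window, half-open: ratio_lo <= Ti/Te < ratio_hi.
RATIO_WINDOW: tuple[float, float] = (0.5, 1.5)

WAVEFORM_SHAPES = ("square", "half_sine", "passive")

#: expiratory time constant of the "passive" shape, as a fraction of Te:
#: ~4.5 time constants fit in the expiratory phase, so flow has decayed to
#: about 1% of its peak by end-expiration (a realistic tidal-breathing tail)
PASSIVE_EXP_TAU_FRACTION = 0.22


class InfeasibleScenarioError(ValueError):
    """The requested (VT, RR, Ti) combination has no positive expiratory time."""


@dataclass(frozen=True)
class BreathingScenario:
    """One fixed tidal-breathing pattern.

    Parameters
    ----------
    vt_ml : float
        Tidal volume (mL).
    rr_bpm : float
        Respiratory rate (breaths/min).
    ti_ms : float
        Inspiratory time (ms).

    Derived attributes ``te_ms`` (expiratory time), ``ti_te_ratio`` and
    ``mv_ml_min`` (minute ventilation, VT x RR) are computed on construction.
    """

    vt_ml: float
    rr_bpm: float
    ti_ms: float
    te_ms: float = field(init=False)
    ti_te_ratio: float = field(init=False)
    mv_ml_min: float = field(init=False)

    def __post_init__(self) -> None:
        if self.vt_ml <= 0 or self.rr_bpm <= 0 or self.ti_ms <= 0:
            raise ValueError("vt_ml, rr_bpm and ti_ms must all be positive")
        te = 60000.0 / self.rr_bpm - self.ti_ms
        if te <= 0:
            raise InfeasibleScenarioError(
                f"Te = {te:.1f} ms <= 0 for RR {self.rr_bpm} bpm, Ti {self.ti_ms} ms"
            )
        object.__setattr__(self, "te_ms", te)
        object.__setattr__(self, "ti_te_ratio", self.ti_ms / te)
        object.__setattr__(self, "mv_ml_min", self.vt_ml * self.rr_bpm)

    @property
    def cycle_ms(self) -> float:
        """Respiratory cycle length Ti + Te (ms)."""
        return self.ti_ms + self.te_ms


@dataclass(frozen=True)
class WaveformSpec:
    """Instantaneous piston flow profile.

    shape
        ``"passive"`` (the default: velocity-ramped half-sine inspiration
        and passive exponential expiration with time constant
        ``PASSIVE_EXP_TAU_FRACTION`` x Te, leaving a near-zero-flow
        end-expiratory tail), ``"half_sine"`` (half-sine in both phases,
        zero flow at the phase boundaries), or ``"square"`` (constant flow,
        the degenerate profile used for closed-form checks).
    dt_ms
        Integration time step; must not exceed Ti/10 of any scenario the
        spec is applied to.
    """

    shape: str = "passive"
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in WAVEFORM_SHAPES:
            raise ValueError(
                f"unknown waveform shape {self.shape!r}; expected one of {WAVEFORM_SHAPES}"
            )
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    def validate_for(self, scenario: BreathingScenario) -> None:
        if self.dt_ms > scenario.ti_ms / 10.0:
            raise ValueError(
                f"dt_ms = {self.dt_ms} too coarse for Ti = {scenario.ti_ms} ms "
                "(require dt_ms <= Ti/10)"
            )


def enumerate_grid(
    vt_values: Iterable[float] = TABLE_VT_ML,
    rr_values: Iterable[float] = TABLE_RR_BPM,
    ti_values: Iterable[float] = TABLE_TI_MS,
    ratio_lo: float = RATIO_WINDOW[0],
    ratio_hi: float = RATIO_WINDOW[1],
) -> list[BreathingScenario]:
    """Cross the VT/RR/Ti grids and keep feasible scenarios.

    A combination is retained when its Te is positive and its Ti/Te ratio r
    satisfies ``ratio_lo <= r < ratio_hi`` (half-open upper bound).  Ordering
    is deterministic: VT-major, then RR, then Ti.
    """
    if ratio_lo <= 0 or ratio_hi <= 0:
        raise ValueError("ratio bounds must be positive")
    if ratio_lo >= ratio_hi:
        raise ValueError("ratio_lo must be smaller than ratio_hi")
    vt_values = sorted(vt_values)
    rr_values = sorted(rr_values)
    ti_values = sorted(ti_values)
    if any(v <= 0 for v in itertools.chain(vt_values, rr_values, ti_values)):
        raise ValueError("all grid values must be positive")

    out: list[BreathingScenario] = []
    for vt, rr, ti in itertools.product(vt_values, rr_values, ti_values):
        te = 60000.0 / rr - ti
        if te <= 0:
            continue
        ratio = ti / te
        if ratio_lo <= ratio < ratio_hi:
            out.append(BreathingScenario(vt, rr, ti))
    return out


def feasible_ti(
    rr_bpm: float,
    ti_grid: Sequence[float] = TABLE_TI_MS,
    ratio_lo: float = RATIO_WINDOW[0],
    ratio_hi: float = RATIO_WINDOW[1],
) -> list[float]:
    """Ti values from the grid with positive Te and Ti/Te in the window at this RR."""
    if rr_bpm <= 0:
        raise ValueError("rr_bpm must be positive")
    out = []
    for ti in sorted(ti_grid):
        te = 60000.0 / rr_bpm - ti
        if te > 0 and ratio_lo <= ti / te < ratio_hi:
            out.append(ti)
    return out


def scenario_from_weight(
    weight_kg: float, vt_per_kg: float, rr_bpm: float, ti_ms: float
) -> BreathingScenario:
    """Scenario for an infant of given weight with a weight-proportional VT.

    Clinical convention sets VT at 5 or 7.5 mL/kg; any positive value is
    accepted.  Raises :class:`InfeasibleScenarioError` when the implied Te
    is not positive.
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    if vt_per_kg <= 0:
        raise ValueError("vt_per_kg must be positive")
    return BreathingScenario(weight_kg * vt_per_kg, rr_bpm, ti_ms)


def make_waveform(
    scenario: BreathingScenario, spec: WaveformSpec
) -> Callable[[float], float]:
    """Piecewise flow-magnitude function of time over one breath (mL/s).

    The returned callable maps time in seconds (taken modulo the cycle) to
    the magnitude of piston flow: inspiratory flow on [0, Ti), expiratory
    flow on [Ti, Ti+Te).  For each phase the integral of the magnitude is
    exactly VT.  The half-sine shape has zero flow at both phase boundaries;
    the passive shape's expiratory flow peaks at the start of expiration and
    decays exponentially toward a near-zero end-expiratory tail.
    """
    spec.validate_for(scenario)
    vt = scenario.vt_ml
    ti = scenario.ti_ms / 1000.0
    te = scenario.te_ms / 1000.0
    cycle = ti + te

    if spec.shape == "square":

        def flow(t: float) -> float:
            t = t % cycle
            return vt / ti if t < ti else vt / te

    elif spec.shape == "half_sine":

        def flow(t: float) -> float:
            t = t % cycle
            if t < ti:
                return (math.pi / 2.0) * (vt / ti) * math.sin(math.pi * t / ti)
            return (math.pi / 2.0) * (vt / te) * math.sin(math.pi * (t - ti) / te)

    else:  # passive: half-sine inspiration, exponential expiration
        c = 1.0 / PASSIVE_EXP_TAU_FRACTION
        norm = 1.0 - math.exp(-c)

        def flow(t: float) -> float:
            t = t % cycle
            if t < ti:
                return (math.pi / 2.0) * (vt / ti) * math.sin(math.pi * t / ti)
            x = (t - ti) / te
            return (vt / te) * (c / norm) * math.exp(-c * x)

    return flow


def phase_step_volumes(
    vt_ml: float, duration_ms: float, shape: str, dt_ms: float, phase: str = "insp"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step swept volumes and step durations for one breath phase.

    Steps are the intervals [k*dt, (k+1)*dt) clipped to the phase duration;
    volumes are differences of the closed-form cumulative displacement, so
    they sum to VT exactly regardless of dt.  ``phase`` ("insp" or "exp")
    matters only for the asymmetric "passive" shape.  Returns
    ``(volumes_ml, durations_s)``.
    """
    if shape not in WAVEFORM_SHAPES:
        raise ValueError(f"unknown waveform shape {shape!r}")
    if phase not in ("insp", "exp"):
        raise ValueError(f"phase must be 'insp' or 'exp', got {phase!r}")
    n = int(math.ceil(duration_ms / dt_ms))
    edges_ms = np.minimum(np.arange(n + 1) * dt_ms, duration_ms)
    x = edges_ms / duration_ms
    if shape == "square":
        cum = vt_ml * x
    elif shape == "passive" and phase == "exp":
        c = 1.0 / PASSIVE_EXP_TAU_FRACTION
        cum = vt_ml * (1.0 - np.exp(-c * x)) / (1.0 - math.exp(-c))
    else:
        cum = 0.5 * vt_ml * (1.0 - np.cos(np.pi * x))
    vols = np.diff(cum)
    durs = np.diff(edges_ms) / 1000.0
    return vols, durs


def scenarios_to_frame(scenarios: Iterable[BreathingScenario]) -> pd.DataFrame:
    """Serialize scenarios to a DataFrame (CSV contract of the grid stage)."""
    return pd.DataFrame(
        [
            {
                "vt_ml": s.vt_ml,
                "rr_bpm": s.rr_bpm,
                "ti_ms": s.ti_ms,
                "te_ms": s.te_ms,
                "ti_te_ratio": s.ti_te_ratio,
                "mv_ml_min": s.mv_ml_min,
            }
            for s in scenarios
        ],
        columns=["vt_ml", "rr_bpm", "ti_ms", "te_ms", "ti_te_ratio", "mv_ml_min"],
    )
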