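"""Computational twin of the infant breathing bench.

The rig is modelled as two gas spaces in series:

* an upper-airway **dead space** (nasal passages and pharynx of the airway
  replica) treated as a first-in-first-out plug-flow column of gas parcels
  with fixed total volume, and
* a well-mixed **lung compartment** (the piston syringe) whose volume is the
  residual volume plus the piston displacement.

A nasal cannula blows supply gas (O2 fraction up to 1.0) at constant flow Fc
into the nares end of the column.  During inspiration with piston flow Q(t),
the gas entering the nares is pure supply gas at rate min(Fc, Q) plus
entrained room air (O2 fraction 0.21) at rate max(Q - Fc, 0); whenever the
cannula flow exceeds the instantaneous piston flow, the excess max(Fc - Q, 0)
*flushes* the nares-end parcels — supply gas replaces an equal volume of
column gas, which is vented.  During expiration the lung pushes its mixed gas
into the lung end of the column while parcels exit at the nares, and the
excess cannula flow max(Fc - Qe, 0) again flushes the nares end.  This flush
is the upper-airway oxygen reservoir: gas stored near the nares around the
zero-flow phase reversals is inhaled first on the next breath, which is why
measured FiO2 exceeds the no-reservoir closed forms at low minute
ventilation.

There is no gas exchange (no O2 consumption), matching the bench: at steady
state the expired gas has the lung's O2 fraction, and the reported effective
FiO2 is the lung-compartment fraction at end-inspiration (the bench analyzer
sat at the tip of the syringe).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lfnc.scenarios import (
    BreathingScenario,
    WaveformSpec,
    phase_step_volumes,
)

ROOM_AIR_O2 = 0.21

# parcels whose O2 fractions differ by less than this are merged on append;
# keeps the column compact without measurable smearing of the stored front
_MERGE_TOL = 1e-12


@dataclass(frozen=True)
class RigGeometry:
    """Geometry of the airway replica and breathing compartment.

    dead_space_ml
        Base volume of the upper-airway replica's air passages (mL); the
        bench value is 5.2 mL by water displacement.  Zero removes the
        reservoir entirely (the regime of the closed-form oracle).
    lung_residual_ml
        Compartment (syringe) volume at end-expiration (mL).  With no gas
        exchange it affects wash-in speed only, not the steady state.
    n_cells
        Minimum plug-flow resolution of the dead space: no parcel is larger
        than dead_space_ml / n_cells.
    small_vt_rod_ml
        Volume of the pliant rod inserted to reduce dead space when VT < 10 mL.
    extension_fraction
        Dead space as a fraction of VT once VT > 50 mL (expandable-tube rule):
        effective VD = max(dead_space_ml, extension_fraction * VT).
    """

    dead_space_ml: float = 5.2
    lung_residual_ml: float = 30.0
    n_cells: int = 50
    small_vt_rod_ml: float = 1.0
    extension_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.dead_space_ml < 0:
            raise ValueError("dead_space_ml must be non-negative")
        if self.lung_residual_ml < 0:
            raise ValueError("lung_residual_ml must be non-negative")
        if self.n_cells < 10:
            raise ValueError("n_cells must be at least 10")


@dataclass(frozen=True)
class CannulaSetting:
    """Cannula flow (L/min) and O2 fraction of the supplied gas (0.21-1)."""

    flow_l_min: float
    supply_o2_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.flow_l_min < 0:
            raise ValueError("flow_l_min must be non-negative")
        if not (ROOM_AIR_O2 <= self.supply_o2_fraction <= 1.0):
            raise ValueError("supply_o2_fraction must lie in [0.21, 1]")

    @property
    def flow_ml_s(self) -> float:
        return self.flow_l_min * 1000.0 / 60.0


@dataclass
class SimulationResult:
    """Steady-state effective FiO2 for one scenario x cannula setting.

    fio2_percent is the converged end-inspiratory lung O2 fraction (%),
    geometrically extrapolated from the tail of the wash-in trace so the
    reported value is insensitive to where the convergence test fires.
    mass_balance_error is the largest relative O2 bookkeeping drift seen at
    any time step.
    """

    fio2_percent: float
    n_breaths: int
    converged: bool
    per_breath_fio2: np.ndarray = field(repr=False)
    mass_balance_error: float = 0.0


def effective_dead_space(vt_ml: float, base: RigGeometry) -> float:
    """Dead-space volume actually in play for a given tidal volume (mL).

    The bench reduced dead space with a 1-mL rod for VT < 10 mL and extended
    it for VT > 50 mL; the extension is modelled as a weight-proportional
    anatomical dead space of ``extension_fraction`` x VT (floored at the base
    replica volume).
    """
    if vt_ml <= 0:
        raise ValueError("vt_ml must be positive")
    if base.dead_space_ml == 0.0:
        return 0.0  # reservoir-free rig (closed-form oracle regime)
    if vt_ml < 10:
        return max(base.dead_space_ml - base.small_vt_rod_ml, 0.0)
    if vt_ml <= 50:
        return base.dead_space_ml
    return max(base.dead_space_ml, base.extension_fraction * vt_ml)


def _take(column: deque, o2: list, volume: float, side: int) -> float:
    """Remove `volume` from one end of the column; return the O2 amount removed.

    side=0 pops from the lung end (left), side=1 from the nares end (right).
    Mutates the boundary parcel in place for partial removals.
    """
    removed = 0.0
    remaining = volume
    while remaining > 0.0 and column:
        parcel = column[0] if side == 0 else column[-1]
        pv, pf = parcel
        if pv <= remaining + 1e-15:
            removed += pv * pf
            remaining -= pv
            if side == 0:
                column.popleft()
            else:
                column.pop()
        else:
            removed += remaining * pf
            parcel[0] = pv - remaining
            remaining = 0.0
    o2[0] -= removed
    return removed


def _flush(column: deque, o2: list, volume: float, supply_frac: float) -> float:
    """Grow the pure-supply front at the nares end by `volume`.

    The cannula jet deposits supply gas at the nares end and displaces an
    equal volume of resident column gas from just beyond the already-
    deposited front, which is vented.  If the front has consumed the whole
    column, the excess jet gas simply blows back out.  Returns the vented O2
    amount.  (Expiratory piston flow still vents from the nares end front
    first, so mid-expiration deposits are swept out; only gas deposited once
    the expiratory flow has fallen below the cannula flow survives to the
    next inspiration — the upper-airway reservoir effect.)
    """
    front = 0.0
    if column and abs(column[-1][1] - supply_frac) < _MERGE_TOL:
        front = column.pop()[0]
        o2[0] -= front * supply_frac
    removed_o2 = 0.0
    remaining = volume
    while remaining > 0.0 and column:
        pv, pf = column[-1]
        if pv <= remaining + 1e-15:
            removed_o2 += pv * pf
            remaining -= pv
            column.pop()
        else:
            removed_o2 += remaining * pf
            column[-1][0] = pv - remaining
            remaining = 0.0
    o2[0] -= removed_o2
    vented = removed_o2 + remaining * supply_frac
    front += volume - remaining
    if front > 0.0:
        _push(column, o2, front, supply_frac, 1)
    return vented


def _push(column: deque, o2: list, volume: float, frac: float, side: int) -> None:
    """Add a parcel at one end (side=0 lung end, side=1 nares end)."""
    if volume <= 0.0:
        return
    o2[0] += volume * frac
    if column:
        parcel = column[0] if side == 0 else column[-1]
        if abs(parcel[1] - frac) < _MERGE_TOL:
            parcel[0] += volume
            return
    if side == 0:
        column.appendleft([volume, frac])
    else:
        column.append([volume, frac])


def simulate_steady_state(
    scenario: BreathingScenario,
    cannula: CannulaSetting,
    geometry: RigGeometry | None = None,
    waveform: WaveformSpec | None = None,
    tol_pp: float = 0.01,
    max_breaths: int = 500,
    initial_o2_fraction: float = ROOM_AIR_O2,
) -> SimulationResult:
    """Time-step the rig model to steady-state effective FiO2.

    Breathing repeats the scenario's waveform; the run stops once the
    end-inspiratory lung O2 fraction changes by less than ``tol_pp``
    percentage points over three consecutive breaths (or at ``max_breaths``,
    flagged ``converged=False``).  ``initial_o2_fraction`` sets the starting
    gas everywhere (0.21 = room-air start, the wash-in protocol; 1.0
    reproduces the between-run wash-out when the cannula flow is zero).
    """
    if geometry is None:
        geometry = RigGeometry()
    if waveform is None:
        waveform = WaveformSpec()
    if tol_pp <= 0:
        raise ValueError("tol_pp must be positive")
    waveform.validate_for(scenario)

    vd = effective_dead_space(scenario.vt_ml, geometry)
    fc = cannula.flow_ml_s
    fs = cannula.supply_o2_fraction
    dt = waveform.dt_ms

    insp_v, insp_d = phase_step_volumes(
        scenario.vt_ml, scenario.ti_ms, waveform.shape, dt, phase="insp"
    )
    exp_v, exp_d = phase_step_volumes(
        scenario.vt_ml, scenario.te_ms, waveform.shape, dt, phase="exp"
    )

    # per-step cannula volumes and the inspiration partition into entrained
    # supply, entrained room air and flush excess (all scenario constants)
    insp_c = fc * insp_d
    exp_c = fc * exp_d
    insp_supply = np.minimum(insp_c, insp_v)
    insp_air = insp_v - insp_supply
    insp_flush = insp_c - insp_supply
    with np.errstate(invalid="ignore", divide="ignore"):
        insp_frac = np.where(
            insp_v > 0, (insp_supply * fs + insp_air * ROOM_AIR_O2) / insp_v, 0.0
        )
    exp_flush = np.maximum(exp_c - exp_v, 0.0)
    exp_vent_supply = exp_c - exp_flush  # cannula gas vented against the expiratory stream

    n_insp = len(insp_v)
    n_exp = len(exp_v)

    # plain lists: the breath loop below is scalar code
    insp_v = insp_v.tolist()
    insp_c = insp_c.tolist()
    insp_air = insp_air.tolist()
    insp_flush = insp_flush.tolist()
    insp_frac = insp_frac.tolist()
    exp_v = exp_v.tolist()
    exp_c = exp_c.tolist()
    exp_flush = exp_flush.tolist()
    exp_vent_supply = exp_vent_supply.tolist()

    # state
    column: deque = deque()
    col_o2 = [0.0]
    if vd > 0:
        _push(column, col_o2, vd, initial_o2_fraction, 1)
    lung_vol = geometry.lung_residual_ml
    lung_o2 = lung_vol * initial_o2_fraction

    # O2 bookkeeping for the conservation check
    initial_total = lung_o2 + col_o2[0]
    supplied = 0.0
    entrained = 0.0
    vented = 0.0
    max_drift = 0.0

    trace: list[float] = []
    consecutive = 0
    converged = False
    # don't judge steady state before the inspired volume has displaced the
    # apparatus volume a few times: with VT smaller than the dead space the
    # wash-in front takes many breaths to percolate through the column, and
    # the trace is deceptively flat until it does
    min_breaths = min(
        int(np.ceil(3.0 * (lung_vol + vd + scenario.vt_ml) / scenario.vt_ml)),
        max_breaths,
    )

    for breath in range(max_breaths):
        for k in range(n_insp):
            fl = insp_flush[k]
            if fl > 0.0 and vd > 0:
                vented += _flush(column, col_o2, fl, fs)
            elif fl > 0.0:
                vented += fl * fs  # no dead space to flush: excess vented directly
            supplied += insp_c[k] * fs
            entrained += insp_air[k] * ROOM_AIR_O2
            v = insp_v[k]
            if v > 0.0:
                if vd > 0:
                    _push(column, col_o2, v, insp_frac[k], 1)
                    lung_o2 += _take(column, col_o2, v, 0)
                else:
                    lung_o2 += v * insp_frac[k]
                lung_vol += v
            drift = (lung_o2 + col_o2[0] + vented) - (initial_total + supplied + entrained)
            scale = max(initial_total + supplied + entrained, 1.0)
            if abs(drift) / scale > max_drift:
                max_drift = abs(drift) / scale

        trace.append(100.0 * lung_o2 / lung_vol)

        for k in range(n_exp):
            w = exp_v[k]
            if w > 0.0:
                frac_lung = lung_o2 / lung_vol
                out_o2 = w * frac_lung
                lung_o2 -= out_o2
                lung_vol -= w
                if vd > 0:
                    _push(column, col_o2, w, frac_lung, 0)
                    vented += _take(column, col_o2, w, 1)
                else:
                    vented += out_o2
            g = exp_flush[k]
            if g > 0.0 and vd > 0:
                vented += _flush(column, col_o2, g, fs)
            elif g > 0.0:
                vented += g * fs
            supplied += exp_c[k] * fs
            vented += exp_vent_supply[k] * fs
            drift = (lung_o2 + col_o2[0] + vented) - (initial_total + supplied + entrained)
            scale = max(initial_total + supplied + entrained, 1.0)
            if abs(drift) / scale > max_drift:
                max_drift = abs(drift) / scale

        if breath >= 1 and abs(trace[-1] - trace[-2]) < tol_pp:
            consecutive += 1
            if consecutive >= 3 and breath + 1 >= min_breaths:
                converged = True
                break
        else:
            consecutive = 0

    trace_arr = np.asarray(trace)
    fio2 = _extrapolate_steady_state(trace_arr)
    lo = 100.0 * min(ROOM_AIR_O2, initial_o2_fraction)
    hi = 100.0 * max(fs, initial_o2_fraction)
    fio2 = float(np.clip(fio2, lo, hi))
    return SimulationResult(
        fio2_percent=fio2,
        n_breaths=len(trace_arr),
        converged=converged,
        per_breath_fio2=trace_arr,
        mass_balance_error=max_drift,
    )


def _extrapolate_steady_state(trace: np.ndarray) -> float:
    """Geometric (Aitken-type) extrapolation of the wash-in tail.

    Multi-breath wash-in of a well-mixed compartment is geometric, so the
    limit is f_n + d_n * r / (1 - r) with r the ratio of successive
    per-breath increments.  Falls back to the last value when the tail is
    not contracting.
    """
    if len(trace) < 3:
        return float(trace[-1])
    d1 = trace[-2] - trace[-3]
    d2 = trace[-1] - trace[-2]
    if d1 == 0.0 or d2 == 0.0:
        return float(trace[-1])
    r = d2 / d1
    if 0.0 < r < 0.9999:
        return float(trace[-1] + d2 * r / (1.0 - r))
    return float(trace[-1])


def generate_dataset(
    scenarios: list[BreathingScenario],
    flows_l_min: list[float],
    geometry: RigGeometry | None = None,
    waveform: WaveformSpec | None = None,
    noise_sd_pp: float = 0.15,
    replicates: int = 3,
    seed: int | None = None,
    supply_o2_fraction: float = 1.0,
    tol_pp: float = 0.01,
    max_breaths: int = 500,
) -> pd.DataFrame:
    """Simulate the full protocol: every scenario x flow, in replicate.

    Each cell is simulated once to steady state; replicate readings add
    Gaussian measurement noise of sd ``noise_sd_pp`` percentage points
    (clipped to [21, 100]), emulating the bench's triplicate protocol with
    printed replicate SDs of 0.1-0.2 pp.  A fixed ``seed`` reproduces the
    dataset exactly.

    Returns a DataFrame with columns vt_ml, rr_bpm, ti_ms, te_ms,
    mv_ml_min, flow_l_min, replicate, fio2_percent.
    """
    if noise_sd_pp < 0:
        raise ValueError("noise_sd_pp must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    rng = np.random.default_rng(seed)
    rows = []
    for scen in scenarios:
        for flow in flows_l_min:
            res = simulate_steady_state(
                scen,
                CannulaSetting(flow, supply_o2_fraction),
                geometry,
                waveform,
                tol_pp=tol_pp,
                max_breaths=max_breaths,
            )
            if noise_sd_pp > 0:
                vals = np.clip(
                    res.fio2_percent + rng.normal(0.0, noise_sd_pp, replicates),
                    21.0,
                    100.0,
                )
            else:
                vals = np.full(replicates, res.fio2_percent)
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "vt_ml": scen.vt_ml,
                        "rr_bpm": scen.rr_bpm,
                        "ti_ms": scen.ti_ms,
                        "te_ms": scen.te_ms,
                        "mv_ml_min": scen.mv_ml_min,
                        "flow_l_min": flow,
                        "replicate": rep,
                        "fio2_percent": float(vals[rep - 1]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "vt_ml",
            "rr_bpm",
            "ti_ms",
            "te_ms",
            "mv_ml_min",
            "flow_l_min",
            "replicate",
            "fio2_percent",
        ],
    )
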