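"""Closed-form effective-FiO2 estimators in clinical use, at 100% O2 supply.

Two literature formulas convert a low cannula flow into an effective FiO2:

* **Benaron-Benitz**: the cannula gas inhaled per breath is flow x Ti
  (capped at VT); FiO2 = 21 + (supply% - 21) x v / VT.  Assumes the upper
  airway stores no oxygen.
* **Finer**: a minute-ventilation balance; FiO2 = 100 x (f x Fs +
  (MV - f) x 0.21) / MV with f the flow in mL/min.  Deliberately *not*
  capped here — its well-known flaw of exceeding 100% at low MV is part of
  the bias analysis downstream.

The STOP-ROP trial convention applies Benaron-Benitz with fixed Ti = 300 ms
and VT = 5 mL/kg.  The blender correction rescales a 100%-supply chart value
to a blender-diluted supply.
"""

from __future__ import annotations

from dataclasses import dataclass

ROOM_AIR_PERCENT = 21.0


@dataclass(frozen=True)
class FormulaEstimate:
    """An estimated effective FiO2 (%) with provenance and cap flag."""

    fio2_percent: float
    formula_name: str
    capped: bool = False


def _ml_per_s(flow_l_min: float) -> float:
    return flow_l_min * 1000.0 / 60.0


def _ml_per_min(flow_l_min: float) -> float:
    return flow_l_min * 1000.0


def benaron_benitz_fio2(
    flow_l_min: float,
    ti_ms: float,
    vt_ml: float,
    supply_o2_percent: float = 100.0,
) -> FormulaEstimate:
    """Benaron-Benitz estimate: cannula volume per inspiration over VT.

    The inhaled cannula volume v = flow x Ti is capped at VT (one cannot
    inhale more cannula gas than the breath itself); ``capped`` records
    whether the cap was hit, in which case the estimate equals the supply
    concentration.
    """
    if vt_ml <= 0 or ti_ms <= 0:
        raise ValueError("vt_ml and ti_ms must be positive")
    if flow_l_min < 0:
        raise ValueError("flow_l_min must be non-negative")
    v = _ml_per_s(flow_l_min) * (ti_ms / 1000.0)
    capped = v > vt_ml
    v = min(v, vt_ml)
    fio2 = ROOM_AIR_PERCENT + (supply_o2_percent - ROOM_AIR_PERCENT) * v / vt_ml
    return FormulaEstimate(fio2, "benaron_benitz", capped)


def finer_fio2(
    flow_l_min: float,
    mv_ml_min: float,
    supply_o2_percent: float = 100.0,
) -> FormulaEstimate:
    """Finer estimate from cannula flow and minute ventilation, uncapped.

    At 100% supply this is 100 x (0.79 f + 0.21 MV) / MV with f in mL/min.
    When f approaches or exceeds MV the value exceeds 100% — a known flaw
    of the formula that is preserved intentionally (``capped`` flags it).
    """
    if mv_ml_min <= 0:
        raise ValueError("mv_ml_min must be positive")
    if flow_l_min < 0:
        raise ValueError("flow_l_min must be non-negative")
    f = _ml_per_min(flow_l_min)
    fs = supply_o2_percent / 100.0
    # the air term (MV - f) is deliberately not clamped at zero: when the
    # cannula flow exceeds MV the formula extrapolates past 100%
    fio2 = 100.0 * (f * fs + (mv_ml_min - f) * 0.21) / mv_ml_min
    return FormulaEstimate(fio2, "finer", capped=fio2 > 100.0)


def stoprop_fio2(flow_l_min: float, weight_kg: float) -> FormulaEstimate:
    """STOP-ROP conversion: Benaron-Benitz at fixed Ti 300 ms, VT 5 mL/kg."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be positive")
    est = benaron_benitz_fio2(flow_l_min, ti_ms=300.0, vt_ml=5.0 * weight_kg)
    return FormulaEstimate(est.fio2_percent, "stoprop", est.capped)


def blender_corrected_fio2(
    chart_fio2_percent: float, blender_fio2_percent: float
) -> float:
    """Rescale a 100%-supply chart FiO2 to a blender-diluted supply.

    effective FiO2 = 21 + (chart - 21) x blender / 100.  Linear in the
    blender setting, identity at 100%, and fixes the room-air point 21.
    """
    if chart_fio2_percent < ROOM_AIR_PERCENT:
        raise ValueError("chart_fio2_percent must be at least 21")
    if not (ROOM_AIR_PERCENT <= blender_fio2_percent <= 100.0):
        raise ValueError("blender_fio2_percent must lie in [21, 100]")
    return ROOM_AIR_PERCENT + (chart_fio2_percent - ROOM_AIR_PERCENT) * (
        blender_fio2_percent / 100.0
    )
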