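"""Simulate oxygen wash-in for one breathing scenario and compare formulas.

A 5-mL tidal volume, 30 breaths/min, 900-ms inspiratory time infant on a
0.1 L/min cannula at 100% oxygen: the smallest minute ventilation of the
study grid, where the upper-airway reservoir matters most.
"""

from lfnc import (
    BreathingScenario,
    CannulaSetting,
    benaron_benitz_fio2,
    finer_fio2,
    simulate_steady_state,
    stoprop_fio2,
)

scenario = BreathingScenario(vt_ml=5, rr_bpm=30, ti_ms=900)
cannula = CannulaSetting(flow_l_min=0.1)

result = simulate_steady_state(scenario, cannula)

print(f"scenario: VT {scenario.vt_ml} mL, RR {scenario.rr_bpm}/min, "
      f"Ti {scenario.ti_ms} ms (Te {scenario.te_ms:.0f} ms, "
      f"MV {scenario.mv_ml_min:.0f} mL/min)")
print(f"simulated effective FiO2: {result.fio2_percent:.1f}% "
      f"({result.n_breaths} breaths to steady state)")
print(f"wash-in trace (every 20th breath): "
      f"{[round(float(v), 1) for v in result.per_breath_fio2[::20]]}")

bb = benaron_benitz_fio2(0.1, 900, 5)
fi = finer_fio2(0.1, scenario.mv_ml_min)
sr = stoprop_fio2(0.1, weight_kg=1.0)  # a 1-kg infant breathing 5 mL
print(f"Benaron-Benitz formula:  {bb.fio2_percent:.1f}%")
print(f"Finer formula:           {fi.fio2_percent:.1f}%")
print(f"STOP-ROP convention:     {sr.fio2_percent:.1f}%")
print("The simulator exceeds Benaron-Benitz because cannula gas stored in the")
print("upper airway during the low-flow end of expiration is inhaled first on")
print("the next breath; the formulas ignore that reservoir.")
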