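"""Build a bedside FiO2 chart panel and apply the blender correction.

Charts answer the clinical question: given only cannula flow, infant weight
and respiratory rate (VT and Ti are unmeasurable at the bedside), what
effective FiO2 is the infant receiving?  VT is taken as 5 mL/kg; each RR
maps to its representative inspiratory time.
"""

from lfnc import ChartSpec, blender_corrected_fio2, build_chart, write_chart

spec = ChartSpec(
    flow_l_min=0.1,
    vt_per_kg=5.0,
    weight_grid=(1.0, 2.0, 3.0, 4.0, 5.0),
    rr_grid=(30, 40, 50, 60, 70, 80),
)
table = build_chart(spec)
print(f"effective FiO2 (%) at {spec.flow_l_min} L/min, VT {spec.vt_per_kg} mL/kg:")
print(table.cells.round(1).to_string())
print("FiO2 falls as weight (hence VT) or RR rises; the 30-60 bpm band is the")
print("clinically typical range.")

path = write_chart(table, "lfnc_out/chart_flow0.1_vt5.csv")
print(f"long-format chart written to {path}")

cell = table.value(2.0, 40)
corrected = blender_corrected_fio2(cell, blender_fio2_percent=50.0)
print(f"2-kg infant at RR 40: chart {cell:.1f}% -> {corrected:.1f}% effective "
      "when the supply is blended down to 50% oxygen")
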