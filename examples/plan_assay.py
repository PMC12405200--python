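"""Plan the bench work for one serum sample: volumes and dilution ladder.

Reproduces the reference configuration: triplicates over a 7-step
two-fold series, MOI 100 on 1e5 cells with a 1e10 vg/mL AAV stock.
"""

from nabstat.planner import dilution_table, plan_plate, worksheet_display

plan = plan_plate(n_replicates=3, n_steps=7, moi=100,
                  total_cells=1e5, titer_vg_per_ml=1e10)

print(f"serum needed per series : {plan.serum_volume_ul} uL   ((n+1) x 10)")
print(f"AAV mix, dilution series: {plan.aav_mix_total_ul} uL  (steps x (n+1) x 10)")
print(f"AAV mix, control wells  : {plan.control_mix_ul} uL")
print(f"viral genomes per well  : {plan.vg_per_well:.0e}  "
      f"({plan.aav_volume_per_well_ul:.2f} uL of stock)")

print("\nserial-dilution worksheet (uL, rounded for the bench):")
cols = ["during_serum", "during_fbs_prev", "final_serum", "serial_dilution",
        "mix_aav", "final_dilution"]
print(worksheet_display(dilution_table(3, 7))[cols].to_string())
print(
    "\nRow A starts at a 1/2 serum dilution; adding an equal volume of AAV "
    "mix halves\nevery concentration once more, so cells see 1/4 ... 1/256. "
    "Row H is the\nantibody-free control."
)
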