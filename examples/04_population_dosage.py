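"""Monte Carlo dosage evaluation: %T>MIC percentiles and PTA.

Simulates a virtual population per dose/schedule, computes the
percentage of the 24-h dosing day during which the free concentration
exceeds the MIC (the efficacy driver for a time-dependent
beta-lactam), and reports population percentiles plus the probability
of attaining a 40% target (gram-negative pathogens).

n=200 keeps this example quick; the study-scale analysis uses n=1000.
"""

from ceqpbpk import default_params, evaluate_dosage_grid, pta

phys, chem = default_params()
ev = evaluate_dosage_grid(phys, chem, doses=(2.0, 4.0), schedules=("q24h", "q12h"),
                          mics=(0.25,), n=200, seed=7)

print("%T>MIC (percent of the 24-h day), MIC 0.25 ug/mL, n=200:\n")
print(ev.table[["dose_mg_per_kg", "schedule", "matrix", "p10", "p50", "p90"]]
      .to_string(index=False, float_format="%.1f"))

print("\nPTA at the 40% gram-negative target:")
for dose in (2.0, 4.0):
    for schedule in ("q24h", "q12h"):
        vals = ev.values(dose, schedule, "lung_pelf", 0.25)
        print(f"  {dose:.0f} mg/kg {schedule} (lung): PTA = {pta(vals, 40.0):.2f}")
print("\nReading: once-daily label dosing leaves most animals far below "
      "the 40% target; splitting the same daily dose q12h roughly "
      "doubles %T>MIC, which is why twice-daily extra-label regimens "
      "are advised for gram-negative respiratory pathogens.")
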