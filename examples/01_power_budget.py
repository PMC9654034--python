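"""Battery autonomy of a receiver buoy.

A surface receiver carries two 12 V / 10 Ah gel batteries (20 Ah total).
The electronics draw ~0.65 W on average and 1 W when transmitting
permanently; with the solar panel failed, autonomy is energy over power.
"""

from aquapos import PowerBudget, autonomy_hours, autonomy_hours_rounded

for label, watts in [("worst case (permanent GSM transmission)", 1.0),
                     ("average case", 0.65)]:
    budget = PowerBudget(battery_voltage=12.0, battery_capacity_ah=20.0,
                         consumption_w=watts)
    print(f"{label}: {autonomy_hours(budget):7.2f} h "
          f"(~{autonomy_hours_rounded(budget)} h, "
          f"{autonomy_hours(budget) / 24:.1f} days)")

# The worst case, 240 h, is the guaranteed window for a maintenance
# intervention after a solar-panel failure; the average case is ~15 days.
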