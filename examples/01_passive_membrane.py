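"""Estimate membrane capacitance and resistance from a capacitive transient.

Simulates the 45 ms, -90 to -70 mV step for the two representative cells
and recovers their passive properties from the recorded current.
"""

from ionclamp import passive, simulate as sim

for cell in (sim.mock_default(), sim.cln1_default()):
    sweep = sim.simulate_sweep(cell, sim.capacitance_protocol())
    est = passive.passive_estimate(sweep)
    print(
        f"{cell.cell_id:13s} Cm = {est.cm:5.2f} pF   Rm = {est.rm:5.2f} GOhm   "
        f"G/Cm = {est.g_density:5.2f} pS/pF   I_hold/Cm = {est.holding_density:+.2f} pA/pF"
    )

print(
    "\nCm is the charge of the capacitive transient divided by the 20 mV step\n"
    "(a proxy for membrane surface area); the mock cell is about twice the\n"
    "size of the CLN1-overexpressing cell, while the conductance per unit\n"
    "area (~35 vs ~32 pS/pF) and the holding-current density are similar."
)
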