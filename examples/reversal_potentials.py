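"""Resting Cl⁻/HCO3⁻ reversal potentials and the GABA_A reversal.

E_Cl and E_HCO3 follow from the Nernst equation at 35 °C; E_GABA is their
conductance-weighted mean with a HCO3⁻ fraction P = 0.25. The printed value
is what every simulation in this package relaxes to at rest.
"""

from cldend import IonParams, egaba, nernst

ions = IonParams()
e_cl = nernst(-1, ions.cl_in_rest, ions.cl_out, ions.temperature)
e_hco3 = nernst(-1, ions.hco3_in, ions.hco3_out, ions.temperature)

print(f"E_Cl   = {e_cl:8.2f} mV   (5 / 133.5 mM)")
print(f"E_HCO3 = {e_hco3:8.2f} mV   (16 / 26 mM)")
print(f"E_GABA = {egaba(e_cl, e_hco3, ions.p_hco3):8.2f} mV   (P = 0.25)")
print()
print("E_GABA sits between the two: Cl⁻ dominates (75% of the conductance),")
print("so any activity-dependent rise in [Cl⁻]_i drags E_GABA upward and")
print("weakens inhibition — the basis of short-term ionic plasticity.")
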