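"""Solve the combined model for one clinical blood-gas state, both directions.

Given a whole-blood base excess, pCO2, hematocrit and plasma composition, the
solver finds the equilibrium pH and the split of the base excess between the
plasma and erythrocyte compartments; the transferred-ion charge Z_TI is the
chloride shift that reconciles them.  The inverse (BE from a measured pH) is
closed-form.
"""

from acidbase import BloodSpec, be_from_ph, solve_combined

# A mild metabolic acidosis with respiratory compensation.
spec = BloodSpec(be=-7.0, pco2=30.0, hct=0.45, alb=44.0, pi=1.15)
sol = solve_combined(spec)

print(f"inputs: BE {spec.be} mEq/l, pCO2 {spec.pco2} mmHg, Hct {spec.hct}")
print(f"pH        {sol.ph:.4f}   (acidemic: < 7.40)")
print(f"Z_TI      {sol.z_ti:+.3f} mEq/l  (ion charge moved into plasma)")
print(f"BE_HCT0   {sol.be_hct0:+.3f} mEq/l  (plasma share)")
print(f"BE_HCT1   {sol.be_hct1:+.3f} mEq/l  (erythrocyte share)")
print(f"SID       {sol.sid:.3f} mEq/l vs NSID {sol.nsid:.3f}  (SID = NSID + BE_HCT0)")
print(f"HCO3-     {sol.plasma.hco3:.3f} mmol/l")

# Round trip: the measured pH gives back the whole-blood BE algebraically.
be_back = be_from_ph(sol.ph, spec.pco2, spec.hct, spec.alb, spec.pi)
print(f"BE from pH {sol.ph:.4f}: {be_back:+.4f} mEq/l (recovers the input)")
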