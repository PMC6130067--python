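"""CO2 titration of full blood vs plasma: why erythrocytes matter.

At fixed base excess, varying pCO2 moves the pH.  Full blood deviates less
from 7.40 than erythrocyte-free plasma because hemoglobin buffers the
carbonic-acid load and the chloride shift feeds bicarbonate into plasma —
which also makes the plasma SID pCO2-dependent in full blood, unlike in
isolated plasma where SID is the independent variable.
"""

from acidbase import workbench

table = workbench.titrate_pco2(be=0.0, hct=0.45, pco2_grid=[20, 30, 40, 60, 80])

print("pCO2    pH(blood)  pH(plasma)   SID     Z_TI")
for _, r in table.iterrows():
    print(f"{r.pco2:5.0f}   {r.ph:8.4f}  {r.ph_plasma:9.4f}  {r.sid:6.3f}  {r.z_ti:+6.3f}")

print()
print("Full blood stays closer to pH 7.40 at both extremes, and its plasma")
print("SID rises with pCO2 (chloride shift) while isolated plasma would keep")
print("SID constant by construction.")
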