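"""Saline dilution: dilutional acidosis in open and closed gas regimes.

Diluting blood with saline multiplies SID, albumin, phosphate and hemoglobin
by the dilution factor; the NSID bridge turns the SID deficit into a negative
base excess.  With pCO2 held constant (open system, as in vivo) the pH falls;
if the CO2 content is diluted too (closed system) the pCO2 drops and the
acidosis is milder.
"""

from acidbase import BloodSpec, dilute_closed, dilute_open

spec = BloodSpec(be=0.0, pco2=40.0, hct=0.45, alb=44.0, pi=1.15)

print("factor   mode    BE'      pCO2'    pH'")
for factor in (1.0, 0.9, 0.8, 0.7):
    for run, mode in ((dilute_open, "open"), (dilute_closed, "closed")):
        r = run(spec, factor)
        print(f"{factor:5.2f}  {mode:>6}  {r.be_post:+6.3f}  {r.pco2_post:7.3f}"
              f"  {r.post.ph:.4f}")

print()
print("20% dilution (factor 0.8) produces BE about -4.9 mEq/l: dilutional")
print("acidosis.  The closed system is less acidotic because CO2 leaves with")
print("the diluent (pCO2 falls below 40 mmHg).")
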