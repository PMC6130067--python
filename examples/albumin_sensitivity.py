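"""Albumin sensitivity at constant base excess.

Holding BE fixed while albumin varies means the plasma SID co-varies with the
albumin charge (SID = NSID(Alb) + BE_plasma).  At the standard pCO2 of
40 mmHg the pH is pinned at 7.40 for *any* albumin level — the standard-state
anchor — so the sensitivity only shows off-normal.  Full blood is less
albumin-sensitive than isolated plasma because erythrocytes dominate the
buffering.
"""

from acidbase import workbench

for pco2 in (40.0, 80.0):
    table = workbench.albumin_sensitivity(
        be=0.0, pco2=pco2, hct=0.45, fraction_grid=[0.5, 1.0, 1.5, 2.0])
    print(f"pCO2 {pco2:.0f} mmHg")
    print("  alb fraction   pH(blood)  pH(plasma)")
    for _, r in table.iterrows():
        print(f"  {r.fraction:10.1f}   {r.ph:8.4f}  {r.ph_plasma:9.4f}")
    spread = table["ph"].max() - table["ph"].min()
    spread_pl = table["ph_plasma"].max() - table["ph_plasma"].min()
    print(f"  pH spread: blood {spread:.4f}, plasma {spread_pl:.4f}")
    print()
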