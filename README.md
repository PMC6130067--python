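# acidbase

A gray-box, steady-state model of **full-blood acid-base balance** for
computational physiologists and clinical-modeling engineers: a behavioral
Siggaard-Andersen description of the erythrocyte compartment (Van Slyke
closed form) coupled to a mechanistic Stewart/Fencl physicochemical plasma
compartment through the charge of passively exchanged ions (the chloride
shift). The result is a fast, deterministic, invertible solver for pH, base
excess (BE), strong ion difference (SID) and hemodilution effects — the kind
of robust building block needed inside larger whole-body acid-base and
blood-gas models.

## The model

Blood is split into two theoretical limit compartments sharing one pH:

* **HCT0** — pure plasma, governed by electroneutrality
  (Henderson–Hasselbalch bicarbonate plus linear-in-pH albumin and phosphate
  charges):

  `SID = s_CO2 · pCO2 · 10^(pH − pK) + [Alb](0.123·pH − 0.631) + [Pi](0.309·pH − 0.469)`

* **HCT1** — blood extrapolated to hematocrit 1 (fully oxygenated), governed
  by the Van Slyke equation at MCHC hemoglobin:

  `BE = (1 − 0.023·ctHb) · [(HCO3⁻ − HCO3⁻_ref) + (2.3·ctHb + 7.7)(pH − 7.40)]`

The two are bridged by the **normal SID**, `NSID(Alb, Pi)` = the SID plasma
would have at pH 7.40 / pCO2 40 mmHg, which identifies the plasma-side base
excess `BE_HCT0 = SID − NSID`, and by the transferred-ion charge `Z_TI`:

```
BE_HCT0 = BE − Z_TI·(1 − Hct)        BE_HCT1 = BE + Z_TI·Hct
```

Eliminating `Z_TI` leaves one monotone scalar equation in pH, solved by
bracketed Brent iteration; the reverse direction (BE from a measured pH) is
closed-form. Both submodels are anchored at pH 7.40 / pCO2 40 mmHg, so
BE = 0 always reproduces the physiological reference point exactly. Saline
dilution multiplies SID, albumin, phosphate and hemoglobin by the dilution
factor and predicts the new BE as `BE' = SID_pre·f − NSID(Alb·f, Pi·f)`, in
an open (fixed pCO2) or closed (CO2 content diluted) gas regime.

## Worked example

```python
from acidbase import BloodSpec, be_from_ph, solve_combined

sol = solve_combined(BloodSpec(be=-7.0, pco2=30.0, hct=0.45, alb=44.0, pi=1.15))
print(round(sol.ph, 4), round(sol.z_ti, 3), round(sol.sid, 3))
print(round(be_from_ph(sol.ph, 30.0, 0.45), 4))
```

prints

```
7.3479 2.682 30.322
-7.0
```

A mild metabolic acidosis with respiratory compensation settles at pH 7.348;
the chloride shift moves 2.68 mEq/l of ion charge between the compartments,
the plasma SID falls to 30.3 mEq/l (NSID is 38.8), and the closed-form
inverse recovers the input base excess exactly. The `examples/` directory
holds short narrative scripts for each capability — single solves, CO2
titration curves, albumin sensitivity, and hemodilution — each printing the
numbers it computes and what they mean.

A thin CLI wraps the same library:

```bash
acidbase solve --be 0 --pco2 5.3329kPa --hct 0.45   # pH 7.400, Z_TI 0
acidbase nsid --alb 4.4g/dl --pi 1.15               # 38.80 mEq/l
acidbase titrate pco2 --grid 20,40,80               # CSV titration table
acidbase dilute --factor 0.8 --mode open            # dilutional acidosis
acidbase stability --be-min -30 --be-max 30         # convergence report
```

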