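# Methods

## Model structure

`acidbase` computes the steady-state acid-base equilibrium of whole blood by
coupling two compartment models of opposite style — a *gray-box*
construction: one compartment is mechanistic, the other behavioral.

**Plasma (HCT0), mechanistic.** Plasma pH follows the Stewart principle that
the independent acid-base variables are the strong ion difference (SID),
pCO2 and the weak-acid totals (albumin, phosphate). Electroneutrality of the
dependent buffer anions closes the system:

    SID = [HCO3-] + Q_alb + Q_pi
    [HCO3-] = s_CO2 * pCO2 * 10^(pH - pK)
    Q_alb = [Alb] * (0.123 * pH - 0.631)      (mEq/l, [Alb] in g/l)
    Q_pi  = [Pi]  * (0.309 * pH - 0.469)      (mEq/l, [Pi] in mmol/l)

with pK = 6.1 and s_CO2 = 0.0306 mmol/(l·mmHg) — the classical simple-Fencl
coefficient set. Every term is strictly increasing in pH, so SID(pH) is a
monotone bijection on any fixed (pCO2, Alb, Pi); the inverse pH(SID) is
found by Brent's method on pH ∈ [5, 9]. The effective SID is identified
with the SID (no unmeasured-anion gap is modeled).

**Erythrocytes (HCT1), behavioral.** Blood extrapolated to hematocrit 1 and
full oxygenation is described by the Van Slyke closed form of the
Siggaard-Andersen relation:

    BE = (1 - 0.023*ctHb) * [([HCO3-] - [HCO3-]_ref) + (2.3*ctHb + 7.7)*(pH - 7.40)]

with ctHb in mmol/l of hemoglobin monomer (molar mass 16.114 kg/mol). The
compartment's hemoglobin is the mean corpuscular hemoglobin concentration,
MCHC = 33.34 g/dl ≈ 20.7 mmol/l — the physiological limit of blood that is
all erythrocytes; whole blood carries Hct × MCHC. The reference bicarbonate
is *computed* from the plasma constants as [HCO3-](pH 7.40, pCO2 40)
≈ 24.422 mmol/l rather than taken as a literature literal, which makes
BE(7.40, 40) = 0 exact and anchors both compartments at the same standard
state. A single-formula Zander description is selectable as an alternative
submodel (config `erythrocyte_model: zander`), evaluated at oxygen
saturation 1; it is nearly but not exactly zero at the standard state.

**Coupling.** Mixing the limit compartments into whole blood at hematocrit
Hct, their pH must be equal, and ions exchange passively 1:1 (the chloride
shift, Cl- for HCO3-). The exchanged charge Z_TI splits the whole-blood base
excess:

    BE_HCT0 = BE - Z_TI * (1 - Hct)
    BE_HCT1 = BE + Z_TI * Hct

and on the plasma side BE_HCT0 = SID - NSID, where the *normal SID*
NSID(Alb, Pi) is the SID this plasma would carry at pH 7.40 / pCO2 40 mmHg.
NSID is the quantitative bridge between the base-excess and strong-ion
views: it converts a SID displacement into a base excess and vice versa.

## Solution method

For a trial pH the plasma side yields BE_HCT0 directly, hence Z_TI and
BE_HCT1 by the split equations; the residual is

    r(pH) = pH - pH_SA(BE_HCT1, pCO2, MCHC)

where pH_SA is the erythrocyte-side inverse. r is strictly increasing, so
the root on the bracket pH ∈ [6.5, 8.0] (expanded once to [5.5, 9.0] before
failing) is unique. Brent iteration runs at xtol 1e-12 and the accepted
solution must satisfy |r| < 1e-9 pH units. Inside the residual the
erythrocyte inverse is clamped to its bracket endpoints when BE_HCT1 is
unreachable — a monotone total extension that keeps bracket-endpoint
evaluations defined; a clamped endpoint can never be returned as a
converged root because the sign-change test precedes bisection. The reverse
operation, BE from a known pH, needs no iteration at all: both compartment
base excesses are direct evaluations at the shared pH, and
BE = Hct·BE_HCT0 + (1-Hct)·BE_HCT1 follows algebraically.

The solver is deterministic everywhere: no random state, no initial-guess
sensitivity, bit-identical re-runs.

## Dilution

Saline carries no strong ions and no buffers, so dilution by factor f
multiplies SID, albumin, phosphate and hemoglobin (hence hematocrit) by f.
The post-dilution base excess follows from the NSID bridge:

    BE' = SID_pre * f - NSID(Alb*f, Pi*f)

In the **open** regime pCO2 is held constant (ventilation-regulated, as in
vivo). In the **closed** regime the plasma total CO2 content (dissolved
s_CO2·pCO2 plus bicarbonate) is diluted by the same factor and the
post-dilution pCO2 is found by an outer Brent search; total CO2 content is
strictly increasing in pCO2, so that root is unique as well. The CO2
accounting is plasma-side only — the behavioral erythrocyte compartment has
no explicit CO2 state, so carbamino and intracellular stores are not
conserved. Erythrocyte volume changes under tonicity are ignored
(hct' = hct·f exactly).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| pK | 6.1 | — | apparent carbonic-acid dissociation constant |
| s_CO2 | 0.0306 | mmol/(l·mmHg) | CO2 solubility in plasma |
| albumin charge | 0.123·pH − 0.631 | mEq/l per g/l | linearized albumin titration |
| phosphate charge | 0.309·pH − 0.469 | mEq/l per mmol/l | linearized phosphate titration |
| hb_factor | 0.023 | per mmol/l | Van Slyke plasma-fraction correction |
| buffer value | 2.3·ctHb + 7.7 | mEq/l per pH | non-bicarbonate buffering of blood |
| MCHC | 33.34 | g/dl | hemoglobin of the pure-erythrocyte compartment |
| nominal Alb / Pi / Hct / pCO2 | 44 g/l / 1.15 mmol/l / 0.45 / 40 mmHg | | clinical reference values |

All constants live in `ModelConfig` (YAML-overridable, unknown keys
rejected). The nominal phosphate is 1.15 mmol/l — the normal plasma value;
sources occasionally print this number with a mass unit, which would be
inconsistent with the charge model's mmol/l basis. Canonical internal units
are mmHg / g/l / mmol/l; kPa and g/dl are converted at the I/O boundary
(1 mmHg = 0.133322 kPa).

## Validated domain and known behaviors

Claims are validated for BE ∈ [−25, 25] mEq/l, pCO2 ∈ [10, 150] mmHg,
Hct ∈ [0, 0.7]; the solver in fact converges over BE ±30 and well beyond.
Several structural behaviors of this coupling are kept as defined rather
than corrected, and are frozen in tests:

* The split equations' (1−Hct)/Hct weighting does not volume-conserve
  charge: the volume-weighted compartment sum equals BE + Z_TI·(2·Hct − 1).
* At Hct → 0 the erythrocyte constraint stays active (BE_HCT1 = BE at MCHC
  hemoglobin), so the limit is *not* the plasma-only model. Consequences:
  closed-system dilution of the Hct = 0 state shifts pH by ≈ 0.077 at
  factor 0.8, whereas genuinely erythrocyte-free plasma is exactly
  pH-insensitive under closed dilution (every term scales by f — verified
  against a brute-force oracle); and the open-dilution buffering advantage
  of full blood is measured against the true plasma-only reference, not the
  Hct = 0 limit.
* The Van Slyke form's |dpH/dBE| is non-monotone in hemoglobin: buffering
  improves up to ≈ 10 mmol/l ctHb and then degrades as the (1 − 0.023·ctHb)
  prefactor dominates; at MCHC the compartment titrates steeper than
  hemoglobin-free solution.
* At BE 0 / pCO2 40 the pH is 7.400 for every albumin level (the standard
  state anchors NSID), so albumin-sensitivity comparisons are made at
  off-normal pCO2 (20 and 80 mmHg), where full blood is roughly three times
  less albumin-sensitive than isolated plasma.

## Scope and limitations

Steady state only — no time course, circulation, interstitium or renal /
respiratory regulation. Fully oxygenated blood: no oxygen-saturation
correction of BE, no DPG, fetal-hemoglobin or carboxyhemoglobin effects (the
behavioral data behind the Van Slyke form are for normal DPG and zero HbF /
CO). The simple linear albumin charge ships as the only plasma submodel; a
detailed residue-level albumin description or an Mg2+/Ca2+-binding plasma
model could replace it behind the same interface. No unmeasured-anion
(apparent-vs-effective SID) accounting. Dilution covers saline only — no
colloid or bicarbonate-containing fluids and no volume kinetics.

## Workbench and problem sizes

The workbench reproduces the model's characteristic experiments as CSV-ready
pandas tables: pCO2 titrations (default grid 10–150 mmHg step 5), strong
acid/base titrations with the SID decomposition (BE −25..25 step 1),
albumin sensitivity (50–200 % of nominal), dilution sweeps, and a
solver-stability grid (BE −30..30 step 1) whose summary reports the largest
symmetric BE half-width that converges — 30 mEq/l under the default
constants, comfortably containing the clinical ±25 range. Each solve takes
well under a millisecond, so all default sweeps complete in seconds.
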