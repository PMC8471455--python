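# neuropbpk

Semi-physiological CNS pharmacokinetic modelling in the rat, built from in
vitro blood–brain-barrier (BBB) permeability data.

Getting a drug into the brain is one of the hardest problems in CNS drug
discovery: the BBB and the blood–CSF barrier (BCSFB) keep most candidates
out, and measuring brain concentration–time profiles in vivo is slow and
expensive. `neuropbpk` implements a screening-oriented alternative: derive
the neuropharmacokinetic parameters of a compound from cheap transwell
monolayer assays (MDCK, MDCK-MDR1 or hCMEC/D3 cells), plug them into a
compartmental plasma/brain/CSF model through empirical in vitro → in vivo
scaling factors, and predict rat brain exposure from little more than a
permeability assay and the compound's logP.

## The model

**NeuroPK parameters from transwell assays.** With apparent permeabilities
measured apical→basolateral (A→B), basolateral→apical (B→A) and from a
brain-homogenate donor (HOM):

```
Kp_uu,brain = Papp(A→B) / Papp(B→A)          unbound brain:plasma ratio
f_u,brain   = Papp(B→A) / Papp(HOM)          unbound fraction in brain
V_u,brain   = V_ECF + V_ICF / f_u,brain      = 0.2 + 0.6/f_u  (mL/g brain)
```

**Compartmental model.** Plasma (volume `V_d`), brain tissue (`V_b`) and
CSF (`V_CSF`) exchange unbound drug across the BBB and BCSFB with
permeability–surface products scaled from the in vitro values:

```
PS_BBB,in  = SC1 · Papp(A→B) · S_BBB        PS_BCSFB,in  = SC1 · Papp(A→B) · S_BCSFB
PS_BBB,out = SC2 · Papp(B→A) · S_BBB        PS_BCSFB,out = SC2 · Papp(B→A) · S_BCSFB
C_u,p = f_u,plasma · C_p                    C_u,b = SC3 · f_u,brain · C_b
```

ECF bulk flow `Q_bulk` carries drug from tissue to CSF, CSF drainage
`Q_sink` returns it to plasma, elimination is first-order from plasma, and
dosing is an IV bolus, a zero-order infusion, or first-order absorption
from a depot. The system is linear, so an exact matrix-exponential solution
backs the numerical integrator everywhere.

**Fitting, QSPR and validation.** A two-stage fitter estimates the systemic
parameters from plasma data and then the scaling factors SC1–SC3 (in log
space, multi-start) from plasma + brain profiles. Per cell line, the fitted
factors are regressed on lipophilicity — `ln SC1`, `ln SC2` linear in logP,
`ln SC3` parabolic — and internal validation replaces fitted factors by
QSPR predictions and scores the prediction error of brain C_max and AUC:

```
PE% = |experimental − predicted| / experimental · 100
```

A synthetic-data module generates transwell runs and sparse noisy in vivo
profiles from known ground truth, so every estimator is testable by
recovery.

## Worked example

The package bundles the study tables for six model drugs (amitriptyline,
caffeine, carbamazepine, fleroxacin, pefloxacin, zolpidem) in three cell
lines:

```python
import numpy as np
from neuropbpk import derive_neuropk, simulate
from neuropbpk.io import (load_permeability_table, load_drug_table,
                          load_fitted_table, apply_fitted_pk)

perm = load_permeability_table()
n = derive_neuropk(perm[("amitriptyline", "MDCK")])
print(f"Kp_uu,brain = {n.kpuu_brain:.4f}, V_u,brain = {n.vu_brain:.2f} mL/g")

drugs = apply_fitted_pk(load_drug_table(), load_fitted_table()[0])
caf = drugs["caffeine"]
sc = load_fitted_table()[1][("caffeine", "MDCK")]
t = np.linspace(0, 40 / caf.k_el, 201)
prof = simulate(caf, perm[("caffeine", "MDCK")], sc, times=t)
print(f"plasma plateau: {prof[('plasma', 'total')].values[-1]:,.0f} ng/cm^3")
```

prints

```
Kp_uu,brain = 0.4189, V_u,brain = 16.42 mL/g
plasma plateau: 85,797 ng/cm^3
```

The amitriptyline Kp_uu below one reflects net efflux in the MDCK assay,
and its large V_u,brain (16.4 mL/g) the strong brain-tissue binding of a
lipophilic amine. The caffeine plateau equals the analytic steady state
`k_0/(k_el·V_d)` of a constant-rate infusion.

The same stages are available from the shell:

```sh
neuropbpk neuropk --out neuropk.csv
neuropbpk simulate --drug zolpidem --cell-line MDCK --out profiles.csv
neuropbpk qspr fit --out qspr.json
neuropbpk run --out-dir study/        # full pipeline incl. validation
```

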