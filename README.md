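# pbrpk

Physiologically based radiopharmacokinetic (PBRPK) modeling and dosimetry
for radiopharmaceutical therapy (RPT).

In RPT, a receptor-targeting ligand labeled with a therapeutic
radionuclide (e.g. ¹⁷⁷Lu-PSMA for prostate cancer) is injected together
with its inevitable unlabeled ("cold") fraction.  The dose delivered to
the tumor and to organs at risk (kidneys, salivary glands) is a
non-linear function of the injection, because labeled and unlabeled
ligand compete for a finite receptor pool.  `pbrpk` is a tool for
simulating and analyzing these effects with a whole-body compartmental
ODE model (>150 state variables, 19 organs) built on a scalable
*reaction-graph* notation: compartments hold multiple species, and every
process — plasma flow, capillary exchange, receptor binding and
internalization, renal filtration, radioactive decay, albumin binding —
is a reaction.  The model exports to and imports from SBML Level 3.

On top of the simulator sit a self-dose dosimetry layer
(dose_i = Δ·Ñ_i/m_i from the time-integrated activity Ñ_i of each organ)
and the three analyses the package exists for:

* **Hot/cold competition** — sweeps over injected hot × cold amounts;
  receptor saturation tilts the iso-dose contours in the (hot, cold)
  plane, quantified by the **twist** angle (total-least-squares line fit
  per contour, relative to the lowest-dose contour).
* **Injection fractionation** — multi-bolus schedules (n boluses, τ
  minutes apart, fixed totals 10 nmol hot / 100 nmol cold), quantified by
  the **MRDC**, the maximum relative dose change
  (Dose(n\*, τ\*) − Dose_single)/Dose_single.
* **Albumin binding** — sweeping the ligand–albumin dissociation constant
  K_D^alb; albumin-bound ligand escapes renal filtration (raising the
  blood residence time BRT = ∫A_vein dt / A₀) and leaks only into the
  tumor interstitium, quantified by the **enhancement factor**
  EF(K_D^alb) = [TumorDose/OARDose](K_D^alb) ÷ [TumorDose/OARDose](∞).

## Worked example

```python
import numpy as np
from pbrpk import (
    InjectionSchedule, ModelOptions, build_pbrpk_model, blood_residence_time,
    dose_report, load_parameter_table, make_virtual_patient, simulate,
)

base = load_parameter_table()                      # packaged 177Lu-PSMA-like physiology
patient = make_virtual_patient(base, tumor_volume_ml=100.0, receptor_density=40.0)
graph = build_pbrpk_model(patient, ModelOptions(albumin_enabled=False))
print(len(graph.species), "state variables")

res = simulate(graph, InjectionSchedule(hot_total=10.0, cold_total=100.0))
rep = dose_report(res, delta=base.mean_energy_per_decay, density=base.tissue_density,
                  organs=["tumor", "kidneys", "salivary_glands"])
print(rep.table.round(3))
print("BRT [min]:", round(blood_residence_time(res), 1))
```

prints

```
97 state variables
             organ    tia_bq_min  mass_kg  dose_gy
0            tumor  1.278347e+12    0.104   17.475
1          kidneys  8.110516e+11    0.322    3.576
2  salivary_glands  6.727842e+11    0.088   10.820
```

and `BRT [min]: 11.6`.  A 100 mL tumor at 40 nmol/L receptors holds
4 nmol of binding sites, heavily saturated by the 110 nmol injection —
the small, receptor-rich salivary glands take a comparable dose per
kilogram while the free ligand clears from blood within minutes
(BRT ≈ 12 min); the analyses below probe how specific activity,
fractionation and albumin binding move these numbers.  Sweeping this over injection and
patient grids is what the study pipelines automate:

```python
from pbrpk import default_spec, run_study, scale_grid
spec = scale_grid(default_spec("albumin"), 2)      # half-resolution K_D^alb sweep
result = run_study(spec)
print(result.ef["salivary_glands"].ef.max())       # enhancement factor > 1
```

A thin CLI wraps the same functions:

```bash
pbrpk build --tumor-volume 100 --receptor-density 40 --out model.yaml
pbrpk simulate model.yaml --hot 10 --cold 100 --out tacs.csv --doses doses.csv
pbrpk export-sbml model.yaml --out model.xml
pbrpk study hotcold --scale 5 --out hotcold.csv
```

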